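"""Conceptual-DFT reactivity descriptors and NBO second-order energies.

Frontier-orbital energies (HOMO/LUMO, optionally a SOMO for open-shell
species) are the inputs; the descriptors derived from them are the
standard global reactivity indices of conceptual density-functional
theory:

    IP  = -E_HOMO                  ionization potential
    EA  = -E_LUMO                  electron affinity
    E_g = |E_HOMO - E_LUMO|        band gap (magnitude reported)
    η   = (E_LUMO - E_HOMO)/2      chemical hardness
    S   = 1/η                      global softness
    μ   = -(IP + EA)/2             chemical potential
    ω   = μ²/(2η)                  electrophilicity index
    χ   = -μ                       electronegativity

Energies are in eV (softness in eV⁻¹).  All descriptors are computed
from unrounded intermediates.

The donor→acceptor stabilization energy of a natural-bond-orbital
interaction is the second-order perturbative estimate

    E(2) = q_i |F_ij|² / (ε_acceptor - ε_donor)

with q_i the donor-orbital occupancy, F_ij the Fock matrix element and
ε the orbital energies (all in Hartree); the result is reported as a
positive magnitude in kcal/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .constants import HARTREE_TO_KCAL

__all__ = [
    "FrontierOrbitalEnergies",
    "DescriptorSet",
    "NBOInteraction",
    "DegenerateGapError",
    "compute_descriptors",
    "nbo_e2",
    "read_orbital_records",
    "descriptor_table",
]


class DegenerateGapError(ValueError):
    """HOMO and LUMO energies coincide: hardness is 0, softness undefined."""


@dataclass(frozen=True)
class FrontierOrbitalEnergies:
    """Frontier molecular-orbital energies of one species.

    Parameters
    ----------
    e_homo, e_lumo : float
        Orbital energies in eV.  For a closed-shell species
        ``e_homo <= e_lumo`` must hold.
    e_somo : float, optional
        Singly-occupied MO energy (eV) for open-shell species.  Carried
        as an annotation only; descriptors always use (HOMO, LUMO).
    dipole_moment : float
        Dipole moment in Debye (annotation, not used by descriptors).
    label : str
        Species name used in tables.
    """

    e_homo: float
    e_lumo: float
    e_somo: float | None = None
    dipole_moment: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("e_homo", "e_lumo"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.e_homo > self.e_lumo:
            raise ValueError(
                f"closed-shell ordering violated: e_homo={self.e_homo} > "
                f"e_lumo={self.e_lumo}"
            )


@dataclass(frozen=True)
class DescriptorSet:
    """Global reactivity descriptors derived from one frontier-orbital set."""

    label: str
    ip: float
    ea: float
    e_g: float
    e_g_signed: float
    eta: float
    s: float
    mu: float
    omega: float
    chi: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class NBOInteraction:
    """One donor→acceptor natural-bond-orbital interaction (Hartree units)."""

    q_i: float
    f_ij: float
    eps_donor: float
    eps_acceptor: float
    donor_label: str = ""
    acceptor_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.q_i <= 2.0:
            raise ValueError(f"occupancy q_i={self.q_i} outside (0, 2]")
        if self.eps_acceptor == self.eps_donor:
            raise ValueError("degenerate donor/acceptor orbital energies")


def compute_descriptors(foe: FrontierOrbitalEnergies) -> DescriptorSet:
    """Compute the eight global reactivity descriptors from HOMO/LUMO.

    The band gap is stored both signed (``E_HOMO - E_LUMO``, non-positive
    for a valid closed-shell input) and as the magnitude that reactivity
    tables conventionally print.

    Raises
    ------
    DegenerateGapError
        If HOMO and LUMO coincide (hardness zero, softness undefined).
    """
    ip = -foe.e_homo
    ea = -foe.e_lumo
    e_g_signed = foe.e_homo - foe.e_lumo
    eta = (foe.e_lumo - foe.e_homo) / 2.0
    if eta == 0.0:
        raise DegenerateGapError(
            f"degenerate HOMO/LUMO gap at {foe.e_homo} eV: softness undefined"
        )
    mu = -(ip + ea) / 2.0
    return DescriptorSet(
        label=foe.label,
        ip=ip,
        ea=ea,
        e_g=abs(e_g_signed),
        e_g_signed=e_g_signed,
        eta=eta,
        s=1.0 / eta,
        mu=mu,
        omega=mu * mu / (2.0 * eta),
        chi=-mu,
    )


def nbo_e2(interaction: NBOInteraction) -> float:
    """Second-order stabilization energy E(2) in kcal/mol (magnitude).

    Invariant to the sign of the Fock element and quadratic in it.
    """
    gap = interaction.eps_acceptor - interaction.eps_donor
    e2_hartree = -interaction.q_i * interaction.f_ij**2 / gap
    return abs(e2_hartree) * HARTREE_TO_KCAL


# ---------------------------------------------------------------------------
# I/O helpers


def read_orbital_records(path: str | Path) -> list[FrontierOrbitalEnergies]:
    """Read frontier-orbital records from a JSON file.

    The file holds a list of objects with keys ``label``, ``e_homo_eV``,
    ``e_lumo_eV``, optional ``e_somo_eV`` and ``dipole_D``.
    """
    records = json.loads(Path(path).read_text())
    return [
        FrontierOrbitalEnergies(
            e_homo=rec["e_homo_eV"],
            e_lumo=rec["e_lumo_eV"],
            e_somo=rec.get("e_somo_eV"),
            dipole_moment=rec.get("dipole_D", 0.0),
            label=rec.get("label", ""),
        )
        for rec in records
    ]


#: Row order of the rendered descriptor table (name, attribute, unit).
_TABLE_ROWS = [
    ("E_LUMO (eV)", None, None),
    ("E_HOMO (eV)", None, None),
    ("Ionization potential, IP (eV)", "ip", "eV"),
    ("Electron affinity, EA (eV)", "ea", "eV"),
    ("Band gap, E_g (eV)", "e_g", "eV"),
    ("Chemical potential, mu (eV)", "mu", "eV"),
    ("Chemical hardness, eta (eV)", "eta", "eV"),
    ("Global softness, S (1/eV)", "s", "1/eV"),
    ("Electrophilicity, omega (eV)", "omega", "eV"),
    ("Electronegativity, chi (eV)", "chi", "eV"),
]


def descriptor_table(inputs: Iterable[FrontierOrbitalEnergies]) -> pd.DataFrame:
    """One column per species, descriptor rows in conventional order.

    Note: χ is labelled in eV (χ = -μ is an energy).
    """
    inputs = list(inputs)
    sets = [compute_descriptors(foe) for foe in inputs]
    data = {}
    for foe, ds in zip(inputs, sets):
        col = [foe.e_lumo, foe.e_homo] + [
            getattr(ds, attr) for _, attr, _ in _TABLE_ROWS[2:]
        ]
        data[ds.label or foe.label] = col
    return pd.DataFrame(data, index=[name for name, _, _ in _TABLE_ROWS])
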