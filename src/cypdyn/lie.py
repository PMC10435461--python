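"""Ligand–protein linear interaction energies (LIE).

Per-frame electrostatic (point-charge Coulomb) and van-der-Waals
(Lennard-Jones, Lorentz–Berthelot combining) cross-group energies:

    E_elect = Σ 332.0637 · q_i q_j / r_ij          (kcal/mol)
    E_vdW   = Σ 4 ε_ij [(σ_ij/r)¹² − (σ_ij/r)⁶]    (kcal/mol)

over ligand×protein pairs within a cutoff (12 Å default, the common MD
non-bonded cutoff).  The combined interaction energy ΔE_int is by
default the sum of the two attractive components; the alternative
combiner ``"difference"`` (E_elect − E_vdW) is retained because some
LIE write-ups print the difference form.  Uniform dielectric of 1, no
1–4 exclusions (the substrate shares no bonds with the protein), no
long-range correction.

Trajectory summaries identify the tightly bound (TB, most negative ΔE)
and loosely bound (LB, least negative ΔE) frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import COULOMB_KCAL
from .traj import Topology, Trajectory

__all__ = [
    "EnergyProfile",
    "EnergySummary",
    "ClashError",
    "coulomb_energy",
    "lj_energy",
    "lie_profile",
    "summarize_profile",
]

_CLASH_DISTANCE = 0.1  # Å


class ClashError(ValueError):
    """Two interacting atoms are unphysically close."""


@dataclass
class EnergyProfile:
    """Per-frame interaction-energy components in kcal/mol."""

    e_elect: np.ndarray
    e_vdw: np.ndarray
    delta_e: np.ndarray
    combiner: str = "sum"
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        expected = (
            self.e_elect + self.e_vdw
            if self.combiner == "sum"
            else self.e_elect - self.e_vdw
        )
        if not np.allclose(self.delta_e, expected):
            raise ValueError(
                f"delta_e inconsistent with combiner {self.combiner!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.e_elect)),
                "e_elect": self.e_elect,
                "e_vdw": self.e_vdw,
                "delta_e": self.delta_e,
            }
        )


@dataclass(frozen=True)
class EnergySummary:
    mean: float
    std: float
    min: float
    max: float
    tb_frame: int  # most negative delta_e
    lb_frame: int  # least negative delta_e
    combiner: str = "sum"
    cutoff: float = 12.0


def _cross_pairs(coords, group_a, group_b, cutoff):
    """Distances and index pairs of cross-group contacts within cutoff."""
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("interaction groups must be disjoint")
    delta = coords[group_a][:, None, :] - coords[group_b][None, :, :]
    dist = np.linalg.norm(delta, axis=2)
    if np.any(dist < _CLASH_DISTANCE):
        ia, ib = np.unravel_index(np.argmin(dist), dist.shape)
        raise ClashError(
            f"atoms {group_a[ia]} and {group_b[ib]} are "
            f"{dist[ia, ib]:.3f} Å apart (< {_CLASH_DISTANCE} Å)"
        )
    mask = dist <= cutoff if np.isfinite(cutoff) else np.ones_like(dist, bool)
    return dist, mask, group_a, group_b


def coulomb_energy(
    coords, charges, group_a, group_b, cutoff: float = 12.0
) -> float:
    """Cross-group point-charge Coulomb energy in kcal/mol."""
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    dist, mask, ga, gb = _cross_pairs(coords, group_a, group_b, cutoff)
    qq = charges[ga][:, None] * charges[gb][None, :]
    with np.errstate(divide="ignore"):
        e = COULOMB_KCAL * qq / dist
    return float(e[mask].sum())


def lj_energy(
    coords, sigmas, epsilons, group_a, group_b, cutoff: float = 12.0
) -> float:
    """Cross-group Lennard-Jones energy, Lorentz–Berthelot combining.

    σ_ij is the arithmetic and ε_ij the geometric mean of the atomic
    parameters.
    """
    coords = np.asarray(coords, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    epsilons = np.asarray(epsilons, dtype=float)
    dist, mask, ga, gb = _cross_pairs(coords, group_a, group_b, cutoff)
    sig = 0.5 * (sigmas[ga][:, None] + sigmas[gb][None, :])
    eps = np.sqrt(epsilons[ga][:, None] * epsilons[gb][None, :])
    with np.errstate(divide="ignore"):
        sr6 = (sig / dist) ** 6
    e = 4.0 * eps * (sr6**2 - sr6)
    return float(e[mask].sum())


def lie_profile(
    trajectory: Trajectory,
    topology: Topology,
    ligand: np.ndarray | None = None,
    protein: np.ndarray | None = None,
    combiner: str = "sum",
    cutoff: float = 12.0,
) -> EnergyProfile:
    """Per-frame ligand–protein interaction-energy profile.

    Selections default to the topology's ligand flag and its complement.
    ``combiner`` is ``"sum"`` (default) or ``"difference"``.
    """
    if combiner not in ("sum", "difference"):
        raise ValueError(f"unknown combiner {combiner!r}")
    ligand = topology.ligand_indices() if ligand is None else np.asarray(ligand)
    protein = (
        topology.protein_indices() if protein is None else np.asarray(protein)
    )
    if ligand.size == 0 or protein.size == 0:
        raise ValueError("ligand and protein selections must be non-empty")
    if np.intersect1d(ligand, protein).size:
        raise ValueError("ligand and protein selections overlap")
    n = trajectory.n_frames
    e_elect = np.empty(n)
    e_vdw = np.empty(n)
    for i, frame in enumerate(trajectory.coordinates):
        e_elect[i] = coulomb_energy(frame, topology.charges, ligand, protein,
                                    cutoff)
        e_vdw[i] = lj_energy(frame, topology.lj_sigma, topology.lj_epsilon,
                             ligand, protein, cutoff)
    delta = e_elect + e_vdw if combiner == "sum" else e_elect - e_vdw
    return EnergyProfile(e_elect=e_elect, e_vdw=e_vdw, delta_e=delta,
                         combiner=combiner, cutoff=cutoff)


def summarize_profile(profile: EnergyProfile) -> EnergySummary:
    """Summary statistics plus tightly/loosely bound frame indices."""
    de = profile.delta_e
    if de.size == 0:
        raise ValueError("cannot summarize an empty profile")
    return EnergySummary(
        mean=float(de.mean()),
        std=float(de.std(ddof=0)),
        min=float(de.min()),
        max=float(de.max()),
        tb_frame=int(np.argmin(de)),
        lb_frame=int(np.argmax(de)),
        combiner=profile.combiner,
        cutoff=profile.cutoff,
    )
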