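"""Crystal-cell isomorphism index and energy-framework aggregation.

Two crystal structures with near-identical packing are isomorphous; the
unit-cell similarity index quantifies this from cell edge lengths alone:

    π = (a + b + c) / (a' + b' + c') - 1

π = 0 for identical cells; the magnitude is the conventional headline
value.  Cell angles are stored for completeness but do not enter π.

Energy-framework analysis decomposes pairwise molecule–molecule
interaction energies in a crystal into electrostatic, polarization,
dispersion and repulsion components; the model total is a scaled sum
Σ k_i·E_i.  The default scale factors are the CE–HF model constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "UnitCell",
    "EnergyComponents",
    "CE_HF_SCALE_FACTORS",
    "similarity_index",
    "combine_framework_energy",
    "isomorphism_report",
    "read_unit_cell",
]

#: CE–HF energy-model scale factors (electrostatic, polarization,
#: dispersion, repulsion).
CE_HF_SCALE_FACTORS = (1.019, 0.651, 0.901, 0.811)


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: edge lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edge lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} outside (0, 180)")

    @property
    def edge_sum(self) -> float:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class EnergyComponents:
    """Energy-framework components in kcal/mol with their scale factors."""

    electrostatic: float
    polarization: float
    dispersion: float
    repulsion: float
    scale_factors: tuple[float, float, float, float] = field(
        default=CE_HF_SCALE_FACTORS
    )

    def __post_init__(self) -> None:
        if self.repulsion < 0:
            warnings.warn(
                f"repulsion component {self.repulsion} kcal/mol is negative; "
                "expected >= 0",
                stacklevel=3,
            )


def similarity_index(cell_1: UnitCell, cell_2: UnitCell) -> tuple[float, float]:
    """Unit-cell similarity index between two cells.

    Returns
    -------
    (pi_signed, pi_abs_rounded)
        The signed index and its magnitude rounded to 3 decimals, the
        form quoted in isomorphism reports.
    """
    pi = cell_1.edge_sum / cell_2.edge_sum - 1.0
    return pi, round(abs(pi), 3)


def combine_framework_energy(components: EnergyComponents) -> float:
    """Scaled total interaction energy Σ k_i·E_i in kcal/mol."""
    k = components.scale_factors
    return (
        k[0] * components.electrostatic
        + k[1] * components.polarization
        + k[2] * components.dispersion
        + k[3] * components.repulsion
    )


def isomorphism_report(
    cell_1: UnitCell, cell_2: UnitCell, hint_threshold: float = 0.01
) -> dict:
    """One-line JSON-ready verdict on two cells.

    ``isomorphous_hint`` flags |π| ≤ ``hint_threshold``; the threshold is
    a reporting convenience (only π = 0 is a strict prediction of
    isomorphism), so it is echoed in the output.
    """
    pi, pi_abs = similarity_index(cell_1, cell_2)
    return {
        "pi_signed": pi,
        "pi_abs": pi_abs,
        "isomorphous_hint": pi_abs <= hint_threshold,
        "hint_threshold": hint_threshold,
    }


def read_unit_cell(path: str | Path, label: str = "") -> UnitCell:
    """Read a unit cell from a CIF file (cell block only) or JSON.

    JSON files hold ``{"a":…, "b":…, "c":…, "alpha":…, "beta":…,
    "gamma":…}``.  CIF reading uses gemmi and consumes only the cell
    parameters.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rec = json.loads(path.read_text())
        return UnitCell(
            a=rec["a"], b=rec["b"], c=rec["c"],
            alpha=rec.get("alpha", 90.0),
            beta=rec.get("beta", 90.0),
            gamma=rec.get("gamma", 90.0),
            label=label or rec.get("label", ""),
        )
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def _num(tag: str, default: float | None = None) -> float:
        raw = block.find_value(tag)
        if raw is None:
            if default is None:
                raise ValueError(f"{path}: missing {tag}")
            return default
        return gemmi.cif.as_number(raw)

    return UnitCell(
        a=_num("_cell_length_a"),
        b=_num("_cell_length_b"),
        c=_num("_cell_length_c"),
        alpha=_num("_cell_angle_alpha", 90.0),
        beta=_num("_cell_angle_beta", 90.0),
        gamma=_num("_cell_angle_gamma", 90.0),
        label=label or block.name,
    )
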