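"""Worked-example reference data for the Ni(II)/Cu(II) dithiocarbamate system.

Published measurements and simulation summaries for the two isomorphous
bis(N'-(2,6-dichlorophenyl)-N-mesitylformamidine dithiocarbamato)
complexes — [Ni(L)₂] (complex 1) and [Cu(L)₂] (complex 2) — and their
CYP3A4 molecular-dynamics models.  These records serve as ready-made
inputs for the arithmetic stages of the pipeline (descriptor derivation,
cell-similarity, population totals, interdomain aggregation), mirroring
how a practitioner would feed tabulated quantum-chemistry or
crystallography output into the analysis.
"""

from __future__ import annotations

from .crystal import EnergyComponents, UnitCell
from .qc import FrontierOrbitalEnergies

__all__ = [
    "UNIT_CELL_NI",
    "UNIT_CELL_CU",
    "ORBITALS_NI",
    "ORBITALS_CU",
    "HIRSHFELD_COMPONENTS_NI",
    "STATE_PERCENTAGES",
    "INTERDOMAIN_STATE_MEANS",
]

#: 100 K single-crystal unit cells (monoclinic, P2₁/c).
UNIT_CELL_NI = UnitCell(
    a=7.5570, b=29.5198, c=10.2393,
    alpha=90.0, beta=106.398, gamma=90.0,
    label="complex 1 [Ni(L)2]",
)
UNIT_CELL_CU = UnitCell(
    a=7.5424, b=29.800, c=10.060,
    alpha=90.0, beta=108.449, gamma=90.0,
    label="complex 2 [Cu(L)2]",
)

#: M06-L/def2-TZVP frontier-orbital energies (eV) and dipoles (D).
ORBITALS_NI = FrontierOrbitalEnergies(
    e_homo=-4.24, e_lumo=-2.69, dipole_moment=0.29, label="complex 1"
)
ORBITALS_CU = FrontierOrbitalEnergies(
    e_homo=-5.39, e_lumo=-2.66, e_somo=-4.06, dipole_moment=1.04,
    label="complex 2",
)

#: HF/6-31G energy-framework components for complex 1 (kcal/mol):
#: electrostatic, polarization, dispersion, repulsion.
HIRSHFELD_COMPONENTS_NI = EnergyComponents(
    electrostatic=-14.36, polarization=-4.57,
    dispersion=-68.31, repulsion=31.26,
)

#: Core-state occupancy percentages per protein conformational state
#: from GMM/inflection clustering of the backbone-PCA landscapes of the
#: apo and substrate-bound CYP3A4 simulations.
STATE_PERCENTAGES: dict[str, list[float]] = {
    "CYP3A4": [4.9, 1.9, 1.2, 16.7, 10.0],
    "CYP3A4-1": [5.7, 6.3, 9.5, 7.3, 0.4, 8.3],
    "CYP3A4-2": [11.1, 0.5, 4.4, 3.6, 11.5, 7.0],
}

#: Mean interdomain centre-of-mass distances (Å) per binding-site state
#: for the three pairs most relevant to substrate stabilisation.
INTERDOMAIN_STATE_MEANS: dict[str, dict[str, float]] = {
    "S1": {"core-bb": 17.2, "bb-beta": 19.7, "core-beta": 24.5},
    "S2": {"core-bb": 17.4, "bb-beta": 19.4, "core-beta": 24.2},
    "S3": {"core-bb": 16.1, "bb-beta": 20.0, "core-beta": 24.6},
    "S4": {"core-bb": 18.7, "bb-beta": 19.2, "core-beta": 26.0},
    "S5": {"core-bb": 20.4, "bb-beta": 20.2, "core-beta": 26.7},
}
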