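"""Physical constants and unit conversions used package-wide.

All energies are kcal/mol, lengths Å, charges in units of the elementary
charge e, temperatures K, unless a function documents otherwise.
"""

#: Boltzmann constant, kcal/(mol·K).
KB_KCAL = 0.0019872041

#: Hartree → kcal/mol.
HARTREE_TO_KCAL = 627.5095

#: Hartree → eV.
HARTREE_TO_EV = 27.2114

#: Coulomb prefactor e²/(4πε₀) in kcal·Å/(mol·e²):
#: two unit charges 1 Å apart repel with 332.0637 kcal/mol.
COULOMB_KCAL = 332.0637

#: Electric-field prefactor e/(4πε₀) in MV·Å²/(cm·e):
#: a unit point charge produces 1439.964 MV/cm at 1 Å.
EFIELD_MV_CM = 1439.964

#: Default RNG seed recorded in generator output headers.
DEFAULT_SEED = 20230817


def kbt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol at ``temperature`` kelvin."""
    return KB_KCAL * temperature
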