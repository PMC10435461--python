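# cypdyn

Reactivity descriptors, crystal-cell similarity and trajectory
analytics for metal–dithiocarbamate complexes as CYP3A4 substrates.

## What this package is for

Square-planar Ni(II) and Cu(II) complexes of formamidine dithiocarbamate
ligands are candidate substrates/inhibitors of cytochrome P450 3A4
(CYP3A4), the enzyme that metabolises a large share of clinical drugs.
Characterising such complexes computationally spans three layers:

1. **Electronic structure** — global reactivity indices from
   frontier-orbital energies (IP = −E_HOMO, EA = −E_LUMO, gap, hardness
   η = (E_LUMO−E_HOMO)/2, softness S = 1/η, chemical potential
   μ = −(IP+EA)/2, electrophilicity ω = μ²/2η, electronegativity
   χ = −μ), plus NBO second-order stabilization energies
   E(2) = q_i|F_ij|²/Δε.
2. **Crystallography** — the unit-cell similarity index
   π = (a+b+c)/(a′+b′+c′) − 1 quantifying isomorphism of two crystal
   structures, and CE-model aggregation of Hirshfeld energy-framework
   components Σ k_i·E_i.
3. **Dynamics** — for enzyme–substrate MD trajectories: cRMSD/dRMSD/
   RMSF, interdomain centre-of-mass distances of the four mobile CYP3A4
   regions, PCA/LDA collective variables, Gaussian-mixture free-energy
   landscapes G(x) = −k_BT log ρ(x) with inflection-delimited *core
   states* (whose populations sum to < 100 %), ligand–protein linear
   interaction energies (Coulomb + Lennard-Jones), and the per-residue
   electric field projected onto the catalytic sulfur–metal bond,
   E_proj = E⃗·r⃗_bond/|r⃗_bond| in MV/cm.

The quantum-chemistry and MD engines are out of scope: their outputs
are this package's inputs.  A synthetic-systems module generates bead
proteins, planar metal–ligand mimics and metastable trajectories with
exactly known state structure, so every estimator is testable end to
end without external data.  See `docs/methods.md` for models,
conventions and limitations.

## Worked example

Descriptors for the two isomorphous complexes from their M06-L/def2-TZVP
frontier-orbital energies (bundled in `cypdyn.refdata`):

```python
>>> from cypdyn.qc import descriptor_table
>>> from cypdyn.refdata import ORBITALS_NI, ORBITALS_CU
>>> print(descriptor_table([ORBITALS_NI, ORBITALS_CU]).round(2).to_string())
                               complex 1  complex 2
E_LUMO (eV)                        -2.69      -2.66
E_HOMO (eV)                        -4.24      -5.39
Ionization potential, IP (eV)       4.24       5.39
Electron affinity, EA (eV)          2.69       2.66
Band gap, E_g (eV)                  1.55       2.73
Chemical potential, mu (eV)        -3.46      -4.03
Chemical hardness, eta (eV)         0.78       1.36
Global softness, S (1/eV)           1.29       0.73
Electrophilicity, omega (eV)        7.75       5.93
Electronegativity, chi (eV)         3.46       4.03
```

The smaller gap, hardness and higher softness/electrophilicity of the
Ni(II) complex (column 1) mark it as the more reactive of the pair.
Its unit cell is nearly identical to the Cu(II) complex's:

```python
>>> from cypdyn.crystal import isomorphism_report
>>> from cypdyn.refdata import UNIT_CELL_NI, UNIT_CELL_CU
>>> isomorphism_report(UNIT_CELL_NI, UNIT_CELL_CU)
{'pi_signed': -0.00182058292407139, 'pi_abs': 0.002,
 'isomorphous_hint': True, 'hint_threshold': 0.01}
```

|π| = 0.002 ≈ 0: the two structures are predictably isomorphous.

The full dynamics pipeline runs from one YAML config (mandatory seed)
and is bit-reproducible:

```sh
cypdyn all --config run.yaml
```

with e.g.

```yaml
seed: 11
outdir: run/
n_frames: 500
state_weights: [0.5, 0.3, 0.2]
```

This simulates the bead complex and a 3-state metastable trajectory,
computes all metrics and writes per-stage CSV/JSON artifacts, a
rendered `report.txt` (state populations and their total, per-state
interdomain distances, interaction-energy summary with tightly/loosely
bound frames, significant residues by projected field) and a
`manifest.json` of checksums.

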