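# Methods

This note documents the models, conventions and numerical choices behind
`cypdyn`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what each component computes, under which
assumptions, and what the synthetic test systems do and do not show.

## Scope and data model

The package covers the computational analysis arc of a combined
crystallography / quantum-chemistry / MD study of square-planar Ni(II)
and Cu(II) bis(dithiocarbamate) complexes as CYP3A4 substrates.  It does
**not** run SCF/DFT calculations or force-field MD: frontier-orbital
energies, NBO matrix elements, atomic charges, unit cells and
trajectories are *inputs*.  Tabulated quantities from the published
study of this system (`cypdyn.refdata`) serve as worked-example inputs
for the arithmetic stages; everything dynamical runs on synthetic
systems with known ground truth (`cypdyn.synthetic`).

Units throughout: Å, kcal/mol, elementary charges, K, eV for orbital
energies, MV/cm for fields.  Constants are fixed project-wide
(`cypdyn.constants`): k_B = 0.0019872041 kcal/(mol·K), Hartree→kcal/mol
= 627.5095, Hartree→eV = 27.2114, Coulomb prefactor 332.0637
kcal·Å/(mol·e²), field prefactor 1439.964 MV·Å²/(cm·e).

## Reactivity descriptors (`qc`)

The eight global conceptual-DFT indices are computed from unrounded
HOMO/LUMO energies: IP = −E_HOMO, EA = −E_LUMO, gap, hardness
η = (E_LUMO−E_HOMO)/2, softness S = 1/η, chemical potential
μ = −(IP+EA)/2, electrophilicity ω = μ²/2η, electronegativity χ = −μ.
Two conventions worth noting:

* the *signed* gap E_HOMO−E_LUMO is non-positive for valid inputs, but
  reactivity tables print magnitudes; `DescriptorSet` stores both and
  reports the magnitude.
* χ is an energy and is labelled in eV (some tables circulate with a
  stray eV^1/2 unit on χ).
* open-shell species (a SOMO present) still use (HOMO, LUMO); the SOMO
  is carried as annotation only.

Worked-example checks use ±0.05 eV slack on chained quantities (ω, η)
because printed tables round intermediates; identities S·η = 1, χ = −μ,
ω ≥ 0 hold exactly by construction and are property-tested.

NBO second-order stabilization E(2) = q_i|F_ij|²/Δε is reported as a
positive magnitude in kcal/mol; it is invariant to the sign of F_ij and
quadratic in it.

## Crystal metrics (`crystal`)

The unit-cell similarity index π = (a+b+c)/(a′+b′+c′) − 1 uses edge
lengths only (angles are stored but unused — that is the definition of
the index, not an approximation).  π = 0 means predictably isomorphous;
the |π| ≤ 0.01 "isomorphous hint" in reports is a convenience threshold
and is echoed as such in the output.

Energy-framework totals are Σ k_i·E_i over (electrostatic,
polarization, dispersion, repulsion) with the CE–HF model constants
(1.019, 0.651, 0.901, 0.811) as defaults and a config override; reports
always echo the factors used.

## Synthetic systems (`synthetic`)

Three generators provide ground truth; all are bit-reproducible under a
seed (default 20230817).

**Langevin sampler.**  Overdamped (Brownian) Euler–Maruyama on a 2-D
multi-well potential; a full inertial integrator is unnecessary because
only equilibrium statistics feed downstream.  The default potential is
a sum of inverted Gaussian wells U(x) = −Σ dᵢ exp(−|x−cᵢ|²/2wᵢ²)
(harmonic stiffness dᵢ/wᵢ² near each bottom); a single pure-parabola
`"harmonic"` form exists for closed-form calibration (equipartition:
var = k_BT/k).  Wells constructed with equal stiffness have a
free-energy gap equal to their depth difference in the harmonic
approximation, giving Boltzmann occupancy ratios to test against.
Discretization bias of the stationary variance is (1−a/2)⁻¹ with
a = k·dt/γ; tests use a ≤ 0.05 (bias ≤ 2.5%).

**Bead complex.**  A self-avoiding random-walk protein (0.5 Å overlap
floor, resampled, hard error after 100 attempts) of n_residues ×
atoms_per_residue beads with Gaussian charges (mean-centred, so the
fragment is neutral as force-field fragments are), uniform LJ σ/ε, and
four equal residue-range regions (`core`, `phe`, `beta`, `bb_loop`)
mirroring the four mobile CYP3A4 regions.  The ligand mimic is an
idealised square-planar complex: central metal bead, four donor beads
at 2.25 Å, optional ring beads, neutral overall by default (metal
+0.6 e, donors −0.15 e), placed at ~4 Å clearance from the protein —
near the LJ minimum, so thermal fluctuations do not produce unphysical
clashes.

**Metastable trajectory.**  Frames relax toward the current anchor
conformation by an Ornstein–Uhlenbeck update (per-atom harmonic
restraint, default 5 kcal/mol/Å², 300 K) while the anchor index jumps
with probability `switch_prob` to a state drawn from the target
weights.  The jump chain's stationary distribution is *exactly* the
requested weights, and true labels are returned — ground truth for
population-recovery tests.  This is a deliberate idealisation: there is
no barrier-crossing kinetics, no solvent, no force-field realism.
Passing recovery tests therefore demonstrates the *estimators* are
correct, not that real CYP3A4 trajectories would yield these
populations.

## Trajectory metrics (`traj`)

Backbone selection is atom names N/CA/C; residues are 1-based with
inclusive ranges.  cRMSD superposes each frame on the reference over
the selection (Kabsch SVD with determinant correction) before the RMSD;
dRMSD is the RMS over all unique intra-selection pair-distance changes,
with no superposition (rigid-invariant by construction) and heavy atoms
only by default.  RMSF aligns frames to the iteratively refined average
structure (two passes — exact for the harmonic fluctuations generated
here), averages per-atom fluctuations within residues, and reports the
grand mean ± std across residues.  Interdomain features are
mass-weighted COM distances for the six unordered pairs of four named
regions, in fixed `itertools.combinations` column order.

The per-state "total average" of three selected pairs is the mean of
the three pair means (this convention reproduces the published
closed-state 20.5 Å and open-state 22.4 Å totals exactly at 1 d.p.);
its ± is the population std over those three means, which is the one
part of the published table that no convention reproduces.

I/O: PDB via MDAnalysis with a JSON sidecar for charges/LJ/regions
(PDB cannot carry them), multi-frame XYZ and little-endian
CHARMM/X-PLOR DCD for trajectories.

## Dimensionality reduction (`reduce`)

PCA is a mean-centred covariance eigendecomposition ("PCA of the
backbone RMSD" is implemented as PCA of superposed backbone Cartesian
coordinates — the conventional choice behind 2-D PC free-energy
landscapes; per-atom deviation magnitudes are available via
`mode="deviations"`).  LDA whitens the within-class scatter by Cholesky
and takes the SVD of the weighted class-mean matrix; at most
n_classes−1 informative directions, ridge regularization (logged) for
singular scatter.  Interdomain distances are not standardized before
LDA by default (they share units); component signs are fixed by making
each component's largest-magnitude loading positive so runs are
comparable.

## State model (`states`)

The mixture density ρ(x) = Σ aₖN(x; μₖ, Σₖ) is fitted by EM
(scikit-learn, full covariances, tol 1e-6, ≤500 iterations, seeded
k-means++ restarts, covariance floor 1e-6); model order is chosen by
minimum BIC over a candidate range, defaulting to 2-D collective
variables.  The landscape is G(x) = −k_BT log ρ(x) at 300 K on a
100×100 grid spanning the data ± 10%, shifted so min G = 0, with a
1e-12 density floor (cells below it are flagged unsampled, G = +∞).

Core states: for each component the mixture density is profiled along
the component's Mahalanobis radius (averaged over its ± principal-axis
directions, r ∈ [0, 4] in steps of 0.01) and the first concave→convex
second-derivative sign change marks the inflection (r = 1 exactly for
an isolated Gaussian); the mixture density there is the component's
core threshold.  A frame is assigned to component k iff its posterior
for k exceeds ½ **and** its mixture density is at or above threshold k;
everything else stays unassigned.  This is what makes state populations
sum to well under 100%.  When no inflection exists (heavily overlapping
components) the threshold falls back to the 60th density percentile of
the component's members, with a logged warning.  For an isotropic 2-D
Gaussian the core captures 1−e^{−1/2} ≈ 39.3% of the mass, which the
tests verify.

State "pathways" are energy orderings — states sorted by ascending free
energy of their density modes (descending mixture density at the
component means), ties broken by descending population then index.  No
kinetics is implied.

## Interaction energies (`lie`)

Point-charge Coulomb and Lennard-Jones (Lorentz–Berthelot) cross-group
sums, uniform dielectric 1, no exclusions (the substrate is
non-covalently bound and shares no bonded terms with the protein), a
12 Å cutoff by default (the common MD non-bonded cutoff; summaries echo
it), pairs closer than 0.1 Å abort with the pair named.  ΔE_int
defaults to E_elect + E_vdW; the `"difference"` combiner
(E_elect − E_vdW) is retained for comparison with LIE write-ups that
print a difference form.  The tightly bound frame is the argmin of ΔE,
loosely bound the argmax; both are exportable as PDB snapshots.

## Electric fields (`efield`)

The protein's field at the probe bond is the bare point-charge sum with
K = 1439.964 MV·Å²/(cm·e), evaluated at the bond midpoint by default
(configurable to either atom), projected onto the bond axis; positive
means along atom_i→atom_j.  The probe atoms and the entire ligand are
excluded from the source sum — the quantity of interest is the protein
environment's action on the sulfur–metal contact — with a config
override.  No source cutoff (fields decay as r⁻² and the full sum is
cheap at this scale); no induced polarization or solvent reaction
field.  The per-residue decomposition is exactly additive, which is
asserted per frame in tests.  Residues with |mean| ≥ 7.5 MV/cm (the
significance convention for this system) are ranked by |mean|
descending and their summed mean is reported as the total.

## Pipeline and determinism

`run_pipeline` executes all stages from one config with a mandatory
seed, writes per-stage CSV/JSON plus a manifest of SHA-256 checksums,
and aborts on a stage failure with a `FAILED` marker naming the stage.
Re-running an identical config reproduces every checksum (tested).
Rounding (descriptors 2 d.p.; populations, distances, fields 1 d.p.)
happens only in the report renderer; artifacts keep full precision.

Default problem sizes are desk-scale by design: 20-residue/3-atom bead
proteins, hundreds-to-thousands of frames, 2-D CV spaces, 5,000-sample
mixture fits, 2–4·10⁵-step Langevin chains.  These sizes make every
statistical tolerance in the test suite attainable with comfortable
margins while keeping a full run in seconds.

## Known limitations

* Synthetic trajectories have exact harmonic-bath structure; estimator
  correctness on them does not validate force-field or sampling
  adequacy on real proteins.
* The published microsecond-MD absolute numbers (state-population
  tables, −97/−87 kcal/mol interaction averages, per-residue field
  magnitudes, RMSF means) are not reproducible without the original
  trajectories and are not targets of this package; only the printed
  arithmetic conventions around them are.
* The LDA projection is defined up to an invertible linear
  recombination of discriminants (tests compare up to such a map).
* DCD support assumes the little-endian CHARMM/X-PLOR dialect.
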