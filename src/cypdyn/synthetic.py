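"""Synthetic systems: ground-truth inputs for every downstream stage.

Real studies of metal-complex substrates obtain their inputs from
quantum-chemistry engines and microsecond MD.  This module generates
desk-scale stand-ins with *known* ground truth:

* a 2-D overdamped (Brownian) Langevin sampler on a multi-well
  potential, whose long-run histogram converges to the Boltzmann
  distribution — ground truth for free-energy-surface and clustering
  recovery;
* a coarse bead "protein" with per-atom charges and Lennard-Jones
  parameters plus a planar 4-coordinate metal–ligand mimic (one metal
  bead, four donor beads in a square-planar arrangement, optional ring
  beads) — ground truth for energy and field calculations;
* a metastable trajectory generator: frames fluctuate harmonically
  about anchor conformations and hop between anchors by a discrete
  Markov jump process whose stationary distribution equals the
  requested state weights, so the true per-frame state labels are known
  exactly — ground truth for state-population recovery.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_SEED, kbt
from .traj import Topology, Trajectory

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "LigandSpec",
    "ToyComplexSpec",
    "simulate_langevin_2d",
    "build_toy_complex",
    "simulate_toy_trajectory",
]


@dataclass(frozen=True)
class PotentialSpec:
    """A 2-D potential built from wells.

    Each well is ``(center, depth, width)`` with ``center`` a 2-vector
    in collective-variable units, ``depth`` in kcal/mol (> 0) and
    ``width`` in CV units (> 0).

    ``form``:

    * ``"gaussian"`` (default): U(x) = −Σ dᵢ·exp(−|x−cᵢ|²/2wᵢ²).  Near
      well *i*'s bottom the effective harmonic stiffness is dᵢ/wᵢ².
      Wells built with equal stiffness have a free-energy gap equal to
      their depth difference (harmonic approximation).
    * ``"harmonic"``: a single pure parabola U = ½k|x−c|² with
      k = depth/width² — exact closed-form statistics for calibration.
    """

    wells: tuple[tuple[tuple[float, float], float, float], ...]
    temperature: float = 300.0
    form: str = "gaussian"

    def __post_init__(self) -> None:
        if len(self.wells) < 1:
            raise ValueError("at least one well is required")
        for center, depth, width in self.wells:
            if depth <= 0 or width <= 0:
                raise ValueError("well depths and widths must be positive")
            if len(center) != 2:
                raise ValueError("well centers must be 2-vectors")
        if self.form not in ("gaussian", "harmonic"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form == "harmonic" and len(self.wells) != 1:
            raise ValueError("harmonic form supports exactly one well")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    def energy_and_force(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Potential energy (kcal/mol) and force −∇U at position ``x``."""
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            center, depth, width = self.wells[0]
            k = depth / width**2
            dx = x - np.asarray(center)
            return 0.5 * k * float(dx @ dx), -k * dx
        u = 0.0
        force = np.zeros(2)
        for center, depth, width in self.wells:
            dx = x - np.asarray(center)
            g = depth * np.exp(-float(dx @ dx) / (2.0 * width**2))
            u -= g
            force -= g / width**2 * dx
        return u, force


@dataclass(frozen=True)
class LangevinParams:
    """Integration settings for the overdamped sampler.

    ``dt`` and ``friction`` are in reduced units; the mobility dt/γ
    controls the per-step displacement.
    """

    dt: float = 0.01
    friction: float = 1.0
    n_steps: int = 10000
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")


def simulate_langevin_2d(
    potential: PotentialSpec, params: LangevinParams
) -> np.ndarray:
    """Sample a 2-D overdamped-Langevin (Brownian-dynamics) trajectory.

    Euler–Maruyama update
    ``x ← x + (dt/γ)·F(x) + sqrt(2·k_B·T·dt/γ)·ξ`` with ξ ~ N(0, I).
    The chain starts at the deepest well's center.  Long runs sample the
    Boltzmann distribution of the potential at the spec temperature.

    Returns an ``(n_steps, 2)`` position matrix.
    """
    rng = np.random.default_rng(params.seed)
    mobility = params.dt / params.friction
    noise_scale = np.sqrt(2.0 * kbt(potential.temperature) * mobility)
    x = np.asarray(max(potential.wells, key=lambda w: w[1])[0], dtype=float).copy()
    noise = rng.standard_normal((params.n_steps, 2)) * noise_scale
    out = np.empty((params.n_steps, 2))
    for i in range(params.n_steps):
        _, force = potential.energy_and_force(x)
        if not np.all(np.isfinite(force)):
            raise FloatingPointError(
                f"non-finite force at step {i}, position {x}: "
                "reduce dt or check the potential"
            )
        x = x + mobility * force + noise[i]
        out[i] = x
    return out


@dataclass(frozen=True)
class LigandSpec:
    """Planar 4-coordinate metal–ligand mimic at bead resolution.

    A central metal bead, four donor (sulfur-like) beads at the corners
    of a square of side defined by ``bond_length``, and ``n_ring_beads``
    outer beads on a circle of ``ring_radius``, all in the z = 0 plane
    of the ligand frame (a distorted-square-planar complex flattened to
    its ideal geometry).
    """

    metal_charge: float = 0.6
    donor_charge: float = -0.15
    ring_charge: float = 0.0
    bond_length: float = 2.25  # Å, metal–donor
    n_ring_beads: int = 4
    ring_radius: float = 4.0  # Å
    lj_sigma: float = 3.5  # Å
    lj_epsilon: float = 0.15  # kcal/mol
    metal_mass: float = 58.7  # amu (Ni-like)
    bead_mass: float = 32.0  # amu (S-like)

    @property
    def n_atoms(self) -> int:
        return 1 + 4 + self.n_ring_beads


@dataclass(frozen=True)
class ToyComplexSpec:
    """Specification of the coarse bead protein plus ligand mimic."""

    n_residues: int = 20
    atoms_per_residue: int = 3
    charge_scale: float = 0.2  # e, std of bead charges
    lj_sigma_range: tuple[float, float] = (3.0, 4.0)  # Å
    lj_epsilon_range: tuple[float, float] = (0.05, 0.3)  # kcal/mol
    ligand_spec: LigandSpec = field(default_factory=LigandSpec)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.atoms_per_residue < 1:
            raise ValueError("need at least one residue and one atom each")


_MIN_SEPARATION = 0.5  # Å; closer beads are resampled


def build_toy_complex(spec: ToyComplexSpec) -> tuple[Topology, np.ndarray]:
    """Build the bead complex: (topology, reference coordinates in Å).

    Protein beads are placed sequentially on a loose self-avoiding
    random walk (bond length ~1.5 Å, resampled on overlap closer than
    0.5 Å, error after 100 attempts per bead); the ligand sits at the
    protein centroid, displaced until clash-free.  The topology carries
    per-atom charge, LJ σ/ε, mass, residue index and a ligand flag, and
    defines four equal residue-range regions named ``core``, ``phe``,
    ``beta`` and ``bb_loop`` mirroring the four mobile regions used for
    interdomain features.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lig = spec.ligand_spec
    n_prot = spec.n_residues * spec.atoms_per_residue

    positions = np.empty((n_prot, 3))
    positions[0] = 0.0
    for i in range(1, n_prot):
        for attempt in range(100):
            step = rng.standard_normal(3)
            step *= 1.5 / np.linalg.norm(step)
            candidate = positions[i - 1] + step
            d = np.linalg.norm(positions[:i] - candidate, axis=1)
            if np.all(d >= _MIN_SEPARATION):
                positions[i] = candidate
                break
        else:
            raise RuntimeError(
                f"could not place bead {i} without overlap after 100 tries"
            )

    # Ligand beads in the z=0 ligand frame, then shifted near the centroid.
    lig_local = [np.zeros(3)]
    for ang in np.deg2rad([45.0, 135.0, 225.0, 315.0]):
        lig_local.append(
            np.array([np.cos(ang), np.sin(ang), 0.0]) * lig.bond_length
        )
    for j in range(lig.n_ring_beads):
        ang = 2.0 * np.pi * j / max(lig.n_ring_beads, 1)
        lig_local.append(
            np.array([np.cos(ang), np.sin(ang), 0.0]) * lig.ring_radius
        )
    lig_local = np.array(lig_local)
    # Ligand sits near the protein centroid at van-der-Waals contact
    # distance, so thermal fluctuations cannot drive unphysical clashes.
    clearance = 4.0  # Å, near the Lennard-Jones minimum for σ ≈ 3.5 Å
    centroid = positions.mean(axis=0)
    for attempt in range(100):
        offset = centroid + rng.standard_normal(3) * (clearance + attempt * 0.3)
        lig_pos = lig_local + offset
        dmin = np.min(
            np.linalg.norm(
                positions[:, None, :] - lig_pos[None, :, :], axis=2
            )
        )
        if dmin >= clearance:
            break
    else:
        raise RuntimeError("could not place ligand without overlap")

    coords = np.vstack([positions, lig_pos])

    bead_names = ["N", "CA", "C", "O", "CB", "CG"]
    names = [
        bead_names[a % len(bead_names)]
        for _ in range(spec.n_residues)
        for a in range(spec.atoms_per_residue)
    ]
    resids = np.repeat(np.arange(1, spec.n_residues + 1), spec.atoms_per_residue)
    resnames = ["GLY"] * n_prot
    if spec.charge_scale != 0:
        charges = rng.standard_normal(n_prot) * spec.charge_scale
        charges -= charges.mean()  # neutral protein fragment
    else:
        charges = np.zeros(n_prot)
    lj_sigma = rng.uniform(*spec.lj_sigma_range, n_prot)
    lj_epsilon = rng.uniform(*spec.lj_epsilon_range, n_prot)
    masses = np.full(n_prot, 12.0)

    lig_resid = spec.n_residues + 1
    names += ["MT"] + [f"S{k}" for k in range(1, 5)] + [
        f"CR{k}" for k in range(1, lig.n_ring_beads + 1)
    ]
    resids = np.concatenate([resids, np.full(lig.n_atoms, lig_resid)])
    resnames += ["LIG"] * lig.n_atoms
    charges = np.concatenate(
        [
            charges,
            [lig.metal_charge],
            [lig.donor_charge] * 4,
            [lig.ring_charge] * lig.n_ring_beads,
        ]
    )
    lj_sigma = np.concatenate([lj_sigma, np.full(lig.n_atoms, lig.lj_sigma)])
    lj_epsilon = np.concatenate(
        [lj_epsilon, np.full(lig.n_atoms, lig.lj_epsilon)]
    )
    masses = np.concatenate(
        [masses, [lig.metal_mass], np.full(4 + lig.n_ring_beads, lig.bead_mass)]
    )
    is_ligand = np.concatenate(
        [np.zeros(n_prot, dtype=bool), np.ones(lig.n_atoms, dtype=bool)]
    )

    quarter = max(spec.n_residues // 4, 1)
    regions = {
        "core": [(1, quarter)],
        "phe": [(quarter + 1, 2 * quarter)],
        "beta": [(2 * quarter + 1, 3 * quarter)],
        "bb_loop": [(3 * quarter + 1, spec.n_residues)],
    }

    topology = Topology(
        names=names,
        resids=resids,
        resnames=resnames,
        charges=charges,
        lj_sigma=lj_sigma,
        lj_epsilon=lj_epsilon,
        masses=masses,
        is_ligand=is_ligand,
        regions=regions,
    )
    return topology, coords


def simulate_toy_trajectory(
    topology: Topology,
    anchors: Sequence[np.ndarray],
    weights: Sequence[float],
    params: LangevinParams,
    temperature: float = 300.0,
    stiffness: float = 5.0,
    switch_prob: float = 0.02,
) -> tuple[Trajectory, np.ndarray]:
    """Metastable trajectory: harmonic baths around anchors + Markov jumps.

    Per frame every atom relaxes toward the current anchor with an
    Ornstein–Uhlenbeck update (per-atom harmonic restraint ``stiffness``
    kcal/mol/Å², thermal noise at ``temperature``), and the anchor index
    switches with probability ``switch_prob`` to a state drawn from
    ``weights`` — a jump chain whose stationary distribution is exactly
    ``weights``, so the returned labels are exact ground truth.

    Returns ``(trajectory, labels)`` with 1-based state labels.
    """
    weights = np.asarray(weights, dtype=float)
    if len(anchors) != len(weights):
        raise ValueError("one weight per anchor is required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    anchors = [np.asarray(a, dtype=float) for a in anchors]
    for a in anchors:
        if a.shape != (topology.n_atoms, 3):
            raise ValueError(
                f"anchor shape {a.shape} does not match topology "
                f"({topology.n_atoms} atoms)"
            )

    rng = np.random.default_rng(params.seed)
    relax = stiffness * params.dt / params.friction
    if relax >= 1.0:
        raise ValueError("stiffness·dt/friction must be < 1 for stability")
    noise_scale = np.sqrt(2.0 * kbt(temperature) * params.dt / params.friction)

    state = int(rng.choice(len(anchors), p=weights))
    x = anchors[state].copy()
    frames = np.empty((params.n_steps, topology.n_atoms, 3))
    labels = np.empty(params.n_steps, dtype=int)
    for i in range(params.n_steps):
        if rng.random() < switch_prob:
            state = int(rng.choice(len(anchors), p=weights))
        anchor = anchors[state]
        x = x - relax * (x - anchor)
        if noise_scale > 0:
            x = x + noise_scale * rng.standard_normal(x.shape)
        frames[i] = x
        labels[i] = state + 1
    return Trajectory(coordinates=frames), labels
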