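"""Structure/trajectory containers, I/O, and deviation metrics.

Implements the standard deviation measures of protein MD post-analysis:

* **cRMSD** — per-frame coordinate RMSD of a selection (backbone
  N/Cα/C by default) after optimal rigid-body superposition onto a
  reference.
* **dRMSD** — superposition-free RMSD over all unique internal pair
  distances of a selection relative to the reference, the conventional
  measure of ligand conformational displacement.
* **RMSF** — per-residue root-mean-square fluctuation about the
  time-average structure after aligning every frame to that average.
* **Interdomain distances** — per-frame mass-weighted centre-of-mass
  distances between named residue regions (six pairs for the four
  CYP3A4 mobile regions: substrate-core residues, Phe cluster, β
  domain, B–B' loop/B' helix).

Coordinates are Å throughout; residue numbering is 1-based with
inclusive ranges.  Structures are exchanged as PDB (with a JSON sidecar
carrying charges and Lennard-Jones parameters, which PDB cannot hold),
trajectories as multi-frame XYZ or CHARMM/X-PLOR DCD via MDAnalysis.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "Topology",
    "Trajectory",
    "SuperpositionResult",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "kabsch_superpose",
    "c_rmsd",
    "d_rmsd",
    "rmsf",
    "interdomain_features",
    "summarize_interdomain_by_state",
    "BACKBONE_NAMES",
]

BACKBONE_NAMES = ("N", "CA", "C")


@dataclass
class Topology:
    """Per-atom metadata plus named residue regions.

    ``regions`` maps a region name to a list of inclusive 1-based
    ``(start, end)`` residue-index ranges.
    """

    names: list[str]
    resids: np.ndarray  # 1-based, non-decreasing
    resnames: list[str]
    charges: np.ndarray  # e
    lj_sigma: np.ndarray  # Å
    lj_epsilon: np.ndarray  # kcal/mol
    masses: np.ndarray  # amu
    is_ligand: np.ndarray  # bool
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.resids = np.asarray(self.resids, dtype=int)
        if np.any(np.diff(self.resids) < 0):
            raise ValueError("residue indices must be non-decreasing")
        n = len(self.names)
        for arr_name in ("charges", "lj_sigma", "lj_epsilon", "masses"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            setattr(self, arr_name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{arr_name} must have one entry per atom")
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        max_resid = int(self.resids.max()) if n else 0
        for region, ranges in self.regions.items():
            for start, end in ranges:
                if not 1 <= start <= end <= max_resid:
                    raise ValueError(
                        f"region {region!r} range ({start}, {end}) outside "
                        f"residue bounds 1..{max_resid}"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resids))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def select_names(self, names=BACKBONE_NAMES, protein_only: bool = True):
        """Indices of atoms whose names are in ``names`` (backbone default)."""
        mask = np.isin(np.asarray(self.names), list(names))
        if protein_only:
            mask &= ~self.is_ligand
        return np.flatnonzero(mask)

    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_ligand)

    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_ligand)

    def heavy_indices(self, subset: np.ndarray | None = None) -> np.ndarray:
        """Atoms that are not hydrogens (name does not start with 'H')."""
        mask = np.array([not nm.startswith("H") for nm in self.names])
        idx = np.flatnonzero(mask)
        if subset is not None:
            idx = np.intersect1d(idx, subset)
        return idx

    def region_indices(self, region: str) -> np.ndarray:
        """Atom indices belonging to a named residue-range region."""
        if region not in self.regions:
            raise KeyError(f"region {region!r} not defined in topology")
        mask = np.zeros(self.n_atoms, dtype=bool)
        for start, end in self.regions[region]:
            mask |= (self.resids >= start) & (self.resids <= end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(f"region {region!r} selects no atoms")
        return idx


@dataclass
class Trajectory:
    """Stack of coordinate frames (Å), constant atom count."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd_after: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_structure(
    path: str | Path, topology: Topology, coordinates: np.ndarray
) -> None:
    """Write a PDB plus a JSON sidecar with charges/LJ/region metadata."""
    import MDAnalysis as mda

    path = Path(path)
    coordinates = np.asarray(coordinates, dtype=float)
    n = topology.n_atoms
    resids_unique, res_inverse = np.unique(topology.resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(resids_unique),
        atom_resindex=res_inverse,
        trajectory=True,
    )
    u.add_TopologyAttr("names", topology.names)
    u.add_TopologyAttr("resids", resids_unique)
    resname_per_res = [""] * len(resids_unique)
    for atom_i, res_i in enumerate(res_inverse):
        resname_per_res[res_i] = topology.resnames[atom_i][:4] or "UNK"
    u.add_TopologyAttr("resnames", resname_per_res)
    u.add_TopologyAttr("elements", [""] * n)
    u.atoms.positions = coordinates
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    sidecar = {
        "charges_e": topology.charges.tolist(),
        "lj_sigma_A": topology.lj_sigma.tolist(),
        "lj_epsilon_kcal": topology.lj_epsilon.tolist(),
        "masses_amu": topology.masses.tolist(),
        "is_ligand": topology.is_ligand.astype(int).tolist(),
        "regions": {k: [list(r) for r in v] for k, v in topology.regions.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_structure(path: str | Path) -> tuple[Topology, np.ndarray]:
    """Read a PDB structure (file order preserved, 1-based resids kept).

    A ``<name>.pdb.json`` sidecar, when present, supplies charges,
    Lennard-Jones parameters, masses, ligand flags and region
    definitions; otherwise neutral unit-mass atoms are assumed.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        line_no = _first_bad_pdb_line(path)
        hint = f" (first malformed record at line {line_no})" if line_no else ""
        raise ValueError(f"{path}: cannot parse PDB{hint}: {exc}") from exc
    n = len(u.atoms)
    if n == 0:
        raise ValueError(f"{path}: no atoms found")
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sc = json.loads(sidecar_file.read_text())
        charges = np.asarray(sc["charges_e"], dtype=float)
        lj_sigma = np.asarray(sc["lj_sigma_A"], dtype=float)
        lj_epsilon = np.asarray(sc["lj_epsilon_kcal"], dtype=float)
        masses = np.asarray(sc["masses_amu"], dtype=float)
        is_ligand = np.asarray(sc["is_ligand"], dtype=bool)
        regions = {
            k: [tuple(r) for r in v] for k, v in sc.get("regions", {}).items()
        }
    else:
        charges = np.zeros(n)
        lj_sigma = np.zeros(n)
        lj_epsilon = np.zeros(n)
        masses = np.ones(n)
        is_ligand = np.zeros(n, dtype=bool)
        regions = {}
    topology = Topology(
        names=[a.name for a in u.atoms],
        resids=u.atoms.resids,
        resnames=[a.resname for a in u.atoms],
        charges=charges,
        lj_sigma=lj_sigma,
        lj_epsilon=lj_epsilon,
        masses=masses,
        is_ligand=is_ligand,
        regions=regions,
    )
    return topology, u.atoms.positions.astype(float).copy()


def _first_bad_pdb_line(path: Path) -> int | None:
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip()) < 54:
            return i
    return None


def write_trajectory(
    path: str | Path, trajectory: Trajectory, names: list[str] | None = None
) -> None:
    """Write a trajectory as multi-frame XYZ (Å) or DCD, by extension."""
    import MDAnalysis as mda

    path = Path(path)
    n_atoms = trajectory.n_atoms
    u = mda.Universe.empty(n_atoms=n_atoms, trajectory=True)
    u.add_TopologyAttr("names", names or ["X"] * n_atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n_atoms) as w:
            for frame in trajectory.coordinates:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_trajectory(path: str | Path, n_atoms: int | None = None) -> Trajectory:
    """Read a multi-frame XYZ or DCD trajectory into memory.

    DCD is assumed little-endian CHARMM/X-PLOR dialect (the MDAnalysis
    reader); other dialects fail with the reader's diagnostic.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XYZ import XYZReader

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    reader_cls = {".xyz": XYZReader, ".dcd": DCDReader}.get(suffix)
    if reader_cls is None:
        raise ValueError(f"unsupported trajectory format: {suffix}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = reader_cls(str(path))
            frames = np.array([ts.positions.copy() for ts in reader])
    except Exception as exc:
        raise ValueError(
            f"{path}: cannot read {suffix} trajectory "
            f"(DCD must be little-endian CHARMM/X-PLOR): {exc}"
        ) from exc
    if n_atoms is not None and frames.shape[1] != n_atoms:
        raise ValueError(
            f"{path}: trajectory has {frames.shape[1]} atoms, expected {n_atoms}"
        )
    return Trajectory(coordinates=frames)


# ---------------------------------------------------------------------------
# Superposition and deviation metrics


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    The transform is fitted on ``selection`` (all atoms when None);
    ``rmsd_after`` is the RMSD over the selection after the fit.
    Requires at least 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    x = mobile[selection]
    y = reference[selection]
    if x.shape != y.shape:
        raise ValueError("selection shapes differ between mobile and reference")
    if x.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # Collinearity check: rank of the centered point cloud.
    if np.linalg.matrix_rank(xc, tol=1e-9) < 2:
        raise ValueError("selection points are collinear")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - rot @ x.mean(axis=0)
    fitted = x @ rot.T + trans
    rmsd_after = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans,
                               rmsd_after=rmsd_after)


def c_rmsd(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray,
) -> np.ndarray:
    """Per-frame coordinate RMSD (Å) after optimal superposition.

    Each frame is superposed onto the reference on ``selection`` and the
    RMSD is taken over the same selection.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection for cRMSD")
    out = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.coordinates):
        out[i] = kabsch_superpose(frame, reference, selection).rmsd_after
    return out


def d_rmsd(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray,
) -> np.ndarray:
    """Per-frame distance RMSD (Å): RMS difference over all unique
    intra-selection pair distances versus the reference.  No
    superposition is performed (internal distances are rigid-invariant).
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 2:
        raise ValueError("dRMSD needs at least 2 atoms in the selection")
    ref_d = pdist(np.asarray(reference, dtype=float)[selection])
    out = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.coordinates):
        out[i] = np.sqrt(np.mean((pdist(frame[selection]) - ref_d) ** 2))
    return out


def rmsf(
    trajectory: Trajectory,
    topology: Topology,
    selection: np.ndarray | None = None,
    align: bool = True,
) -> tuple[pd.DataFrame, float, float]:
    """Per-residue RMSF (Å) about the time-average structure.

    With ``align=True`` (default) every frame is first superposed onto
    the iteratively refined average structure over the selection.
    Per-atom fluctuations are averaged within each residue; the grand
    mean ± std across residues is the "average mobility" summary.

    Returns
    -------
    (table, grand_mean, grand_std)
        ``table`` has columns ``resid`` and ``rmsf_A``.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    if selection is None:
        selection = np.arange(trajectory.n_atoms)
    selection = np.asarray(selection, dtype=int)
    coords = trajectory.coordinates[:, selection, :]
    if align:
        # Two-pass alignment to the mean structure (converges quickly
        # for the harmonic fluctuations this package analyses).
        mean = coords.mean(axis=0)
        for _ in range(2):
            aligned = np.empty_like(coords)
            for i, frame in enumerate(coords):
                res = kabsch_superpose(frame, mean)
                aligned[i] = res.apply(frame)
            mean = aligned.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    resids = topology.resids[selection]
    table = (
        pd.DataFrame({"resid": resids, "rmsf_A": per_atom})
        .groupby("resid", as_index=False)
        .mean()
    )
    grand_mean = float(table["rmsf_A"].mean())
    grand_std = float(table["rmsf_A"].std(ddof=0))
    return table, grand_mean, grand_std


def interdomain_features(
    trajectory: Trajectory,
    topology: Topology,
    regions: list[str],
) -> pd.DataFrame:
    """Per-frame mass-weighted COM distances between the 6 pairs of 4 regions.

    Columns are named ``"<A>--<B>"`` in the fixed order produced by
    ``itertools.combinations`` over the region list.
    """
    if len(regions) != 4:
        raise ValueError("exactly 4 named regions are required")
    idx = {r: topology.region_indices(r) for r in regions}
    masses = topology.masses
    cols = {}
    for a, b in itertools.combinations(regions, 2):
        com_a = _com_series(trajectory, idx[a], masses)
        com_b = _com_series(trajectory, idx[b], masses)
        cols[f"{a}--{b}"] = np.linalg.norm(com_a - com_b, axis=1)
    return pd.DataFrame(cols)


def _com_series(
    trajectory: Trajectory, atom_idx: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    m = masses[atom_idx]
    if np.all(m == 0):
        m = np.ones_like(m)
    w = m / m.sum()
    return np.einsum("fad,a->fd", trajectory.coordinates[:, atom_idx, :], w)


def summarize_interdomain_by_state(
    features: pd.DataFrame,
    labels: np.ndarray,
    pairs: list[str],
) -> pd.DataFrame:
    """Per-state mean ± std for selected distance pairs plus a total row.

    The ``total_average`` for a state is the mean of the selected pair
    means; its ± is the population standard deviation over those pair
    means.  Frames with label < 1 (unassigned) are ignored; states with
    zero member frames are omitted with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels must align with feature frames")
    if len(pairs) != 3:
        raise ValueError("exactly 3 distance pairs are summarized")
    rows = []
    for state in sorted(set(labels[labels >= 1])):
        member = features.loc[labels == state, pairs]
        if member.empty:
            warnings.warn(f"state {state} has no frames; omitted", stacklevel=2)
            continue
        row: dict = {"state": int(state), "n_frames": len(member)}
        means = []
        for p in pairs:
            row[f"{p}_mean"] = member[p].mean()
            row[f"{p}_std"] = member[p].std(ddof=0)
            means.append(member[p].mean())
        means = np.array(means)
        row["total_average"] = means.mean()
        row["total_std"] = means.std(ddof=0)
        rows.append(row)
    return pd.DataFrame(rows)
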