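"""Superposition, cRMSD/dRMSD/RMSF, interdomain distances, and I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cypdyn.refdata import INTERDOMAIN_STATE_MEANS
from cypdyn.traj import (
    Topology,
    Trajectory,
    c_rmsd,
    d_rmsd,
    interdomain_features,
    kabsch_superpose,
    read_structure,
    read_trajectory,
    rmsf,
    summarize_interdomain_by_state,
    write_structure,
    write_trajectory,
)


def brute_force_min_rmsd(mobile, reference):
    """Oracle: minimize RMSD over Euler-angle rotations numerically."""
    xc = mobile - mobile.mean(axis=0)
    yc = reference - reference.mean(axis=0)

    def cost(angles):
        r = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((xc @ r.T - yc) ** 2, axis=1)))

    best = np.inf
    for start in np.random.default_rng(0).uniform(-np.pi, np.pi, (20, 3)):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


def simple_topology(n_res, atoms_per_res=1, regions=None):
    n = n_res * atoms_per_res
    return Topology(
        names=["CA"] * n,
        resids=np.repeat(np.arange(1, n_res + 1), atoms_per_res),
        resnames=["GLY"] * n,
        charges=np.zeros(n),
        lj_sigma=np.zeros(n),
        lj_epsilon=np.zeros(n),
        masses=np.ones(n),
        is_ligand=np.zeros(n, dtype=bool),
        regions=regions or {},
    )


class TestKabsch:
    def test_identity_on_self(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(res.translation, 0, atol=1e-10)
        assert res.rmsd_after == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_recovered(self):
        pts = np.random.default_rng(2).normal(size=(8, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + [3.0, -1.0, 2.0]
        res = kabsch_superpose(moved, pts)
        assert res.rmsd_after == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for n_pts in (4, 5, 6):
            ref = rng.normal(size=(n_pts, 3))
            mobile = ref + rng.normal(scale=0.3, size=ref.shape)
            res = kabsch_superpose(mobile, ref)
            oracle = brute_force_min_rmsd(mobile, ref)
            assert res.rmsd_after == pytest.approx(oracle, abs=1e-6)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                        dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestCRmsd:
    def test_copies_of_reference_give_zero(self):
        ref = np.random.default_rng(4).normal(size=(6, 3))
        traj = Trajectory(np.stack([ref] * 5))
        sel = np.arange(6)
        assert np.allclose(c_rmsd(traj, ref, sel), 0.0, atol=1e-10)

    def test_uniform_displacement_removed_by_superposition(self):
        ref = np.random.default_rng(5).normal(size=(6, 3))
        traj = Trajectory((ref + [1.0, 0, 0])[None])
        assert c_rmsd(traj, ref, np.arange(6))[0] == pytest.approx(0, abs=1e-9)

    def test_matches_superposition_oracle(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(size=(5, 3))
        frame = ref + rng.normal(scale=0.5, size=ref.shape)
        value = c_rmsd(Trajectory(frame[None]), ref, np.arange(5))[0]
        assert value == pytest.approx(brute_force_min_rmsd(frame, ref),
                                      abs=1e-6)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(8, 3))
        frames = ref[None] + rng.normal(scale=0.3, size=(4, 8, 3))
        base = c_rmsd(Trajectory(frames), ref, np.arange(8))
        rot = Rotation.random(random_state=np.random.RandomState(0)).as_matrix()
        moved = frames @ rot.T + np.array([5.0, -2.0, 1.0])
        assert np.allclose(
            c_rmsd(Trajectory(moved), ref, np.arange(8)), base, atol=1e-8
        )

    def test_empty_selection_rejected(self):
        ref = np.zeros((4, 3))
        with pytest.raises(ValueError, match="empty"):
            c_rmsd(Trajectory(ref[None]), ref, np.array([], dtype=int))


class TestDRmsd:
    def test_rigid_copy_is_exactly_zero(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(6, 3))
        rot = Rotation.random(random_state=np.random.RandomState(1)).as_matrix()
        moved = ref @ rot.T + [10.0, 0, 0]
        val = d_rmsd(Trajectory(moved[None]), ref, np.arange(6))[0]
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_dilated_triangle_hand_value(self):
        """2× dilation of a unit triangle grows every pair by 1 Å."""
        tri = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        val = d_rmsd(Trajectory((2 * tri)[None]), tri, np.arange(3))[0]
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_singleton_selection_rejected(self):
        ref = np.zeros((3, 3))
        with pytest.raises(ValueError, match="2 atoms"):
            d_rmsd(Trajectory(ref[None]), ref, np.array([0]))


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        topo = simple_topology(5)
        ref = np.random.default_rng(9).normal(size=(5, 3)) * 4
        traj = Trajectory(np.stack([ref] * 10))
        table, mean, std = rmsf(traj, topo)
        assert np.allclose(table["rmsf_A"], 0.0, atol=1e-10)
        assert mean == pytest.approx(0.0, abs=1e-10)

    def test_oscillating_atom_definition(self):
        """±1 Å square-wave oscillation along x gives RMSF exactly 1."""
        topo = simple_topology(4)
        base = np.array(
            [[0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float
        )
        frames = []
        for i in range(20):
            f = base.copy()
            f[0, 0] += 1.0 if i % 2 == 0 else -1.0
            frames.append(f)
        table, mean, _ = rmsf(Trajectory(np.array(frames)), topo, align=False)
        assert table.loc[table["resid"] == 1, "rmsf_A"].item() == \
            pytest.approx(1.0)
        assert np.allclose(table["rmsf_A"].iloc[1:], 0.0, atol=1e-10)
        assert mean == pytest.approx(table["rmsf_A"].mean())

    def test_single_frame_rejected(self):
        topo = simple_topology(3)
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(Trajectory(np.zeros((1, 3, 3))), topo)


class TestInterdomain:
    def test_point_mass_regions_distance(self):
        regions = {"a": [(1, 1)], "b": [(2, 2)], "c": [(3, 3)], "d": [(4, 4)]}
        topo = simple_topology(4, regions=regions)
        coords = np.array(
            [[0, 0, 0], [5, 0, 0], [0, 12, 0], [0, 0, 9]], dtype=float
        )
        feats = interdomain_features(Trajectory(coords[None]), topo,
                                     ["a", "b", "c", "d"])
        assert feats.shape == (1, 6)
        assert feats["a--b"].iloc[0] == pytest.approx(5.0)
        assert feats["a--c"].iloc[0] == pytest.approx(12.0)
        assert feats["a--d"].iloc[0] == pytest.approx(9.0)

    def test_duplicated_region_zero_distance(self):
        regions = {"a": [(1, 2)], "a2": [(1, 2)], "b": [(3, 3)],
                   "c": [(4, 4)]}
        topo = simple_topology(4, regions=regions)
        coords = np.random.default_rng(10).normal(size=(4, 3))
        feats = interdomain_features(Trajectory(coords[None]), topo,
                                     ["a", "a2", "b", "c"])
        assert feats["a--a2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_mass_weighted_com(self):
        """Two 2-atom regions with unequal masses: hand-computed COM."""
        regions = {"a": [(1, 2)], "b": [(3, 4)], "c": [(5, 5)],
                   "d": [(6, 6)]}
        topo = simple_topology(6, regions=regions)
        topo.masses = np.array([1.0, 3.0, 2.0, 2.0, 1.0, 1.0])
        coords = np.array(
            [[0, 0, 0], [4, 0, 0], [10, 0, 0], [12, 0, 0],
             [0, 20, 0], [0, 0, 30]], dtype=float
        )
        feats = interdomain_features(Trajectory(coords[None]), topo,
                                     ["a", "b", "c", "d"])
        # COM(a) = (0·1 + 4·3)/4 = 3; COM(b) = 11 → distance 8.
        assert feats["a--b"].iloc[0] == pytest.approx(8.0)

    def test_requires_four_regions(self):
        topo = simple_topology(4, regions={"a": [(1, 4)]})
        with pytest.raises(ValueError, match="4 named regions"):
            interdomain_features(Trajectory(np.zeros((1, 4, 3))), topo, ["a"])


class TestStateSummary:
    def _features_from_reference(self):
        """One frame per state carrying the tabulated pair means."""
        pairs = ["core-bb", "bb-beta", "core-beta"]
        rows, labels = [], []
        for i, (state, means) in enumerate(INTERDOMAIN_STATE_MEANS.items(),
                                           start=1):
            rows.append([means[p] for p in pairs])
            labels.append(i)
        return pd.DataFrame(rows, columns=pairs), np.array(labels), pairs

    def test_reference_total_averages(self):
        """Closed-state S1 totals 20.5 Å, open-state S5 totals 22.4 Å."""
        feats, labels, pairs = self._features_from_reference()
        out = summarize_interdomain_by_state(feats, labels, pairs)
        totals = dict(zip(out["state"], out["total_average"]))
        assert round(totals[1], 1) == 20.5
        assert round(totals[5], 1) == 22.4

    def test_identical_frames_zero_std(self):
        pairs = ["p1", "p2", "p3"]
        feats = pd.DataFrame([[1.0, 2.0, 3.0]] * 6, columns=pairs)
        out = summarize_interdomain_by_state(
            feats, np.ones(6, dtype=int), pairs
        )
        assert np.allclose(out[["p1_std", "p2_std", "p3_std"]], 0.0)
        assert out["total_average"].iloc[0] == pytest.approx(2.0)

    def test_unassigned_frames_ignored(self):
        pairs = ["p1", "p2", "p3"]
        feats = pd.DataFrame([[1, 1, 1], [9, 9, 9]], columns=pairs,
                             dtype=float)
        out = summarize_interdomain_by_state(
            feats, np.array([0, 1]), pairs
        )
        assert len(out) == 1
        assert out["total_average"].iloc[0] == pytest.approx(9.0)


class TestStructureIO:
    def test_pdb_round_trip(self, toy_complex, tmp_path):
        topology, coords = toy_complex
        path = tmp_path / "complex.pdb"
        write_structure(path, topology, coords)
        topo2, coords2 = read_structure(path)
        assert topo2.n_atoms == topology.n_atoms
        assert np.allclose(coords2, coords, atol=1e-3)  # PDB precision
        assert np.allclose(topo2.charges, topology.charges)
        assert np.array_equal(topo2.is_ligand, topology.is_ligand)
        assert topo2.regions == topology.regions

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_structure(path)

    def test_toy_complex_counts(self, toy_complex, tmp_path):
        topology, coords = toy_complex
        path = tmp_path / "c.pdb"
        write_structure(path, topology, coords)
        topo2, _ = read_structure(path)
        assert topo2.n_residues == 21

    def test_xyz_trajectory_round_trip(self, toy_trajectory, tmp_path):
        traj, _ = toy_trajectory
        short = Trajectory(traj.coordinates[:5])
        path = tmp_path / "t.xyz"
        write_trajectory(path, short)
        back = read_trajectory(path)
        assert back.n_frames == 5
        assert np.allclose(back.coordinates, short.coordinates, atol=1e-4)

    def test_dcd_trajectory_round_trip(self, toy_trajectory, tmp_path):
        traj, _ = toy_trajectory
        short = Trajectory(traj.coordinates[:5])
        path = tmp_path / "t.dcd"
        write_trajectory(path, short)
        back = read_trajectory(path, n_atoms=short.n_atoms)
        assert back.n_frames == 5
        assert np.allclose(back.coordinates, short.coordinates, atol=1e-4)
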