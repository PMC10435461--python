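"""GMM fitting, free-energy surfaces, inflection core states, populations."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cypdyn.constants import kbt
from cypdyn.refdata import STATE_PERCENTAGES
from cypdyn.states import (
    GMMParams,
    extract_core_states,
    free_energy_surface,
    gmm_fit,
    order_states_by_energy,
    state_populations,
)


def two_component_sample(n=5000, w=(0.7, 0.3), seed=0):
    rng = np.random.default_rng(seed)
    n1 = rng.binomial(n, w[0])
    a = rng.normal(loc=[0.0, 0.0], scale=0.5, size=(n1, 2))
    b = rng.normal(loc=[5.0, 5.0], scale=0.5, size=(n - n1, 2))
    return np.vstack([a, b])


class TestGmmFit:
    def test_weight_recovery_two_components(self):
        """Weights (0.7, 0.3) recovered within ±0.05 from 5000 samples."""
        x = two_component_sample()
        model = gmm_fit(x, k_range=[2], seed=1)
        w = np.sort(model.weights)[::-1]
        assert abs(w[0] - 0.7) <= 0.05
        assert abs(w[1] - 0.3) <= 0.05
        means = model.means[np.argsort(model.weights)[::-1]]
        assert np.linalg.norm(means[0] - [0, 0]) < 0.1
        assert np.linalg.norm(means[1] - [5, 5]) < 0.1

    def test_single_gaussian_selects_k1(self):
        rng = np.random.default_rng(2)
        x = rng.normal(loc=[1.0, -1.0], scale=0.3, size=(2000, 2))
        model = gmm_fit(x, k_range=[1, 2, 3], seed=3)
        assert model.n_components == 1
        se = 0.3 / np.sqrt(2000)
        assert np.all(np.abs(model.means[0] - [1.0, -1.0]) < 3 * se)

    def test_bic_selects_true_k(self):
        x = two_component_sample(seed=4)
        model = gmm_fit(x, k_range=range(1, 5), seed=4)
        assert model.n_components == 2
        assert set(model.bic_by_k) == {1, 2, 3, 4}

    def test_seed_determinism_bitwise(self):
        x = two_component_sample(seed=5)
        m1 = gmm_fit(x, k_range=[2, 3], seed=9)
        m2 = gmm_fit(x, k_range=[2, 3], seed=9)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.means, m2.means)
        assert np.array_equal(m1.covariances, m2.covariances)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            gmm_fit(np.zeros((10, 2)), k_range=[2], seed=0)


def isotropic_model(d=2):
    return GMMParams(
        weights=np.array([1.0]),
        means=np.zeros((1, d)),
        covariances=np.eye(d)[None],
    )


class TestFreeEnergySurface:
    def test_gaussian_closed_form_energy_difference(self):
        """1-D standard Gaussian: G(1σ) − G(0) = k_B·T/2 ≈ 0.298 kcal/mol."""
        model = isotropic_model(d=1)
        surf = free_energy_surface(
            model, grid_axes=[np.array([0.0, 1.0])], temperature=300.0
        )
        diff = surf.g_values[1] - surf.g_values[0]
        assert diff == pytest.approx(kbt(300.0) / 2, abs=1e-9)
        assert diff == pytest.approx(0.298, abs=1e-3)

    def test_symmetric_mixture_two_equal_minima(self):
        model = GMMParams(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-2.0, 0.0], [2.0, 0.0]]),
            covariances=np.stack([np.eye(2) * 0.25] * 2),
        )
        xs = np.linspace(-4, 4, 81)
        surf = free_energy_surface(
            model, grid_axes=[xs, np.array([0.0])], temperature=300.0
        )
        g = surf.g_values[:, 0]
        assert np.allclose(g, g[::-1], atol=1e-9)
        minima = xs[np.isclose(g, 0.0, atol=1e-9)]
        assert len(minima) == 2
        assert sorted(np.round(minima, 6)) == [-2.0, 2.0]

    def test_argmin_at_mode(self):
        model = isotropic_model(d=2)
        surf = free_energy_surface(model, n_grid=41, temperature=300.0)
        ij = np.unravel_index(np.argmin(surf.g_values), surf.g_values.shape)
        mode = np.array([surf.grid_axes[0][ij[0]], surf.grid_axes[1][ij[1]]])
        cell = surf.grid_axes[0][1] - surf.grid_axes[0][0]
        assert np.all(np.abs(mode) <= cell + 1e-12)

    def test_monotone_in_density(self):
        model = isotropic_model(d=2)
        surf = free_energy_surface(model, n_grid=31, temperature=300.0)
        pts_x, pts_y = np.meshgrid(*surf.grid_axes, indexing="ij")
        rho = model.density(np.column_stack([pts_x.ravel(), pts_y.ravel()]))
        g = surf.g_values.ravel()
        order = np.argsort(rho)
        assert np.all(np.diff(g[order]) <= 1e-9)

    def test_misplaced_grid_rejected(self):
        model = isotropic_model(d=2)
        with pytest.raises(ValueError, match="grid"):
            free_energy_surface(
                model,
                grid_axes=[np.array([1e6, 2e6]), np.array([1e6, 2e6])],
            )


class TestCoreStates:
    def test_single_gaussian_core_fraction(self):
        """Core mass of an isotropic 2-D Gaussian is the χ² mass inside
        the unit Mahalanobis radius, ≈ 39.3%."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(40000, 2))
        model = isotropic_model(d=2)
        assignment = extract_core_states(model, x)
        frac = (assignment.labels == 1).mean()
        expected = 1 - np.exp(-0.5)  # 0.3935
        assert frac == pytest.approx(expected, abs=0.02)

    def test_no_cross_assignment_for_separated_components(self):
        rng = np.random.default_rng(7)
        a = rng.normal(loc=[0, 0], scale=0.5, size=(2000, 2))
        b = rng.normal(loc=[8, 8], scale=0.5, size=(1000, 2))
        x = np.vstack([a, b])
        model = GMMParams(
            weights=np.array([2 / 3, 1 / 3]),
            means=np.array([[0.0, 0.0], [8.0, 8.0]]),
            covariances=np.stack([np.eye(2) * 0.25] * 2),
        )
        assignment = extract_core_states(model, x)
        labels_a = assignment.labels[:2000]
        labels_b = assignment.labels[2000:]
        assert np.all(np.isin(labels_a, [0, 1]))
        assert np.all(np.isin(labels_b, [0, 2]))

    def test_max_threshold_assigns_nothing(self):
        x = np.random.default_rng(8).normal(size=(500, 2))
        model = isotropic_model(d=2)
        assignment = extract_core_states(model, x)
        assignment.thresholds[:] = assignment.densities.max() * 1.01
        labels = np.where(
            assignment.densities >= assignment.thresholds[0], 1, 0
        )
        assert np.all(labels == 0)

    def test_assigned_frames_meet_threshold(self):
        x = two_component_sample(seed=9)
        model = gmm_fit(x, k_range=[2], seed=9)
        assignment = extract_core_states(model, x)
        for k in range(model.n_components):
            member = assignment.labels == k + 1
            assert np.all(
                assignment.densities[member] >= assignment.thresholds[k]
            )


class TestPopulations:
    def test_apo_reference_row_total(self):
        """Tabulated apo-state percentages total 34.7%."""
        labels = _labels_from_percent(STATE_PERCENTAGES["CYP3A4"])
        pops = state_populations(labels, n_states=5)
        assert pops.total == pytest.approx(34.7, abs=1e-9)
        assert np.allclose(pops.percent, STATE_PERCENTAGES["CYP3A4"])

    def test_nickel_bound_reference_row_total(self):
        labels = _labels_from_percent(STATE_PERCENTAGES["CYP3A4-1"])
        pops = state_populations(labels, n_states=6)
        assert pops.total == pytest.approx(37.5, abs=1e-9)

    def test_all_unassigned_gives_zeros(self):
        pops = state_populations(np.zeros(100, dtype=int), n_states=3)
        assert np.all(pops.percent == 0.0)
        assert pops.total == 0.0

    def test_recovery_from_synthetic_trajectory(self, toy_complex):
        """Hard-assignment populations recover anchor weights (0.5, 0.3,
        0.2) within ±0.05; core populations are strictly smaller."""
        from cypdyn.reduce import backbone_coordinate_features, \
            pca_fit_transform
        from cypdyn.synthetic import LangevinParams, simulate_toy_trajectory

        topology, reference = toy_complex
        mobile = np.concatenate([
            topology.region_indices("beta"),
            topology.region_indices("bb_loop"),
        ])
        anchors = [reference]
        for direction in ([3.0, 0, 0], [0, 3.0, 0]):
            a = reference.copy()
            a[mobile] += np.asarray(direction, dtype=float)
            anchors.append(a)
        weights = (0.5, 0.3, 0.2)
        traj, true_labels = simulate_toy_trajectory(
            topology, anchors, weights,
            LangevinParams(dt=0.1, n_steps=5000, seed=21),
            switch_prob=0.05,
        )
        feats = backbone_coordinate_features(
            traj, reference, topology.select_names()
        )
        _, pcs = pca_fit_transform(feats, k=2)
        model = gmm_fit(pcs, k_range=[3], seed=21)
        resp = model.responsibilities(pcs)
        hard = np.argmax(resp, axis=1)
        # Match fitted components to true states by majority vote.
        hard_pop = np.array([np.mean(hard == k) for k in range(3)])
        assert np.all(np.abs(np.sort(hard_pop) - np.sort(weights)) <= 0.05)
        assignment = extract_core_states(model, pcs)
        core_pop = np.array(
            [np.mean(assignment.labels == k + 1) for k in range(3)]
        )
        assert np.all(core_pop < hard_pop)


def _labels_from_percent(percents):
    """Build a label vector of 1000 frames realizing exact percentages."""
    labels = []
    for state, p in enumerate(percents, start=1):
        labels += [state] * int(round(p * 10))
    labels += [0] * (1000 - len(labels))
    return np.array(labels)


class TestOrdering:
    def test_weight_ordering_equal_covariances(self):
        model = GMMParams(
            weights=np.array([0.2, 0.5, 0.3]),
            means=np.array([[0.0, 0], [10.0, 0], [20.0, 0]]),
            covariances=np.stack([np.eye(2)] * 3),
        )
        pops = state_populations(np.array([2] * 5 + [3] * 3 + [1] * 2),
                                 n_states=3)
        # Density at mode ∝ weight: state 2 (w=0.5) first, then 3, then 1.
        assert order_states_by_energy(model, pops) == [2, 3, 1]

    def test_tie_broken_by_population_then_index(self):
        model = GMMParams(
            weights=np.array([1 / 3, 1 / 3, 1 / 3]),
            means=np.array([[0.0, 0], [10.0, 0], [20.0, 0]]),
            covariances=np.stack([np.eye(2)] * 3),
        )
        pops = state_populations(np.array([2] * 6 + [1] * 3 + [3] * 3),
                                 n_states=3)
        assert order_states_by_energy(model, pops) == [2, 1, 3]

    def test_singleton_path(self):
        model = isotropic_model(d=2)
        pops = state_populations(np.ones(10, dtype=int), n_states=1)
        assert order_states_by_energy(model, pops) == [1]
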