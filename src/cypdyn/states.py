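"""Gaussian-mixture free-energy landscapes and core-state clustering.

The density of projected trajectory frames x ∈ ℝ^d is modelled with a
Gaussian mixture ρ(x) = Σ aₖ N(x; μₖ, Σₖ); the free-energy landscape is

    G(x) = -k_B·T·log ρ(x)

shifted so the global minimum on the evaluation grid is 0.  Metastable
conformations are the *cores* of the mixture components: for each
component the density profile along its Mahalanobis radius has an
inflection (at radius 1 for a pure Gaussian); the mixture density at
that inflection is the component's core threshold.  A frame belongs to
state k iff its posterior responsibility for k exceeds ½ *and* the
mixture density at the frame is at least k's threshold — frames in the
low-density shoulders stay unassigned, which is why state populations
sum to well under 100%.

Model order is selected by BIC over a candidate range, with seeded
k-means++-style restarts (scikit-learn's EM underneath).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture

from .constants import kbt

__all__ = [
    "GMMParams",
    "FreeEnergySurface",
    "StateAssignment",
    "StatePopulations",
    "gmm_fit",
    "free_energy_surface",
    "extract_core_states",
    "state_populations",
    "order_states_by_energy",
]

logger = logging.getLogger(__name__)

#: Densities below this floor are treated as unsampled before the log.
DENSITY_FLOOR = 1e-12


@dataclass
class GMMParams:
    """Fitted Gaussian-mixture parameters plus selection metadata."""

    weights: np.ndarray  # (k,), sums to 1
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d), full SPD
    seed: int = 0
    restarts: int = 1
    bic_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.weights < 0):
            raise ValueError("mixture weights must be non-negative")
        for cov in self.covariances:
            np.linalg.cholesky(cov)  # SPD check

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def log_density(self, points: np.ndarray) -> np.ndarray:
        """log ρ(x) of the mixture at each point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        logs = np.empty((points.shape[0], self.n_components))
        for k in range(self.n_components):
            logs[:, k] = np.log(self.weights[k] + 1e-300) + multivariate_normal(
                self.means[k], self.covariances[k], allow_singular=False
            ).logpdf(points)
        return logsumexp(logs, axis=1)

    def density(self, points: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(points))

    def responsibilities(self, points: np.ndarray) -> np.ndarray:
        """Posterior p(component | x), shape (n_points, k)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        logs = np.empty((points.shape[0], self.n_components))
        for k in range(self.n_components):
            logs[:, k] = np.log(self.weights[k] + 1e-300) + multivariate_normal(
                self.means[k], self.covariances[k]
            ).logpdf(points)
        logs -= logsumexp(logs, axis=1, keepdims=True)
        return np.exp(logs)


@dataclass
class FreeEnergySurface:
    """G = -k_B T log ρ on a rectangular grid, global minimum at 0.

    Cells whose density fell below the floor are +inf and flagged in
    ``sampled``.
    """

    grid_axes: list[np.ndarray]
    g_values: np.ndarray  # kcal/mol, grid-shaped
    temperature: float
    sampled: np.ndarray  # bool mask, grid-shaped

    def __post_init__(self) -> None:
        finite = self.g_values[self.sampled]
        if finite.size and not np.isclose(finite.min(), 0.0, atol=1e-9):
            raise ValueError("surface must be shifted so min(G) = 0")


@dataclass
class StateAssignment:
    """Per-frame core-state labels: 1..k, or 0 for unassigned frames."""

    labels: np.ndarray  # (n_frames,), int
    thresholds: np.ndarray  # (k,), core density threshold per state
    densities: np.ndarray  # (n_frames,), mixture density at each frame

    @property
    def n_states(self) -> int:
        return len(self.thresholds)


@dataclass
class StatePopulations:
    """Percent of all frames inside each state core, plus the total."""

    percent: np.ndarray  # (k,)
    total: float

    def __post_init__(self) -> None:
        self.percent = np.asarray(self.percent, dtype=float)
        if np.any(self.percent < 0):
            raise ValueError("populations cannot be negative")
        if not np.isclose(self.total, self.percent.sum()):
            raise ValueError("total must equal the sum of state populations")
        if self.total > 100.0 + 1e-9:
            raise ValueError("total population cannot exceed 100%")


def gmm_fit(
    points,
    k_range=range(2, 9),
    restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GMMParams:
    """Fit a full-covariance Gaussian mixture; choose k by minimum BIC.

    For each candidate k, EM runs ``restarts`` times from seeded
    k-means++ initializations and the best restart (highest likelihood)
    is kept; across k the minimum-BIC model wins.  Singular-covariance
    collapse is guarded by a 1e-6 covariance floor.  Deterministic under
    ``seed``.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    k_range = [int(k) for k in k_range]
    if x.shape[0] < 10 * max(k_range):
        raise ValueError(
            f"need at least {10 * max(k_range)} frames for k_max="
            f"{max(k_range)}; got {x.shape[0]}"
        )
    best = None
    bic_by_k: dict[int, float] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            tol=tol,
            max_iter=max_iter,
            n_init=restarts,
            init_params="k-means++",
            reg_covar=1e-6,
            random_state=seed,
        )
        try:
            gm.fit(x)
        except ValueError as exc:  # EM collapse despite the floor
            logger.warning("GMM fit failed at k=%d: %s", k, exc)
            continue
        bic = gm.bic(x)
        bic_by_k[k] = float(bic)
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        raise RuntimeError("all GMM fits failed across the k range")
    gm = best[1]
    return GMMParams(
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        seed=seed,
        restarts=restarts,
        bic_by_k=bic_by_k,
    )


def free_energy_surface(
    model: GMMParams,
    grid_axes: list[np.ndarray] | None = None,
    temperature: float = 300.0,
    n_grid: int = 100,
    pad_fraction: float = 0.10,
    points: np.ndarray | None = None,
) -> FreeEnergySurface:
    """Evaluate G(x) = -k_B·T·log ρ(x) on a rectangular grid.

    When ``grid_axes`` is omitted the grid spans the data range
    (``points``, falling back to the component means ± 3σ) padded by
    ``pad_fraction``, with ``n_grid`` nodes per dimension.
    """
    d = model.n_dims
    if grid_axes is None:
        if points is not None:
            lo = np.min(points, axis=0)
            hi = np.max(points, axis=0)
        else:
            sig = np.sqrt(
                np.array([np.diag(c) for c in model.covariances])
            )
            lo = np.min(model.means - 3 * sig, axis=0)
            hi = np.max(model.means + 3 * sig, axis=0)
        span = hi - lo
        lo -= pad_fraction * span
        hi += pad_fraction * span
        grid_axes = [np.linspace(lo[i], hi[i], n_grid) for i in range(d)]
    mesh = np.meshgrid(*grid_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    rho = model.density(pts)
    sampled = rho >= DENSITY_FLOOR
    if not sampled.any():
        raise ValueError("zero density everywhere on the grid (grid misplaced)")
    kt = kbt(temperature)
    g = np.full(rho.shape, np.inf)
    g[sampled] = -kt * np.log(rho[sampled])
    g -= g[sampled].min()
    shape = tuple(len(ax) for ax in grid_axes)
    return FreeEnergySurface(
        grid_axes=list(grid_axes),
        g_values=g.reshape(shape),
        temperature=temperature,
        sampled=sampled.reshape(shape),
    )


def _inflection_radius(model: GMMParams, component: int) -> float | None:
    """Radius (in Mahalanobis units) of the second-derivative sign change
    of the mixture-density profile around a component's mean.

    The profile is the mixture density averaged over probe points on the
    component's Mahalanobis shells (along ± principal axes), evaluated
    on a fine radial grid; the first concave→convex sign change is
    returned, or None when no inflection exists in (0, 4].
    """
    mean = model.means[component]
    cov = model.covariances[component]
    evals, evecs = np.linalg.eigh(cov)
    radii = np.linspace(0.0, 4.0, 401)
    directions = []
    for j in range(len(evals)):
        axis = evecs[:, j] * np.sqrt(max(evals[j], 1e-300))
        directions.extend([axis, -axis])
    profile = np.zeros_like(radii)
    for direction in directions:
        probe = mean[None, :] + radii[:, None] * direction[None, :]
        profile += model.density(probe)
    profile /= len(directions)
    d2 = np.gradient(np.gradient(profile, radii), radii)
    # Skip the immediate neighbourhood of r=0 where the numerical second
    # derivative is noisy, then find the first -→+ crossing.
    for i in range(5, len(radii) - 1):
        if d2[i] < 0 <= d2[i + 1]:
            return float(radii[i + 1])
    return None


def extract_core_states(model: GMMParams, points) -> StateAssignment:
    """Assign frames to component cores delimited by density inflections.

    For each component the core threshold is the mixture density at the
    inflection of the radial density profile (falling back to the 60th
    density percentile of the component's members when no inflection is
    found).  A frame gets label k iff posterior(k) > 0.5 and its mixture
    density is at or above threshold k; otherwise it stays unassigned
    (label 0).
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    resp = model.responsibilities(x)
    dens = model.density(x)
    hard = np.argmax(resp, axis=1)
    thresholds = np.empty(model.n_components)
    for k in range(model.n_components):
        r_star = _inflection_radius(model, k)
        if r_star is None:
            members = dens[hard == k]
            if members.size == 0:
                thresholds[k] = np.inf
                continue
            logger.warning(
                "no density inflection for component %d; "
                "falling back to 60th percentile threshold", k
            )
            thresholds[k] = np.percentile(members, 60.0)
            continue
        evals, evecs = np.linalg.eigh(model.covariances[k])
        probes = []
        for j in range(len(evals)):
            axis = evecs[:, j] * np.sqrt(max(evals[j], 1e-300))
            probes.append(model.means[k] + r_star * axis)
            probes.append(model.means[k] - r_star * axis)
        thresholds[k] = float(np.mean(model.density(np.array(probes))))
    labels = np.zeros(x.shape[0], dtype=int)
    for k in range(model.n_components):
        in_core = (resp[:, k] > 0.5) & (dens >= thresholds[k])
        labels[in_core] = k + 1
    return StateAssignment(labels=labels, thresholds=thresholds, densities=dens)


def state_populations(
    assignment: StateAssignment | np.ndarray,
    n_states: int | None = None,
) -> StatePopulations:
    """Percent of frames in each state core and their sum.

    Accepts either a ``StateAssignment`` or a raw 1-based label array
    (0 = unassigned).
    """
    if isinstance(assignment, StateAssignment):
        labels = assignment.labels
        n_states = assignment.n_states
    else:
        labels = np.asarray(assignment, dtype=int)
        if n_states is None:
            n_states = int(labels.max()) if labels.size else 0
    n_frames = len(labels)
    if n_frames == 0:
        percent = np.zeros(n_states)
    else:
        percent = np.array(
            [100.0 * np.sum(labels == k + 1) / n_frames for k in range(n_states)]
        )
    return StatePopulations(percent=percent, total=float(percent.sum()))


def order_states_by_energy(
    model: GMMParams,
    populations: StatePopulations,
    temperature: float = 300.0,
) -> list[int]:
    """States ordered by ascending free energy of their density modes.

    The mode density of state k is the mixture density at the
    component's mean (the mode for well-separated components), so the
    ordering is descending mode density.  Ties break by descending
    population, then ascending state index.  Returns 1-based labels.
    """
    dens = model.density(model.means)
    order = sorted(
        range(model.n_components),
        key=lambda k: (-round(dens[k], 12), -populations.percent[k], k),
    )
    return [k + 1 for k in order]
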