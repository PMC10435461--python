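"""Linear projections of frame features to 2-D collective variables.

The state-clustering stages work in low-dimensional collective-variable
(CV) spaces.  Two projections are provided:

* PCA of superposed backbone Cartesian coordinates (or any feature
  matrix) — mean-centred covariance eigendecomposition;
* linear discriminant analysis of interdomain-distance features —
  directions maximizing between-class over within-class scatter,
  computed by SVD of the whitened class-mean matrix (at most
  n_classes − 1 informative components).

Determinism: each component's sign is fixed by making its
largest-magnitude loading positive, so repeated runs are comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .traj import Trajectory, kabsch_superpose

__all__ = [
    "ProjectionModel",
    "pca_fit_transform",
    "lda_fit_transform",
    "backbone_coordinate_features",
]

logger = logging.getLogger(__name__)


@dataclass
class ProjectionModel:
    """A fitted linear projection x ↦ (x − center) @ basis."""

    center: np.ndarray  # (n_features,)
    basis: np.ndarray  # (n_features, k), orthonormal columns
    explained_variance: np.ndarray  # (k,), non-increasing
    kind: str = "pca"

    def transform(self, features: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        return (x - self.center) @ self.basis

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "center": self.center.tolist(),
                    "basis": self.basis.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ProjectionModel":
        rec = json.loads(Path(path).read_text())
        return cls(
            center=np.asarray(rec["center"]),
            basis=np.asarray(rec["basis"]),
            explained_variance=np.asarray(rec["explained_variance"]),
            kind=rec.get("kind", "pca"),
        )


def _fix_signs(basis: np.ndarray) -> np.ndarray:
    """Make each column's largest-|loading| entry positive."""
    out = basis.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def _as_matrix(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("feature matrix must be 2-D with at least 2 frames")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature matrix contains non-finite values")
    return x


def pca_fit_transform(
    features, k: int = 2
) -> tuple[ProjectionModel, np.ndarray]:
    """Principal component analysis by covariance eigendecomposition.

    Uses the covariance (not correlation) matrix; projections onto the
    returned orthonormal basis have variance equal to the eigenvalues.

    Raises
    ------
    ValueError
        If the feature matrix has rank below ``k`` (the attainable rank
        is reported).
    """
    x = _as_matrix(features)
    if x.shape[0] <= k:
        raise ValueError(f"need more than k={k} frames")
    center = x.mean(axis=0)
    xc = x - center
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if rank < k:
        raise ValueError(
            f"feature matrix rank {rank} is below the requested k={k}"
        )
    basis = _fix_signs(evecs[:, :k])
    model = ProjectionModel(
        center=center,
        basis=basis,
        explained_variance=evals[:k],
        kind="pca",
    )
    return model, xc @ basis


def lda_fit_transform(
    features, labels, k: int = 2, ridge: float = 1e-8
) -> tuple[ProjectionModel, np.ndarray]:
    """Linear discriminant directions via SVD of the whitened class means.

    The within-class scatter S_w is Cholesky-whitened; the singular
    vectors of the whitened, weight-scaled class-mean matrix give the
    discriminants.  Only ``min(k, n_classes-1)`` components carry
    discriminative signal; trailing requested components are filled
    from the remaining singular vectors.  A singular S_w is
    ridge-regularized (logged).
    """
    x = _as_matrix(features)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("LDA needs at least 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 frames")
    n, d = x.shape
    center = x.mean(axis=0)
    s_w = np.zeros((d, d))
    mean_rows = []
    weights = []
    for c in classes:
        xc = x[labels == c]
        mu = xc.mean(axis=0)
        dev = xc - mu
        s_w += dev.T @ dev
        mean_rows.append(mu - center)
        weights.append(len(xc) / n)
    s_w /= n
    try:
        chol = np.linalg.cholesky(s_w)
    except np.linalg.LinAlgError:
        eps = ridge * np.trace(s_w) / d if np.trace(s_w) > 0 else ridge
        logger.warning("singular within-class scatter; ridge eps=%.3e", eps)
        chol = np.linalg.cholesky(s_w + eps * np.eye(d))
    m = np.vstack(
        [np.sqrt(w) * row for w, row in zip(weights, mean_rows)]
    )  # (n_classes, d)
    # Whiten: rows of m in the metric of S_w^{-1}.
    m_white = solve_triangular(chol, m.T, lower=True).T
    u, s, vt = np.linalg.svd(m_white, full_matrices=True)
    # Map singular directions back: w = L^{-T} v.
    directions = solve_triangular(chol.T, vt.T, lower=False)
    k_eff = min(k, d)
    basis = directions[:, :k_eff]
    # Orthonormalize (directions are S_w-conjugate, not orthogonal).
    basis, _ = np.linalg.qr(basis)
    basis = _fix_signs(basis)
    ev = np.zeros(k_eff)
    ev[: min(k_eff, s.size)] = (s**2)[: min(k_eff, s.size)]
    model = ProjectionModel(
        center=center, basis=basis, explained_variance=ev, kind="lda"
    )
    return model, (x - center) @ basis


def backbone_coordinate_features(
    trajectory: Trajectory,
    reference: np.ndarray,
    selection: np.ndarray,
    mode: str = "coordinates",
) -> pd.DataFrame:
    """Flatten superposed backbone coordinates into a PCA-ready matrix.

    Each frame is superposed onto the reference over ``selection``;
    ``mode="coordinates"`` (default, the conventional choice behind 2-D
    PC free-energy landscapes) flattens the aligned selection
    coordinates, ``mode="deviations"`` keeps only per-atom deviation
    magnitudes from the reference.
    """
    selection = np.asarray(selection, dtype=int)
    rows = []
    ref_sel = np.asarray(reference, dtype=float)[selection]
    for frame in trajectory.coordinates:
        res = kabsch_superpose(frame, reference, selection)
        aligned = res.apply(frame[selection])
        if mode == "coordinates":
            rows.append(aligned.ravel())
        elif mode == "deviations":
            rows.append(np.linalg.norm(aligned - ref_sel, axis=1))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    cols = (
        [f"a{i}_{ax}" for i in selection for ax in "xyz"]
        if mode == "coordinates"
        else [f"a{i}_dev" for i in selection]
    )
    return pd.DataFrame(np.array(rows), columns=cols)
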