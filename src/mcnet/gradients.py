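"""Principal gradients of the covariance network.

The landmark route correlates every vertex's residual series against a
random subset of landmark vertices only, so memory scales with
``n_vertices * n_landmarks`` instead of ``n_vertices ** 2``.  Gradients are
the top singular components of the row-centered connectivity profiles; the
full-matrix decomposition (``exact_gradients``) uses the same conventions
and serves as the correctness oracle for the approximation.

Design notes
------------
* The embedding is a centered singular value decomposition of raw
  correlation profiles: no affinity kernel, no alpha-normalization, no
  cosine transform.
* Profiles are centered per row (each vertex's profile has its mean
  removed).
* Component sign is fixed by making the loading of the landmark with the
  largest absolute loading positive, so repeated runs and different
  backends agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from mcnet.covnet import CovarianceNetwork, ResidualMatrix, _column_sds

__all__ = [
    "LandmarkSet",
    "GradientSet",
    "select_landmarks",
    "landmark_connectivity",
    "approximate_gradients",
    "exact_gradients",
    "align_components",
    "DEFAULT_N_LANDMARKS",
]

DEFAULT_N_LANDMARKS = 3000


@dataclass(frozen=True)
class LandmarkSet:
    """Sorted unique 0-based vertex indices used as landmarks."""

    indices: np.ndarray
    n_vertices: int
    seed: int

    @property
    def n_landmarks(self) -> int:
        return self.indices.shape[0]

    def validate(self) -> None:
        idx = self.indices
        if idx.ndim != 1:
            raise ValueError("landmark indices must be one-dimensional")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("landmark indices must be strictly increasing")
        if idx.size and (idx[0] < 0 or idx[-1] >= self.n_vertices):
            raise ValueError("landmark indices out of range")


@dataclass
class GradientSet:
    """Vertex scores for k components plus variance-explained fractions.

    ``variance_explained`` is non-increasing and sums to at most 1;
    ``landmarks`` is either a :class:`LandmarkSet` or the string ``"full"``.
    """

    scores: np.ndarray
    variance_explained: np.ndarray
    landmarks: Union[LandmarkSet, str]
    k: int

    @property
    def n_vertices(self) -> int:
        return self.scores.shape[0]

    def validate(self) -> None:
        if self.scores.shape[1] != self.k:
            raise ValueError("score matrix width does not match k")
        ve = self.variance_explained
        if ve.shape != (self.k,):
            raise ValueError("variance_explained length does not match k")
        if np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing")
        if ve.sum() > 1 + 1e-9:
            raise ValueError("variance_explained sums to more than 1")


def select_landmarks(n_vertices: int, n_landmarks: int, seed: int = 0) -> LandmarkSet:
    """Uniform random landmark sample without replacement, sorted."""
    if not 1 <= n_landmarks <= n_vertices:
        raise ValueError(
            f"n_landmarks must be in [1, n_vertices={n_vertices}], got {n_landmarks}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n_vertices, size=n_landmarks, replace=False))
    landmarks = LandmarkSet(indices=idx, n_vertices=n_vertices, seed=seed)
    landmarks.validate()
    return landmarks


def landmark_connectivity(
    residuals: ResidualMatrix, landmarks: LandmarkSet
) -> np.ndarray:
    """Vertex-by-landmark Pearson correlation matrix.

    Entry (v, l) is the correlation between residual columns v and
    landmark l across subjects.  Only the (n_vertices, n_landmarks) block
    is ever materialized.
    """
    landmarks.validate()
    if landmarks.n_vertices != residuals.n_vertices:
        raise ValueError(
            f"landmark set built for {landmarks.n_vertices} vertices, residual "
            f"matrix has {residuals.n_vertices}"
        )
    data = residuals.residuals
    sds = _column_sds(data, "residual column")
    centered = data - data.mean(axis=0)
    z = centered / (sds * np.sqrt(data.shape[0] - 1))
    conn = z.T @ z[:, landmarks.indices]
    return np.clip(conn, -1.0, 1.0)


def _centered_svd(profiles: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-center, decompose, fix signs; returns (scores, variance_explained)."""
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > max(1, centered.shape[0]) * np.finfo(float).eps * s[0])) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the numerical rank ({rank}) of the profiles")
    total = float(np.sum(s**2))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            scores[:, i] = -scores[:, i]
            loadings[i] = -loadings[i]
    ve = s[:k] ** 2 / total
    return scores, ve


def approximate_gradients(
    conn: np.ndarray, k: int, landmarks: Union[LandmarkSet, str, None] = None
) -> GradientSet:
    """Gradients from a vertex-by-landmark connectivity matrix.

    Rows are treated as vertex connectivity profiles; each profile is
    centered and the top-k singular components give the vertex scores.
    ``variance_explained[i]`` is the i-th squared singular value divided by
    the total variance of the centered profile matrix.
    """
    conn = np.asarray(conn, dtype=float)
    if conn.ndim != 2:
        raise ValueError("connectivity matrix must be two-dimensional")
    if k < 1 or k > conn.shape[1]:
        raise ValueError(f"k must be in [1, n_landmarks={conn.shape[1]}], got {k}")
    scores, ve = _centered_svd(conn, k)
    gradients = GradientSet(
        scores=scores,
        variance_explained=ve,
        landmarks=landmarks if landmarks is not None else "unspecified",
        k=k,
    )
    gradients.validate()
    return gradients


def exact_gradients(network: CovarianceNetwork, k: int) -> GradientSet:
    """Full-matrix decomposition with the same conventions (oracle route)."""
    network.validate()
    if k < 1 or k > network.n_vertices:
        raise ValueError(
            f"k must be in [1, n_vertices={network.n_vertices}], got {k}"
        )
    scores, ve = _centered_svd(network.rho, k)
    gradients = GradientSet(
        scores=scores, variance_explained=ve, landmarks="full", k=k
    )
    gradients.validate()
    return gradients


def align_components(a: GradientSet, b: GradientSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-component sign flips and |r| aligning ``b`` onto ``a``.

    Returns ``(flips, abs_r)`` where ``flips[i]`` in {+1, -1} is the sign
    maximizing the correlation of component i and ``abs_r[i]`` the achieved
    absolute correlation.
    """
    if a.n_vertices != b.n_vertices:
        raise ValueError("gradient sets have different vertex counts")
    if a.k != b.k:
        raise ValueError("gradient sets have different k")
    flips = np.empty(a.k)
    abs_r = np.empty(a.k)
    for i in range(a.k):
        r = np.corrcoef(a.scores[:, i], b.scores[:, i])[0, 1]
        flips[i] = 1.0 if r >= 0 else -1.0
        abs_r[i] = abs(r)
    return flips, abs_r
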