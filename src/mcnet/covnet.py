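"""Covariance-network construction.

Residualizes subject-by-vertex maps against an age/gender confound design,
builds the vertex-by-vertex Pearson correlation network of the residuals,
and computes signed per-vertex connectivity strength maps (negative,
positive, and full, with no thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from mcnet.synth import Cohort

__all__ = [
    "DESIGN_COLUMNS",
    "ResidualMatrix",
    "CovarianceNetwork",
    "StrengthMaps",
    "residualize",
    "covariance_network",
    "strength_maps",
]

DESIGN_COLUMNS = ("intercept", "age", "age2", "gender", "age_x_gender")


@dataclass
class ResidualMatrix:
    """Residuals of the per-vertex confound regression.

    Parameters
    ----------
    residuals : ndarray, shape (n_subjects, n_vertices)
        Observed minus fitted values; column means are zero (the design
        contains an intercept).
    coefficients : ndarray, shape (5, n_vertices)
        Fitted ordinary-least-squares coefficients for the design columns
        ``DESIGN_COLUMNS``.
    """

    residuals: np.ndarray
    coefficients: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.residuals.shape[1]


@dataclass
class CovarianceNetwork:
    """Symmetric vertex-by-vertex Pearson correlation matrix.

    Entries lie in [-1, 1], the diagonal is exactly 1, and all values are
    finite.
    """

    rho: np.ndarray
    n_subjects: int

    @property
    def n_vertices(self) -> int:
        return self.rho.shape[0]

    def validate(self) -> None:
        if self.rho.ndim != 2 or self.rho.shape[0] != self.rho.shape[1]:
            raise ValueError(f"rho must be square, got shape {self.rho.shape}")
        if not np.all(np.isfinite(self.rho)):
            raise ValueError("rho contains non-finite values")
        if not np.allclose(self.rho, self.rho.T, atol=1e-12):
            raise ValueError("rho is not symmetric")
        if not np.allclose(np.diag(self.rho), 1.0, atol=1e-12):
            raise ValueError("rho diagonal is not 1")


@dataclass
class StrengthMaps:
    """Signed per-vertex strength over off-diagonal network entries.

    ``full`` is computed as ``positive + negative`` elementwise, so the
    additivity identity holds exactly in floating point.  ``negative <= 0``
    and ``positive >= 0`` everywhere; entries that are exactly zero
    contribute to neither signed map.
    """

    negative: np.ndarray
    positive: np.ndarray
    full: np.ndarray


def build_design(age: np.ndarray, gender: np.ndarray) -> np.ndarray:
    """Design matrix [1, age, age^2, gender, age*gender].

    Age is used as given (not centered), following the stated regression
    model literally; rank deficiency is detected downstream.
    """
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=float)
    return np.column_stack(
        [np.ones_like(age), age, age**2, gender, age * gender]
    )


def _check_full_rank(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # QR with column pivoting: columns pivoted beyond the numerical rank
        # are linearly dependent on the earlier ones.
        _, _, piv = scipy.linalg.qr(design, mode="economic", pivoting=True)
        dependent = sorted(DESIGN_COLUMNS[j] for j in piv[rank:])
        raise ValueError(
            f"confound design is rank deficient (rank {rank} of "
            f"{design.shape[1]}); collinear columns: {', '.join(dependent)}"
        )


def residualize(cohort: Cohort) -> ResidualMatrix:
    """Per-vertex OLS residualization against the confound design.

    Fits myelin(v) on [1, age, age^2, gender, age*gender] independently for
    every vertex and returns observed minus fitted values.

    Raises
    ------
    ValueError
        If fewer than 6 subjects are available or the design is rank
        deficient (the offending columns are named, e.g. a single-gender
        cohort makes gender and the interaction collinear).
    """
    cohort.validate()
    if cohort.n_subjects < 6:
        raise ValueError(
            f"residualization needs >= 6 subjects (5 design columns), "
            f"got {cohort.n_subjects}"
        )
    design = build_design(
        cohort.covariates["age"].to_numpy(), cohort.covariates["gender"].to_numpy()
    )
    _check_full_rank(design)
    coef, _, _, _ = np.linalg.lstsq(design, cohort.myelin, rcond=None)
    residuals = cohort.myelin - design @ coef
    return ResidualMatrix(residuals=residuals, coefficients=coef)


def _column_sds(matrix: np.ndarray, what: str) -> np.ndarray:
    sds = matrix.std(axis=0, ddof=1)
    scale = np.abs(matrix).max(axis=0)
    bad = np.flatnonzero(sds <= np.finfo(float).tiny + 1e-14 * scale)
    if bad.size:
        shown = ", ".join(map(str, bad[:20]))
        more = f" (+{bad.size - 20} more)" if bad.size > 20 else ""
        raise ValueError(f"zero-variance {what} at vertex indices: {shown}{more}")
    return sds


def covariance_network(residuals: ResidualMatrix) -> CovarianceNetwork:
    """Pearson correlation of residual columns across subjects.

    Raises
    ------
    ValueError
        If any vertex has zero residual variance (the offending vertex
        indices are listed; vertices are never silently dropped).
    """
    _column_sds(residuals.residuals, "residual column")
    rho = np.corrcoef(residuals.residuals, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    np.clip(rho, -1.0, 1.0, out=rho)
    network = CovarianceNetwork(rho=rho, n_subjects=residuals.n_subjects)
    network.validate()
    return network


def strength_maps(network: CovarianceNetwork) -> StrengthMaps:
    """Per-vertex sums of off-diagonal correlations, split by sign.

    The structural self-correlation on the diagonal is excluded.  The full
    map is defined as ``positive + negative`` so the additivity identity
    holds exactly at every vertex.
    """
    network.validate()
    off = network.rho.copy()
    np.fill_diagonal(off, 0.0)
    positive = np.where(off > 0, off, 0.0).sum(axis=1)
    negative = np.where(off < 0, off, 0.0).sum(axis=1)
    full = positive + negative
    return StrengthMaps(negative=negative, positive=positive, full=full)
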