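"""Class profiles, term decoding, and feature correlations.

Aggregates vertex maps over parcellation classes (unweighted within-class
means, with across-class dispersion using the sample n-1 denominator),
decodes maps against a term bank on jointly non-zero vertices, and
correlates maps with feature maps under Bonferroni or Holm family-wise
error control.  Two-sided p-values come from the exact t-transform of r
with n-2 degrees of freedom; vertices are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from mcnet.covnet import StrengthMaps
from mcnet.gradients import GradientSet

__all__ = [
    "ClassProfile",
    "CorrelationReport",
    "class_means",
    "profile_dispersion",
    "class_profile",
    "decode_terms",
    "correlate_features",
    "holm_adjust",
    "gradient_strength_matrix",
]


@dataclass
class ClassProfile:
    """Per-class means of a vertex map plus across-class dispersion."""

    class_ids: np.ndarray
    means: np.ndarray
    class_labels: list[str]
    dispersion: Optional[float] = None


@dataclass
class CorrelationReport:
    """Pairwise correlation table with an explicit correction rule.

    ``table`` has one row per pair with Pearson r, two-sided p, and a
    significance flag consistent with the stated method and family size m.
    """

    table: pd.DataFrame
    method: str
    alpha: float
    m: int


def class_means(
    values: np.ndarray,
    parcellation: np.ndarray,
    n_classes: Optional[int] = None,
    class_labels: Optional[Sequence[str]] = None,
) -> ClassProfile:
    """Unweighted mean of vertex values within each parcellation class.

    When ``n_classes`` is given, classes 1..n_classes are required to be
    non-empty; an empty class raises an error naming it.
    """
    values = np.asarray(values, dtype=float)
    parcellation = np.asarray(parcellation)
    if values.shape != parcellation.shape:
        raise ValueError(
            f"map length {values.shape} does not match parcellation "
            f"{parcellation.shape}"
        )
    if n_classes is not None:
        ids = np.arange(1, n_classes + 1)
        present = set(np.unique(parcellation).tolist())
        missing = [int(c) for c in ids if int(c) not in present]
        if missing:
            raise ValueError(f"empty parcellation class(es): {missing}")
    else:
        ids = np.unique(parcellation)
    means = np.array([values[parcellation == c].mean() for c in ids])
    if class_labels is None:
        labels = [f"class{int(c)}" for c in ids]
    else:
        if len(class_labels) != len(ids):
            raise ValueError(
                f"{len(class_labels)} labels supplied for {len(ids)} classes"
            )
        labels = list(class_labels)
    return ClassProfile(class_ids=np.asarray(ids), means=means, class_labels=labels)


def profile_dispersion(means: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator) across class means."""
    means = np.asarray(means, dtype=float)
    if means.ndim != 1 or means.size < 2:
        raise ValueError(f"need >= 2 class means, got {means.size}")
    return float(np.std(means, ddof=1))


def class_profile(
    values: np.ndarray,
    parcellation: np.ndarray,
    n_classes: Optional[int] = None,
    class_labels: Optional[Sequence[str]] = None,
) -> ClassProfile:
    """Class means plus across-class dispersion in one call."""
    profile = class_means(values, parcellation, n_classes, class_labels)
    profile.dispersion = profile_dispersion(profile.means)
    return profile


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return np.nan
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def _r_pvalue(r: float, n: int) -> float:
    """Two-sided p from the exact t-transform of r with n-2 dof."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


def decode_terms(
    values: np.ndarray,
    term_maps: np.ndarray,
    term_names: Optional[Sequence[str]] = None,
    min_mask: int = 3,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Correlate a vertex map with each term map on jointly non-zero vertices.

    For every term the correlation is computed only over vertices where both
    the input map and that term map are non-zero.  Terms whose mask holds
    fewer than ``min_mask`` vertices (or whose masked values are constant)
    are flagged undefined and excluded from the ranking.  The table is
    sorted by \\|r\\| descending with unique ranks 1..n over included terms.
    """
    values = np.asarray(values, dtype=float)
    term_maps = np.asarray(term_maps, dtype=float)
    if term_maps.ndim != 2 or term_maps.shape[1] != values.shape[0]:
        raise ValueError(
            f"term_maps shape {term_maps.shape} incompatible with map length "
            f"{values.shape[0]}"
        )
    n_terms = term_maps.shape[0]
    if term_names is None:
        term_names = [f"term{i}" for i in range(n_terms)]
    rows = []
    for i in range(n_terms):
        mask = (values != 0) & (term_maps[i] != 0)
        n_used = int(mask.sum())
        if n_used < min_mask:
            rows.append((term_names[i], np.nan, n_used, "mask_too_small"))
            continue
        r = _pearson(values[mask], term_maps[i][mask])
        if not np.isfinite(r):
            rows.append((term_names[i], np.nan, n_used, "constant_on_mask"))
            continue
        rows.append((term_names[i], r, n_used, ""))
    df = pd.DataFrame(rows, columns=["term", "r", "n_used", "note"])
    included = df[df["note"] == ""]
    if included.empty:
        raise ValueError(
            "empty mask: no term has enough jointly non-zero vertices to decode"
        )
    order = np.argsort(-included["r"].abs().to_numpy(), kind="stable")
    ranked = included.iloc[order].copy()
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    excluded = df[df["note"] != ""].copy()
    excluded["rank"] = pd.NA
    out = pd.concat([ranked, excluded], ignore_index=True)
    if top is not None:
        out = out.head(top)
    return out


def correlate_features(
    maps: Mapping[str, np.ndarray],
    features: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    m: Optional[int] = None,
) -> CorrelationReport:
    """Pearson r and two-sided p per (map, feature) pair, Bonferroni-flagged.

    A pair is flagged non-significant iff p > alpha/m; the family size m
    defaults to the number of pairs (for a 3-map-by-10-feature design,
    m = 30).  Constant inputs yield an undefined correlation flagged with an
    explicit code rather than a silent NaN comparison.
    """
    features = np.asarray(features, dtype=float)
    n_features = features.shape[0]
    if feature_names is None:
        feature_names = [f"feature{i}" for i in range(n_features)]
    if m is None:
        m = len(maps) * n_features
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    rows = []
    for map_name, map_values in maps.items():
        x = np.asarray(map_values, dtype=float)
        if x.shape[0] != features.shape[1]:
            raise ValueError(
                f"map {map_name!r} has {x.shape[0]} vertices, features have "
                f"{features.shape[1]}"
            )
        for j in range(n_features):
            r = _pearson(x, features[j])
            if not np.isfinite(r):
                rows.append((map_name, feature_names[j], np.nan, np.nan, False, "undefined_constant_input"))
                continue
            p = _r_pvalue(r, x.shape[0])
            rows.append((map_name, feature_names[j], r, p, bool(p <= alpha / m), ""))
    table = pd.DataFrame(
        rows, columns=["map", "feature", "r", "p", "significant", "note"]
    )
    return CorrelationReport(table=table, method="bonferroni", alpha=alpha, m=m)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Holm adjustment, preserving the input order.

    Sorted ascending, the i-th smallest p (1-based) is multiplied by
    (m - i + 1); a running maximum enforces monotonicity and values are
    clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def gradient_strength_matrix(
    gradient_set: GradientSet,
    strengths: StrengthMaps,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Gradient-by-strength Pearson matrix with Holm-adjusted p-values.

    Correlates each gradient score column with the negative, positive and
    full strength maps across vertices (family size k x 3, Holm step-down).
    """
    strength_maps = {
        "negative": strengths.negative,
        "positive": strengths.positive,
        "full": strengths.full,
    }
    n_vertices = gradient_set.n_vertices
    rows = []
    for i in range(gradient_set.k):
        g = gradient_set.scores[:, i]
        for name, s in strength_maps.items():
            s = np.asarray(s, dtype=float)
            if s.shape[0] != n_vertices:
                raise ValueError(
                    f"strength map {name!r} has {s.shape[0]} vertices, gradients "
                    f"have {n_vertices}"
                )
            r = _pearson(g, s)
            if not np.isfinite(r):
                rows.append((f"gradient{i + 1}", name, np.nan, np.nan))
                continue
            rows.append((f"gradient{i + 1}", name, r, _r_pvalue(r, n_vertices)))
    table = pd.DataFrame(rows, columns=["map", "feature", "r", "p"])
    finite = table["p"].notna()
    p_adj = np.full(len(table), np.nan)
    if finite.any():
        p_adj[finite.to_numpy()] = holm_adjust(table.loc[finite, "p"].to_numpy())
    table["p_adj"] = p_adj
    table["significant"] = table["p_adj"] <= alpha
    table["note"] = np.where(finite, "", "undefined_constant_input")
    return CorrelationReport(
        table=table, method="holm", alpha=alpha, m=int(finite.sum())
    )
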