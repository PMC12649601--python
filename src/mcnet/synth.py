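"""Synthetic cohorts and annotation assets.

Generates subject-by-vertex matrices whose inter-vertex correlation
structure is low-rank (planted orthonormal component patterns) plus
Gaussian noise, with optional linear confound effects (age, age squared,
gender, age-by-gender interaction) injected on top.  Also generates
parcellations, term-map banks, and feature maps with planted correlations,
so every downstream stage can be tested without external data.

All outputs are fully reproducible from the seed carried in the spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CohortSpec",
    "Cohort",
    "AnnotationBundle",
    "generate_cohort",
    "generate_parcellation",
    "generate_term_maps",
    "generate_feature_maps",
    "write_cohort",
    "write_annotations",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    ``component_loadings`` are per-component score standard deviations and
    must be strictly decreasing so that planted components have strictly
    decreasing variance.  When ``None`` a geometric ladder is used.

    Confound coefficients are scalars applied uniformly across vertices;
    gender is coded 0/1 and ages are drawn uniformly on ``age_range``
    (default matches a young-adult cohort, 22-37 years).
    """

    n_subjects: int
    n_vertices: int
    n_components: int = 1
    component_loadings: Optional[Sequence[float]] = None
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (22.0, 37.0)
    beta_age: float = 0.0
    beta_age2: float = 0.0
    beta_gender: float = 0.0
    beta_interaction: float = 0.0
    seed: int = 0
    pattern_style: str = "flat"
    smooth_sigma: Optional[float] = None

    def loadings(self) -> np.ndarray:
        if self.component_loadings is not None:
            return np.asarray(self.component_loadings, dtype=float)
        # patterns are orthonormal across vertices (entries ~ 1/sqrt(n_vertices)),
        # so score SDs scale with sqrt(n_vertices) to keep per-vertex signal
        # variance independent of resolution
        return 2.0 * 0.65 ** np.arange(self.n_components) * np.sqrt(self.n_vertices)

    def validate(self) -> None:
        if self.n_subjects < 6:
            raise ValueError(f"n_subjects must be >= 6, got {self.n_subjects}")
        if self.n_vertices < 4:
            raise ValueError(f"n_vertices must be >= 4, got {self.n_vertices}")
        if self.n_components < 1:
            raise ValueError(f"n_components must be >= 1, got {self.n_components}")
        if self.n_components > min(self.n_subjects, self.n_vertices):
            raise ValueError(
                "n_components must not exceed min(n_subjects, n_vertices), "
                f"got {self.n_components}"
            )
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must satisfy min < max, got {self.age_range}")
        if self.pattern_style not in ("flat", "smooth"):
            raise ValueError(f"unknown pattern_style {self.pattern_style!r}")
        lam = self.loadings()
        if lam.shape != (self.n_components,):
            raise ValueError(
                "component_loadings must have one entry per component, got "
                f"{len(lam)} for n_components={self.n_components}"
            )
        if np.any(lam <= 0) or np.any(np.diff(lam) >= 0):
            raise ValueError(
                "component_loadings must be positive and strictly decreasing, "
                f"got {lam.tolist()}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        if d["component_loadings"] is not None:
            d["component_loadings"] = list(d["component_loadings"])
        return d


@dataclass
class Cohort:
    """Subject-by-vertex matrix with covariates and (optional) ground truth.

    ``truth`` holds the planted per-vertex component patterns
    (``patterns``: components x vertices), per-subject component scores
    (``scores``: subjects x components), and the per-vertex baseline
    (``mu``).  It is only present for synthetic cohorts.
    """

    myelin: np.ndarray
    covariates: pd.DataFrame
    truth: Optional[dict] = None
    spec: Optional[CohortSpec] = None

    @property
    def n_subjects(self) -> int:
        return self.myelin.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.myelin.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.myelin)):
            raise ValueError("myelin matrix contains non-finite values")
        if len(self.covariates) != self.myelin.shape[0]:
            raise ValueError(
                f"covariate rows ({len(self.covariates)}) != subjects "
                f"({self.myelin.shape[0]})"
            )
        for col in ("age", "gender"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates must contain column '{col}'")


@dataclass
class AnnotationBundle:
    """Per-vertex annotation assets used by the profiling stage."""

    parcellation: np.ndarray
    term_maps: np.ndarray
    feature_maps: np.ndarray
    term_names: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def validate(self) -> None:
        n_vertices = self.parcellation.shape[0]
        if self.term_maps.shape[1] != n_vertices:
            raise ValueError("term_maps vertex count does not match parcellation")
        if self.feature_maps.shape[1] != n_vertices:
            raise ValueError("feature_maps vertex count does not match parcellation")


def _orthonormal_patterns(
    rng: np.random.Generator,
    n_components: int,
    n_vertices: int,
    style: str,
    sigma: float,
) -> np.ndarray:
    """Orthonormal vertex patterns.

    ``style='flat'`` (default) uses random-phase square waves with distinct
    spatial frequencies: entries are +-1/sqrt(n) before orthonormalization,
    so every component has a near-constant amplitude profile and the
    per-vertex signal variance is (almost) uniform.  That makes the planted
    patterns the population eigenvectors of the inter-vertex *correlation*
    matrix, not just of the covariance, which is what pattern-recovery
    tests rely on.  ``style='smooth'`` uses Gaussian-filtered noise instead
    (spatially smooth but with a strongly varying amplitude profile, under
    which correlation eigenvectors are distorted relative to the patterns).
    """
    if style == "flat":
        n_freq = max(8, n_components + 2)
        freqs = 1 + rng.permutation(n_freq)[:n_components]
        phases = rng.uniform(0, 2 * np.pi, size=n_components)
        v = np.arange(n_vertices)
        raw = np.sign(
            np.sin(2 * np.pi * freqs[:, None] * v[None, :] / n_vertices + phases[:, None])
        )
        raw[raw == 0] = 1.0
    elif style == "smooth":
        raw = rng.standard_normal((n_components, n_vertices))
        if sigma > 0:
            raw = gaussian_filter1d(raw, sigma=sigma, axis=1, mode="wrap")
    else:
        raise ValueError(f"unknown pattern_style {style!r}")
    q, _ = np.linalg.qr(raw.T)  # columns orthonormal
    patterns = q[:, :n_components].T
    # deterministic sign: largest-magnitude entry positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(patterns[i])))
        if patterns[i, j] < 0:
            patterns[i] = -patterns[i]
    return patterns


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a synthetic cohort according to ``spec``.

    myelin(s, v) = mu(v) + sum_k score(s, k) pattern(k, v)
                 + b1 age + b2 age^2 + b3 gender + b4 age*gender + noise

    Planted patterns are mutually orthonormal across vertices and component
    score variances are strictly decreasing.  The random draw order does not
    depend on the confound coefficients, so cohorts generated from specs
    differing only in betas share all random draws.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    sigma = spec.smooth_sigma
    if sigma is None:
        sigma = max(1.0, spec.n_vertices / 50.0)
    patterns = _orthonormal_patterns(
        rng, spec.n_components, spec.n_vertices, spec.pattern_style, sigma
    )
    mu = rng.standard_normal(spec.n_vertices)

    loadings = spec.loadings()
    scores = rng.standard_normal((spec.n_subjects, spec.n_components)) * loadings

    age = rng.uniform(spec.age_range[0], spec.age_range[1], size=spec.n_subjects)
    # balanced 0/1 gender, shuffled: guarantees a full-rank confound design
    gender = np.zeros(spec.n_subjects, dtype=int)
    gender[spec.n_subjects // 2 :] = 1
    gender = rng.permutation(gender)

    noise = rng.standard_normal((spec.n_subjects, spec.n_vertices)) * spec.noise_sd

    confound = (
        spec.beta_age * age
        + spec.beta_age2 * age**2
        + spec.beta_gender * gender
        + spec.beta_interaction * age * gender
    )

    myelin = mu[None, :] + scores @ patterns + confound[:, None] + noise
    covariates = pd.DataFrame({"age": age, "gender": gender})
    truth = {"patterns": patterns, "scores": scores, "mu": mu}
    cohort = Cohort(myelin=myelin, covariates=covariates, truth=truth, spec=spec)
    cohort.validate()
    return cohort


def generate_parcellation(
    n_vertices: int, n_classes: int, seed: int = 0, mode: str = "blocks"
) -> np.ndarray:
    """Per-vertex class labels in 1..n_classes; every class is non-empty.

    ``mode='blocks'`` assigns contiguous, near-equal blocks; ``mode='random'``
    assigns labels at random but pins one vertex per class so no class is
    empty.
    """
    if n_classes < 1:
        raise ValueError(f"n_classes must be >= 1, got {n_classes}")
    if n_classes > n_vertices:
        raise ValueError(
            f"n_classes ({n_classes}) must not exceed n_vertices ({n_vertices})"
        )
    if mode == "blocks":
        base = n_vertices // n_classes
        extra = n_vertices % n_classes
        sizes = [base + (1 if i < extra else 0) for i in range(n_classes)]
        return np.repeat(np.arange(1, n_classes + 1), sizes)
    if mode == "random":
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, n_classes + 1, size=n_vertices)
        pinned = rng.choice(n_vertices, size=n_classes, replace=False)
        labels[pinned] = np.arange(1, n_classes + 1)
        return labels
    raise ValueError(f"unknown parcellation mode {mode!r}")


def generate_term_maps(
    n_terms: int,
    n_vertices: int,
    planted: Optional[Sequence[tuple[int, np.ndarray]]] = None,
    seed: int = 0,
    noise_sd: float = 1.0,
    planted_noise_sd: float = 0.0,
    zero_fraction: float = 0.0,
) -> np.ndarray:
    """Term x vertex bank: independent noise rows plus planted copies.

    A ``zero_fraction`` of entries is set to exactly zero to exercise
    downstream joint-non-zero masking.
    """
    if planted:
        idx = [i for i, _ in planted]
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate planted term indices: {sorted(idx)}")
        for i, _ in planted:
            if not 0 <= i < n_terms:
                raise ValueError(f"planted term index {i} out of range [0, {n_terms})")
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError(f"zero_fraction must be in [0, 1], got {zero_fraction}")
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((n_terms, n_vertices)) * noise_sd
    if planted:
        for i, vec in planted:
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n_vertices,):
                raise ValueError(
                    f"planted map for term {i} has shape {vec.shape}, "
                    f"expected ({n_vertices},)"
                )
            maps[i] = vec + rng.standard_normal(n_vertices) * planted_noise_sd
    if zero_fraction > 0:
        maps[rng.random((n_terms, n_vertices)) < zero_fraction] = 0.0
    return maps


def generate_feature_maps(
    n_features: int,
    n_vertices: int,
    planted_correlation: Sequence[float],
    seed: int = 0,
    reference: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature x vertex maps with planted Pearson correlation to a reference.

    Each feature is built as r*z + sqrt(1-r^2)*e with e orthogonalized to
    the standardized reference in-sample, so the realized correlation equals
    the target up to floating point.  Returns ``(features, reference)``.
    """
    r_targets = np.asarray(planted_correlation, dtype=float)
    if r_targets.shape != (n_features,):
        raise ValueError(
            f"planted_correlation must have length {n_features}, got {r_targets.shape}"
        )
    if np.any(np.abs(r_targets) > 1):
        raise ValueError("planted correlations must satisfy |r| <= 1")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = rng.standard_normal(n_vertices)
    reference = np.asarray(reference, dtype=float)
    z = reference - reference.mean()
    z_norm = np.linalg.norm(z)
    if z_norm == 0:
        raise ValueError("reference map is constant; correlation undefined")
    z = z / z_norm
    features = np.empty((n_features, n_vertices))
    for i, r in enumerate(r_targets):
        e = rng.standard_normal(n_vertices)
        e = e - e.mean()
        e = e - (e @ z) * z
        norm = np.linalg.norm(e)
        e = e / norm if norm > 0 else e
        features[i] = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * e
    return features, reference


# ---------------------------------------------------------------------------
# serialization (TSV + JSON sidecar)


def write_cohort(cohort: Cohort, outdir: str | Path, prefix: str = "cohort") -> dict:
    """Write myelin and covariates as TSV with a JSON sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    myelin_path = outdir / f"{prefix}_myelin.tsv"
    cov_path = outdir / f"{prefix}_covariates.tsv"
    sidecar_path = outdir / f"{prefix}_spec.json"
    cols = [f"v{i}" for i in range(cohort.n_vertices)]
    pd.DataFrame(cohort.myelin, columns=cols).to_csv(
        myelin_path, sep="\t", index=False, float_format="%.17g"
    )
    cohort.covariates.to_csv(cov_path, sep="\t", index=False, float_format="%.17g")
    sidecar = {"spec": cohort.spec.to_dict() if cohort.spec else None}
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {
        "myelin": str(myelin_path),
        "covariates": str(cov_path),
        "sidecar": str(sidecar_path),
    }


def write_annotations(
    bundle: AnnotationBundle, outdir: str | Path, prefix: str = "annotations"
) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    cols = [f"v{i}" for i in range(bundle.parcellation.shape[0])]
    for name, arr, index in (
        ("parcellation", bundle.parcellation[None, :], ["label"]),
        ("term_maps", bundle.term_maps, bundle.term_names or None),
        ("feature_maps", bundle.feature_maps, bundle.feature_names or None),
    ):
        path = outdir / f"{prefix}_{name}.tsv"
        df = pd.DataFrame(arr, columns=cols)
        if index is not None:
            df.insert(0, "name", index)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths[name] = str(path)
    return paths
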