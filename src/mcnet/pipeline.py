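"""End-to-end orchestration: config, adapters, staged runs, manifest.

Stage order mirrors the analysis flow: cohort (synthetic or loaded) ->
residualization -> covariance network -> gradients / signed strength ->
class profiles -> term decoding -> feature correlations -> thresholded
graphlet censuses.  All randomness flows from a single master seed split
per stage, so a config fully determines every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from mcnet import __version__ as _version
from mcnet import covnet, gradients, graphlets, profiles, synth

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "StageError",
    "run_pipeline",
    "read_cohort",
    "read_vertex_map",
    "read_matrix_tsv",
]

logger = logging.getLogger("mcnet")

DEFAULT_THRESHOLDS = (-0.4, -0.2, 0.2, 0.4)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run.

    Exactly one of ``synthetic`` (CohortSpec keyword dict) or
    ``cohort_paths`` (dict with 'myelin' and 'covariates' TSV paths) must be
    set.  Annotation assets are generated when ``annotation_paths`` is None.
    """

    outdir: str = "mcnet_out"
    seed: int = 0
    synthetic: Optional[dict] = None
    cohort_paths: Optional[dict] = None
    annotation_paths: Optional[dict] = None
    n_classes: int = 5
    n_terms: int = 50
    n_features: int = 10
    n_landmarks: Optional[int] = None  # default min(3000, n_vertices)
    gradient_k: int = 3
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    census_method: str = "auto"
    census_max_subgraphs: int = 5_000_000
    census_max_edges: int = 3000
    census_n_samples: int = 10000
    alpha: float = 0.05
    feature_family: Optional[int] = None  # default n_maps * n_features
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.cohort_paths is None):
            raise ValueError("exactly one of synthetic/cohort_paths must be set")
        if self.gradient_k < 1:
            raise ValueError(f"gradient_k must be >= 1, got {self.gradient_k}")
        for t in self.thresholds:
            if t == 0:
                raise ValueError("thresholds must be nonzero")
            if abs(t) > 1:
                raise ValueError(f"|threshold| must be <= 1, got {t}")
        if self.census_method not in ("auto", "exact", "sampled"):
            raise ValueError(f"unknown census_method {self.census_method!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and d["thresholds"] is not None:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Inventory of a finished run: config snapshot, seeds, files, timings."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    timings: dict[str, float] = field(default_factory=dict)
    files: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def verify(self, base: str | Path) -> None:
        """Every declared output exists and matches its checksum."""
        base = Path(base)
        for name, info in self.files.items():
            path = base / info["path"]
            if not path.exists():
                raise FileNotFoundError(f"manifest entry {name!r} missing: {path}")
            if _sha256(path) != info["sha256"]:
                raise ValueError(f"checksum mismatch for {name!r}: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(names, children)
    }


# ---------------------------------------------------------------------------
# adapters


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a numeric TSV; a non-numeric cell raises with its coordinates."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell in {path} at row {row}, column {col!r}: "
                f"{df[col].iloc[row]!r}"
            )
        df[col] = converted
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return df


def read_cohort(myelin_path: str | Path, covariates_path: str | Path) -> synth.Cohort:
    """Load a cohort from TSV files with dimension cross-checks."""
    myelin = read_matrix_tsv(myelin_path)
    covariates = read_matrix_tsv(covariates_path)
    if len(covariates) != len(myelin):
        raise ValueError(
            f"covariate row count ({len(covariates)}) does not match subject "
            f"count ({len(myelin)})"
        )
    cohort = synth.Cohort(
        myelin=myelin.to_numpy(dtype=float), covariates=covariates, truth=None
    )
    cohort.validate()
    return cohort


def read_vertex_map(path: str | Path) -> np.ndarray:
    """Per-vertex values from TSV, CIFTI-2 dscalar, or GIFTI metric."""
    path = Path(path)
    suffix = "".join(path.suffixes)
    if suffix.endswith(".dscalar.nii"):
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.get_fdata()).ravel()
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=float).ravel()
    df = read_matrix_tsv(path)
    arr = df.to_numpy(dtype=float)
    return arr.ravel() if 1 in arr.shape or arr.ndim == 1 else arr[:, 0]


# ---------------------------------------------------------------------------
# pipeline


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write every product under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    stage_names = [
        "cohort", "annotations", "residualize", "network", "gradients",
        "strength", "profiles", "decode", "features", "graphlets",
    ]
    seeds = _stage_seeds(config.seed, stage_names)
    manifest = RunManifest(
        config=config.to_dict(), version=_version, stage_seeds=seeds
    )
    files = manifest.files

    def record(name: str, path: Path) -> None:
        files[name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s ...", name)
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    # --- cohort -----------------------------------------------------------
    with stage("cohort"):
        if config.synthetic is not None:
            spec_kwargs = dict(config.synthetic)
            spec_kwargs.setdefault("seed", seeds["cohort"])
            spec = synth.CohortSpec(**spec_kwargs)
            cohort = synth.generate_cohort(spec)
        else:
            cohort = read_cohort(
                config.cohort_paths["myelin"], config.cohort_paths["covariates"]
            )
        paths = synth.write_cohort(cohort, outdir)
        for key, p in paths.items():
            record(f"cohort_{key}", Path(p))

    # --- annotations ------------------------------------------------------
    with stage("annotations"):
        if config.annotation_paths is not None:
            parcellation = read_vertex_map(
                config.annotation_paths["parcellation"]
            ).astype(int)
            term_maps = read_matrix_tsv(config.annotation_paths["term_maps"]).to_numpy()
            feature_maps = read_matrix_tsv(
                config.annotation_paths["feature_maps"]
            ).to_numpy()
            bundle = synth.AnnotationBundle(
                parcellation=parcellation,
                term_maps=term_maps,
                feature_maps=feature_maps,
            )
        else:
            nv = cohort.n_vertices
            parcellation = synth.generate_parcellation(
                nv, config.n_classes, seed=seeds["annotations"], mode="blocks"
            )
            term_maps = synth.generate_term_maps(
                config.n_terms, nv, seed=seeds["annotations"]
            )
            feature_rng = np.random.default_rng(seeds["annotations"] + 1)
            targets = np.round(feature_rng.uniform(-0.8, 0.8, config.n_features), 3)
            feature_maps, _ = synth.generate_feature_maps(
                config.n_features, nv, targets, seed=seeds["annotations"] + 2
            )
            bundle = synth.AnnotationBundle(
                parcellation=parcellation,
                term_maps=term_maps,
                feature_maps=feature_maps,
                term_names=[f"term{i}" for i in range(config.n_terms)],
                feature_names=[f"feature{i}" for i in range(config.n_features)],
            )
        bundle.validate()
        for key, p in synth.write_annotations(bundle, outdir).items():
            record(f"annotations_{key}", Path(p))

    # --- residualize / network -------------------------------------------
    with stage("residualize"):
        residuals = covnet.residualize(cohort)

    with stage("network"):
        network = covnet.covariance_network(residuals)
        net_path = outdir / "network.tsv"
        _write_tsv(pd.DataFrame(network.rho), net_path)
        record("network", net_path)

    # --- gradients --------------------------------------------------------
    with stage("gradients"):
        n_landmarks = config.n_landmarks
        if n_landmarks is None:
            n_landmarks = min(gradients.DEFAULT_N_LANDMARKS, cohort.n_vertices)
        landmarks = gradients.select_landmarks(
            cohort.n_vertices, n_landmarks, seed=seeds["gradients"]
        )
        conn = gradients.landmark_connectivity(residuals, landmarks)
        gradient_set = gradients.approximate_gradients(
            conn, config.gradient_k, landmarks=landmarks
        )
        grad_path = outdir / "gradients.tsv"
        _write_tsv(
            pd.DataFrame(
                gradient_set.scores,
                columns=[f"gradient{i + 1}" for i in range(gradient_set.k)],
            ),
            grad_path,
        )
        record("gradients", grad_path)
        meta_path = outdir / "gradients.json"
        meta_path.write_text(
            json.dumps(
                {
                    "k": gradient_set.k,
                    "n_landmarks": int(landmarks.n_landmarks),
                    "landmark_seed": int(landmarks.seed),
                    "landmark_indices": landmarks.indices.tolist(),
                    "variance_explained": gradient_set.variance_explained.tolist(),
                },
                indent=2,
                sort_keys=True,
            )
        )
        record("gradients_meta", meta_path)

    # --- strength ---------------------------------------------------------
    with stage("strength"):
        strengths = covnet.strength_maps(network)
        strength_path = outdir / "strength.tsv"
        _write_tsv(
            pd.DataFrame(
                {
                    "negative": strengths.negative,
                    "positive": strengths.positive,
                    "full": strengths.full,
                }
            ),
            strength_path,
        )
        record("strength", strength_path)

    vertex_maps = {
        f"gradient{i + 1}": gradient_set.scores[:, i] for i in range(gradient_set.k)
    }
    strength_named = {
        "strength_negative": strengths.negative,
        "strength_positive": strengths.positive,
        "strength_full": strengths.full,
    }

    # --- class profiles ---------------------------------------------------
    with stage("profiles"):
        rows = []
        n_classes = int(bundle.parcellation.max())
        for name, values in {**vertex_maps, **strength_named}.items():
            profile = profiles.class_profile(values, bundle.parcellation, n_classes)
            rows.append(
                [name, *profile.means.tolist(), profile.dispersion]
            )
        prof_df = pd.DataFrame(
            rows,
            columns=["map", *[f"class{i + 1}" for i in range(n_classes)], "dispersion"],
        )
        prof_path = outdir / "class_profiles.tsv"
        _write_tsv(prof_df, prof_path)
        record("class_profiles", prof_path)

    # --- decoding ---------------------------------------------------------
    with stage("decode"):
        frames = []
        for name, values in {**vertex_maps, **strength_named}.items():
            table = profiles.decode_terms(
                values, bundle.term_maps, term_names=bundle.term_names or None
            )
            table.insert(0, "map", name)
            frames.append(table)
        decode_path = outdir / "decoding.tsv"
        _write_tsv(pd.concat(frames, ignore_index=True), decode_path)
        record("decoding", decode_path)

    # --- feature correlations --------------------------------------------
    with stage("features"):
        grad_report = profiles.correlate_features(
            vertex_maps,
            bundle.feature_maps,
            feature_names=bundle.feature_names or None,
            alpha=config.alpha,
            m=config.feature_family,
        )
        strength_report = profiles.correlate_features(
            strength_named,
            bundle.feature_maps,
            feature_names=bundle.feature_names or None,
            alpha=config.alpha,
            m=config.feature_family,
        )
        feat_path = outdir / "feature_correlations.tsv"
        _write_tsv(
            pd.concat(
                [grad_report.table, strength_report.table], ignore_index=True
            ),
            feat_path,
        )
        record("feature_correlations", feat_path)

        gs_report = profiles.gradient_strength_matrix(
            gradient_set, strengths, alpha=config.alpha
        )
        gs_path = outdir / "gradient_strength.tsv"
        _write_tsv(gs_report.table, gs_path)
        record("gradient_strength", gs_path)

    # --- graphlets --------------------------------------------------------
    with stage("graphlets"):
        catalog = graphlets.build_catalog()
        rows = []
        for t in config.thresholds:
            graph = graphlets.threshold_graph(network, t)
            edge_path = outdir / f"graph_t{t:+.2f}.tsv".replace("+", "p").replace(
                "-", "m"
            )
            graphlets.write_edgelist(graph, edge_path)
            record(f"graph_{t:+.2f}", edge_path)
            method = config.census_method
            if method == "auto":
                # desk-scale guardrail: exact counting only when the rough
                # enumeration-size estimate (sum of degree^4, an upper proxy
                # for the number of 5-node connected subgraphs) stays within
                # budget and the edge count is moderate
                degrees = np.bincount(graph.edges.ravel(), minlength=graph.n_nodes)
                estimate = float(np.sum(degrees.astype(float) ** 4))
                method = (
                    "exact"
                    if graph.n_edges <= config.census_max_edges
                    and estimate <= config.census_max_subgraphs
                    else "sampled"
                )
                logger.info(
                    "threshold %+0.2f: %d edges (est %.2g subgraphs) -> %s census",
                    t, graph.n_edges, estimate, method,
                )
            if method == "exact":
                census = graphlets.census_exact(
                    graph, catalog, max_subgraphs=config.census_max_subgraphs
                )
            else:
                census = graphlets.census_sampled(
                    graph,
                    catalog,
                    n_samples=config.census_n_samples,
                    seed=seeds["graphlets"],
                )
            normalized = graphlets.normalize_census(census)
            for i in range(graphlets.N_CLASSES):
                rows.append(
                    [
                        t,
                        f"G{i}",
                        census.counts[i],
                        normalized.fstar[i],
                        census.standard_errors[i]
                        if census.standard_errors is not None
                        else 0.0,
                    ]
                )
        census_path = outdir / "graphlet_census.tsv"
        _write_tsv(
            pd.DataFrame(
                rows, columns=["threshold", "graphlet", "count", "fstar", "se"]
            ),
            census_path,
        )
        record("graphlet_census", census_path)

    config.to_yaml(outdir / "config.yaml")
    record("config", outdir / "config.yaml")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    manifest.verify(outdir)
    return manifest
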