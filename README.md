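# mcnet

Vertex-level structural covariance network analysis for cortical
myelin-proxy maps (or any subject-by-vertex measurement), built around six
stages:

1. **synth** — synthetic cohorts: subject × vertex matrices with planted
   orthonormal component patterns, confound effects (age, age², gender,
   age × gender), plus parcellations, term-map banks and feature maps with
   planted correlations. Everything downstream is testable offline.
2. **covnet** — per-vertex OLS residualization against the confound
   design, vertex × vertex Pearson covariance network, and signed
   per-vertex strength maps (negative / positive / full, no thresholding;
   `full = positive + negative` exactly).
3. **gradients** — principal gradients of the network via a landmark
   approximation: correlate every vertex against a random landmark subset
   only, row-center the profiles, and take the top singular components.
   A full-matrix decomposition with identical conventions serves as the
   oracle; sign fixing and component alignment utilities included.
4. **profiles** — parcellation-class means and across-class dispersion
   (sample n−1 standard deviation), term-map decoding on jointly non-zero
   vertices, feature-map correlations with Bonferroni flagging, Holm
   step-down adjustment, and the gradient × strength correlation matrix.
5. **graphlets** — signed thresholding (ρ ≤ t for t < 0, ρ ≥ t for t > 0),
   the 30-class catalog of connected 2–5-node graphs (G0–G29), an exact
   induced-subgraph census (enumeration + canonical-form classification),
   an unbiased lift-and-reweight sampled census with standard errors, and
   the log-normalization `f* = log10(1 + (f+1)/Σ(f+1))`.
6. **pipeline / CLI** — YAML-configured orchestration with per-stage
   seeds, TSV/JSON outputs, and a checksummed run manifest; optional
   CIFTI-2 dscalar / GIFTI metric read adapters.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: worked
dispersion/additivity examples, the graphlet-catalog and census oracle
battery, landmark-gradient recovery, the qualitative star-vs-path
dissociation of thresholded networks, and the statistical contracts.

## CLI

```sh
mcnet simulate --n-subjects 120 --n-vertices 150 --outdir out
mcnet covnet --myelin out/cohort_myelin.tsv --covariates out/cohort_covariates.tsv --outdir out
mcnet gradients --myelin out/cohort_myelin.tsv --covariates out/cohort_covariates.tsv --k 3 --outdir out
mcnet profile --vertex-map out/gradients.tsv --parcellation parc.tsv
mcnet decode --vertex-map map.tsv --term-maps terms.tsv --top 30
mcnet graphlets --network out/network.tsv --threshold -0.2 --threshold 0.2
mcnet run-all --config config.yaml --seed 1
```

A config file mirrors `mcnet.pipeline.PipelineConfig`; defaults follow the
reference analysis (3 gradients, `min(3000, n_vertices)` landmarks,
thresholds −0.4, −0.2, 0.2, 0.4, α = 0.05 with a 30-pair feature family).
Rerunning the same config and seed reproduces every numeric output
bit-for-bit.

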