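# v1drift

Encoding-model based analysis of representational drift across scanning
sessions, runnable end to end on synthetic multi-session data with known
ground truth.

The pipeline fits an image-computable spectral encoding model (steerable
pyramid features sampled through per-voxel Gaussian receptive fields,
per-voxel OLS) independently on every session, then quantifies how well
each session's model predicts every other session:

* **Cross-session generalization** — sessions × sessions goodness-of-fit
  matrices under two metrics: cross-validated R² (sensitive to baseline
  and gain changes) and Pearson correlation (insensitive to them).
* **Drift statistic** — correlation between off-diagonal matrix cells and
  the number of intervening sessions, averaged across subjects, with a
  session-order permutation test for significance.
* **Normalization interventions** — per-session mean subtraction and
  per-session variance equalization localize drift to mean-response
  changes versus variance changes.
* **Population analyses** — per-image cross-session similarity of
  simulated population responses, and within-session representational
  dissimilarity matrices (RDMs) whose cross-session Spearman stability is
  tested the same way.
* **Tuning simulation** — a 1-D Gaussian tuning curve demonstrating that
  only an additive baseline change moves the mean response without moving
  its SD.
* **Synthetic data** — a generator for multi-subject, multi-session
  experiments with configurable drift processes (correlated baseline
  random walk, gain walk, tuning jitter) and full seed provenance, so
  every statistic can be validated against ground truth.

## Layout

| module | contents |
| --- | --- |
| `v1drift.pyramid_features` | stimulus preparation (grayscale, 425→714 upsample, gray-pad to 1024, downsample to 512), frequency-domain complex steerable pyramid (8 orientations × 7 levels + 2 residuals = 58 channels), pRF sampling, design matrices |
| `v1drift.encoding` | per-voxel OLS, prediction, cvR² and Pearson goodness of fit |
| `v1drift.drift` | GOF matrices, interval profiles, drift statistic, permutation test, normalization interventions, session-series statistics |
| `v1drift.population` | simulated population responses, image-similarity matrices, RDMs and RDM stability |
| `v1drift.tuning_sim` | Gaussian tuning curve, moments, parameter sweep |
| `v1drift.synthetic_data` | image library (1/f noise), ground-truth voxels, experiment generator (feature-level fast path and image-level slow path) |
| `v1drift.cli_io` | run configuration, persistence, stage orchestration, CLI |

## CLI

End-to-end run on synthetic data (writes GOF/similarity/RDM matrices as
CSV, permutation nulls, a tuning sweep table, and a plain-text report):

```sh
v1drift run --out runs/demo --seed 1
```

With a YAML configuration (all `RunConfig` fields are accepted; see
`v1drift.cli_io.RunConfig`):

```yaml
# cfg.yaml
seed: 1
n_subjects: 2
n_sessions: 10
n_voxels: 200
images_per_session: 100
noise_sd: 1.0
drift:
  baseline_walk_sd: 0.5
  baseline_corr: 0.5
normalization: none   # none | subtract_mean | normalize_variance
n_perm: 1000
```

```sh
v1drift run --config cfg.yaml --out runs/demo
```

Individual stages (`simulate`, `fit`, `drift`, `population`, `report`)
operate on an existing run directory; `tuning-sim` is standalone.

Real-data ingestion is an extension point: any beta table plus pRF table
matching the `BetaPanel` / `PRF` schemas can be fed to the same drift and
population machinery.

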