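# tosmat

Threshold-overlap-score (TOS) analysis of two-channel microscopy signals:
a rank/threshold-based colocalization metric, the 9×9 TOS-matrix protocol,
the common comparison metrics it is benchmarked against, simulation designs
for calibrating and stress-testing the metrics, and ROC-based classifier
evaluation — as a tested library and CLI.

## What it computes

For a cell (a pair of equal-length pixel-intensity vectors) and a pair of
*selected fractions* (the top fraction of pixels by intensity rank in each
channel):

1. the observed fractional area of overlap (AO) between the two selected
   pixel sets,
2. the AO ratio — observed AO over its expectation under a uniform,
   independent null (expected AO₁ equals the other channel's selected
   fraction),
3. TOS — the AO ratio linearly rescaled so the analytic minimum, the null
   and the analytic maximum map to −1, 0 and +1 at every fraction pair.

Evaluating TOS over the default 9×9 grid of fraction pairs (0.9 → 0.1,
step 0.1; fraction 1.0 excluded) gives a TOS matrix with three scalar
features: `tos_h` (score at the lowest fraction pair, i.e. the highest
thresholds), `tos_max` and `tos_min` (grid extrema). Scores above/below a
configurable band (default ±0.1) are classified as colocalization /
anti-colocalization; the closed band is non-colocalization.

Also included:

- **`tosmat.compare`** — Pearson, Spearman, Manders M1/M2 at
  Costes-selected thresholds (minimum below-threshold-correlation scan
  along the inter-channel regression line), and the chance-corrected
  M1diff/M2diff.
- **`tosmat.simulate`** — three synthetic-cell designs: uniform null,
  two-population mixtures with stepwise mean shifts, and
  condition-positive/negative populations (off-target slope θ = e^q,
  multiplicative Gaussian noise σ = 0.2) for ROC benchmarking.
- **`tosmat.evaluate`** — two-tailed Mann–Whitney U, histogram edges
  (Scott's rule or fixed increments), ROC curves/AUC per metric with
  per-metric exclusion of undefined values.
- **`tosmat.image_io`** — per-cell pixel extraction from single-plane
  grayscale TIFFs using ImageJ ROIs (`.roi`/`.zip`, polygon dialects; a
  minimal reader/writer is bundled) or integer count-mask TIFFs, with
  object-size filters (default 400–5000 px) and an optional
  background-mean check.
- **`tosmat.report` / `tosmat.cli`** — cohort aggregation (element-wise
  median matrices, p10/median/p90 per metric), CSV/JSON/heat-map export.

## CLI

```sh
tosmat simulate-null    --seed 1 --out out/null --n-cells 200 --n-pixels 500
tosmat simulate-two-pop --seed 1 --out out/twopop --pop1-correlation negative
tosmat simulate-roc     --seed 1 --out out/roc --n-slopes 15 --cells-per-slope 10
tosmat analyze-images   --channel1 c1.tif --channel2 c2.tif \
                        --rois rois.zip --out out/images
```

Common flags: `--seed`, `--out`, `--fractions start:stop:step` (default
`0.9:0.1:0.1`), `--band` (non-colocalization half-width, default 0.1), and
`--config file.yaml` (precedence: CLI > file > defaults). Every run writes
`cell_metrics.csv`, `median_matrix.csv`/`.png`, a `cohort_summary.json`,
mode-specific outputs (`roc_curves.csv`, `roc_summary.json`,
`sweep_manifest.json`) and a `run_log.json` with the resolved config, seed
and library versions. Reruns with identical config and seed are
byte-identical.

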