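# lymphoquant

Density-map lymphocyte detection on IHC tiles, with slide-level immune
quantification and topological introspection of the detector's deep
features. The package is a complete desk-scale pipeline:

- **`simtiles`** — synthetic DAB-stained (brown-blob) tile and multi-slide
  cohort generation with exact ground-truth centers and leakage-safe,
  slide-grouped train/test/CV splits.
- **`density`** — Gaussian density-map regression targets from point
  annotations (unit-mass kernel: map mass = object count).
- **`nn`** — a five-stage encoder-decoder density regressor with
  concurrent spatial/channel squeeze-and-excitation (scSE) attention in
  the decoder, implemented on a small NumPy reverse-mode autograd engine
  (no deep-learning framework required). Includes pixel-wise MSE
  training with Adam, a plateau LR scheduler (factor 0.2, patience 10),
  epoch checkpoints, and hidden-feature extraction from six designated
  inner blocks.
- **`postprocess`** — density map → cell centers: negative clipping, Otsu
  thresholding (256 bins), watershed splitting of dense components
  (seeds = local density maxima, min separation 8 px), density-weighted
  centers of mass.
- **`metrics`** — Hungarian-matched detection scoring (strict 8-px gate,
  precision/recall/F1) and ordinal 7-class count classification
  (MAE/MSE/ACC, quadratically weighted Cohen's kappa, multiclass MCC),
  plus a repeated slide-grouped cross-validation harness.
- **`quantify`** — tile geometry and the per-slide log density
  `L = ln((1/n) Σ c_i/A_i)`, with Pearson comparison against reference
  estimates.
- **`tda`** — Vietoris–Rips persistence (H0 via union-find, H1 via Z/2
  boundary reduction, both implemented from scratch), Betti curves,
  TwoNN intrinsic-dimension estimation, and UMAP+HDBSCAN clustering of
  flattened activations (b=4, 25 neighbors, min_dist 0, min cluster size
  5, min samples 16).
- **`cli` / `config` / `io`** — a `lymphoquant` command-line front end,
  YAML configuration with a stable hash, and CSV/VIA-2 JSON/PNG/npz
  round-tripping.

## CLI

All stages share one YAML config (see `lymphoquant.config.PipelineConfig`
for every knob) and a global `--seed`:

```bash
lymphoquant simulate --slides 8 --tiles 10 --seed 11   # tiles + annotations + manifest
lymphoquant targets --annotations out/annotations.csv  # density-map targets
lymphoquant train                                      # tiny preset, CPU
lymphoquant predict
lymphoquant detect
lymphoquant evaluate                                   # detection + count metrics
lymphoquant quantify                                   # per-slide L
lymphoquant tda --block dec3                           # ID estimate, Betti curve, clusters
lymphoquant report
```

Outputs land in the configured output directory (`lymphoquant_out` by
default). Coordinates are 0-based with x = column, y = row, matching
VIA point exports.

## Notes

- The `tiny` encoder preset (<100k parameters) exists for CPU-scale
  training and tests; `standard` carries the reference decoder widths
  256/128/64/32/16.
- The F1 score is the standard harmonic mean 2PR/(P+R).
- TwoNN's default estimator is the CDF line fit through the origin on
  the smallest 90% of neighbor ratios; `method="mle"` gives the
  closed-form Pareto maximum likelihood `m / Σ log μ_i`.
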