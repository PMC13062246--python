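# Methods

This note documents the models and procedures `lactopath` implements, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design decisions taken where the problem left room.

## Signature scoring and stratification

**ssGSEA.** For one sample, genes are ranked by expression (descending,
ties by stable gene order). With in-set weights `|r_g|^alpha` (where `r_g`
is the gene's ascending rank value in that sample, `alpha = 0.25`) and
uniform out-of-set weights, the score is the sum over all rank positions of
the difference between the weighted in-set ECDF and the out-of-set ECDF.
Two consequences are load-bearing and tested: the score depends on a
sample's values only through their ranks (invariance to strictly monotone
transforms), and it agrees with an independent implementation (gseapy) to
four decimals. No cross-sample rescaling is applied; input must already be
normalized (log-scale TPM or similar) — the scale does not matter, the
ranks do. Genes missing from the matrix are dropped from the set with a
warning; a set covering every measured gene is rejected because the
out-of-set ECDF would be empty.

**Preranked GSEA.** The enrichment score is the signed maximum deviation of
the weighted Kolmogorov–Smirnov running sum (weight exponent 1.0 on the
absolute ranking statistic). The null is built by permuting set membership
over genes; NES divides ES by the mean |ES| of same-sign permutations; the
p-value is the same-sign tail proportion with +1 smoothing, so it is never
exactly zero. Under a null ranking these p-values pass a KS test against
U(0,1) (asserted over 500 replicates).

**Stratification.** `k = max(1, floor(fraction*n))` samples become LAC_H
and LAC_L (default `fraction = 0.33`; with 500 samples, 165 per group).
The `max(1, ·)` guard keeps tiny cohorts (n = 3) usable. Ties at a group
boundary are broken by stable sample-id sort: within a tied score,
lexicographically earlier ids fall in the lower group — arbitrary, but
deterministic and documented. Signature deltas are reported as
`mean(LAC_H) − mean(LAC_L)`; both reporting conventions exist in practice,
so a `high_minus_low` flag flips the sign. The p-value is a two-sided
Wilcoxon rank-sum with tie and continuity correction (normal
approximation), which matches the exact enumeration to ~0.02 at n = 8+8.

## Survival

Kaplan–Meier estimation is delegated to `lifelines`. The two-group log-rank
statistic is computed in-package from the observed-minus-expected summation
over distinct event times — it must be evaluated at every candidate
cutpoint and under score permutations, so a vectorized implementation was
needed — and agrees with `lifelines.statistics.logrank_test` to 1e-9.
Censored observations at an event time are counted as at risk for that
time's events (censorings after events).

**Maximally selected cutpoints.** Every distinct score value whose induced
low-group (`score <= cut`) proportion lies in `[minprop, maxprop]`
(defaults 0.2/0.8) is evaluated; the maximizing cutpoint is returned, ties
toward the lower cutpoint. Because the cutpoint maximizes the statistic,
the naive chi-square p-value is anti-conservative; the implementation
reports it as `p_value_naive` and offers a permutation-adjusted p-value
(`n_permutations` label permutations of the score vector, +1 smoothing,
seeded). Which small-sample approximation original maxstat software would
apply is not modeled; the permutation option is the package's answer.

## Histology preprocessing

Tiling is a strict partition: `floor(H/512) × floor(W/512)` non-overlapping
tiles in row-major order, partial border tiles discarded (no padding).
Background is a pure function of the pixels: by default a tile whose mean
ITU-R 601 gray value exceeds 216 is dropped; a saturation rule
(mean HSV saturation below a threshold, default 0.08) is available since
"brightness" and "saturation" rules differ only on unusual tiles.

**Stain model.** RGB is mapped to optical density
`OD = −ln((I+1)/256)`; Beer–Lambert makes stain mixing approximately
linear there. The 3×2 stain matrix `W` (unit-norm non-negative columns)
and non-negative concentrations `H` are fit by sparse NMF — multiplicative
updates with an L1 penalty (`lambda = 0.1`) on concentrations, 50
iterations, initialized from canonical H&E vectors with seeded jitter, `W`
columns renormalized each round with the inverse rescaling applied to `H`
so the product is unchanged. Hematoxylin is the column with the larger
blue-channel OD loading. The concentration scale is the per-stain 99th
percentile, a robust intensity reference. Pixels with OD norm below 0.15
are treated as unstained and excluded; an image with fewer than 100
stained pixels raises a "no stain content" error. Fitting subsamples at
most 20,000 tissue pixels (seeded) for speed. Normalization recomposes a
tile's concentrations — rescaled per stain by the target/source scale
ratio — through the target stain matrix. On synthetic two-stain images the
fitted vectors reach cosine ≥ 0.99 against truth, and re-estimating the
stains of a normalized tile recovers the target at cosine ≥ 0.98.

## Slide aggregation (MIL)

The featurizer is an interface: any callable mapping tile images to
(n, 768) arrays, so an external pretrained pathology backbone can plug in.
The default backend is a deterministic handcrafted extractor — per-channel
and gray histograms, channel moments, Sobel gradient statistics, gray
quantiles — projected to 768 dimensions by a fixed seeded Gaussian matrix.
It is a pure per-tile function, so batch size provably cannot change
results (asserted), and it is intentionally not brightness-invariant.

The aggregator is a transformer encoder written in numpy with explicit
backpropagation (gradient-checked against central differences at 1e-4
relative tolerance): 768→512 linear + ReLU per patch, learnable CLS token
prepended, two pre-norm layers of 4-head self-attention (128-d subspaces)
with feed-forward width 2048, residual connections and layer norm, final
layer norm, CLS state as the 512-d slide embedding. No positional
encodings are used: a bag of tiles has no canonical order, so the encoder
is exactly permutation-invariant over patches (asserted numerically at
1e-6). Training attaches a temporary logistic head on the CLS token and
minimizes binary cross-entropy with Adam (default lr 1e-3, global
gradient-norm clip 5.0, one bag per step, seeded shuffling); the head is
discarded afterwards. Training arithmetic runs in float32 (halves the
matrix-product cost), inference in float64; both are deterministic given
the seed. Both trained and frozen (seeded-random) encoders are supported —
a frozen encoder is already a usable random-features aggregator.

Slide embeddings are reduced with centered PCA to 128 components, capped
at `min(k, m−1, 512)` with a warning. The reducer is fit on training
slides only and applied to held-out slides to avoid leakage; the same
discipline applies to LASSO and the classifiers.

## Classification and the integrated score

LASSO feature selection defaults to L1-penalized logistic regression over
a 25-point regularization path chosen by stratified cross-validation
(negative log-loss); a linear lasso mode exists, and `alpha = 0` in that
mode reproduces the ordinary least-squares solution (checked against the
normal equations). If the selected penalty zeroes every coefficient, the
weakest penalty with at least one nonzero coefficient is used, with a
warning — feature selection must return something for the pipeline to
continue.

The ensemble is a registry of four seeded probabilistic classifiers:
XGBoost, scikit-learn gradient boosting, LightGBM and an RBF SVM with
built-in Platt calibration. Any mapping of name → estimator with `fit` and
`predict_proba` can replace the registry. Tree-model defaults are sized
for desk-scale cohorts (200 trees, depth 3; LightGBM `min_child_samples=5`
because cohorts here are tens of slides, not thousands). The integrated
lactate score is the unweighted sum of the four class-1 probabilities,
bounded in [0, 4] with the bounds attained exactly at the vertex inputs.

Evaluation: AUROC (the Mann–Whitney pair statistic with 0.5 tie credit),
decision-curve net benefit `TP/n − (FP/n)·pt/(1−pt)` with treat-all and
treat-none references (thresholds 0.01–0.99 by 0.01), and threshold
metrics at either the Youden-optimal cutoff (scan over observed
probabilities plus an all-negative sentinel, ties toward the lower cutoff)
or a fixed 0.5. Cohort splitting is stratified with
`train = floor(0.75·n)` — 273 units give 204/69. Extreme-group calls use
`k = round(fraction·n)` per tail (110 units at 10% give 11/11).

## IHC quantification

`H = 1·%weak + 2·%moderate + 3·%strong`, range 0–300. Percentages may sum
to less than 100 (the remainder is the zero-intensity fraction, weight 0);
a sum above 100 is rejected. Group comparison reports medians and a
two-sided rank-sum p-value; tables are assumed already restricted to tumor
regions (upstream segmentation is out of scope).

## Synthetic data: what it emulates, and what it does not

The generators encode the qualitative structure the analysis assumes, with
effect sizes as package conventions (only the directions of these
contrasts are established, not their magnitudes):

- **Expression** (`ExpressionSimConfig`): 2000 genes × 200 samples;
  gene baselines N(5, 1) in log units, noise SD 1.0; a 59-gene signature
  (the curated lactate set size) shifted by `latent_effect` (default
  1.0 log-unit, ~1 noise SD) in latent-high samples; a 50-gene
  proliferation program coupled +1 and 50-gene immune and stromal programs
  coupled −1, matching the direction of microenvironment differences
  expected for high- vs low-lactate tumors.
- **Bags** (`BagSimConfig`): 60 slides of 80–120 patches. In embedding
  mode, patches come from class-conditional 768-d Gaussian mixtures
  (3 shared components, unit noise) whose class means differ by
  `morphology_effect` (default 2.0 SD) along one fixed direction. In image
  mode, high-lactate slides get dense uniform nucleus-like ellipses on a
  pale background ("compact/homogeneous") and low-lactate slides get small
  dark round cells plus fibrous streaks ("infiltrated/heterogeneous") —
  procedural drawings sufficient to exercise tiling, stain math and
  featurization, with no claim of histological realism.
- **Survival** (`SurvivalSimConfig`): exponential event times with hazard
  `h0·exp(logHR·score)`; defaults `h0 = 0.001`/day (~2-year median at
  score 0) and `logHR = 0.5` per score unit. Censoring is an independent
  Bernoulli(`censoring_rate`, default 0.3) mark with the censored time
  drawn uniformly within the latent event time — exact in expectation and
  independent of the score by construction.
- **IHC**: four intensity-class logits (negative, weak, moderate, strong)
  with Gaussian jitter, softmaxed to percentages of 100, so the simplex
  constraint holds by construction; the high group's strong logit is
  raised by `group_shift` (default 2.0).

Every generator is deterministic given its seed (byte-identical reruns).
What passing tests on these data show: the statistics are implemented
correctly, the pipeline recovers planted signal and stays at chance under
the null, and p-values are calibrated. What they do not show: performance
on real slides — scanner variation, batch effects, label noise,
within-slide heterogeneity and realistic morphology are all absent.

## Pipeline

`run_pipeline` executes the stages in dependency order under one
configuration whose numeric defaults are the workflow's standard values
(tile 512, brightness 216, tertile fraction 0.33, extremes 0.10,
128 components, cutpoint band [0.2, 0.8], 3:1 split). Per-stage seeds fan
out deterministically from the global seed via a seed sequence (kept below
2^31). Each stage's output files are SHA-256-hashed into a manifest;
rerunning an identical configuration reproduces identical hashes (HDF5
timestamps are disabled for this reason). Slides are attached to the
stratified LAC_H/LAC_L samples by class-matched pairing, so the imaging
arm sees the same latent truth as the expression arm. In small runs where
an extreme group has fewer than 3 members the IHC stage reports medians
without a rank-sum test.

## Known limitations

- The featurizer's handcrafted default is a stand-in interface
  implementation; representation quality on real tiles is far below a
  pretrained pathology backbone.
- The transformer trainer is plain Adam without dropout, early stopping or
  schedules; at desk scale (tens of bags) this is adequate and keeps runs
  deterministic, but it is not tuned for thousands of slides.
- Pyramidal WSI formats are not decoded; the tile reader expects plain
  images, with slide readers as an adapter point.
- Whether mid-tertile samples should be excluded from downstream modeling
  is left to the caller (the pipeline models the two extreme tertiles).
- Multiple slides per patient default to slide-level units; patient-level
  mean pooling is a caller decision.
- Test-scale choices (e.g. 60 slides × ~100 patches, 4 training epochs in
  the recovery experiments) are the package's desk-scale defaults for its
  own verification experiments.
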