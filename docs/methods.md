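# Methods

`radpipe` implements the standard workflow of a binary-outcome radiomics
study as a headless library plus CLI: feature extraction from image/ROI
volumes, feature-matrix preparation, exhaustive enumeration of candidate
modeling pipelines evaluated by cross-validation, and clinical-statistics
reporting. This note records the models, conventions and numerical choices,
and what the synthetic fixtures do and do not establish.

## Feature extraction

Features follow the IBSI (Image Biomarker Standardisation Initiative)
reference definitions throughout.

**Quantization.** All texture matrices operate on gray levels obtained by
equal-width binning of the in-ROI intensities into a fixed number of bins
(default 32) spanning `[min, max]` of the ROI; the maximum intensity falls
in the last bin, and a constant ROI collapses to a single level. A fixed
bin *count* (rather than fixed bin *width*) keeps the matrix dimension
bounded regardless of the intensity scale, and makes texture features
invariant to adding a constant to all intensities.

**Direction handling.** GLCM and GLRLM use the 13 unique direction vectors
of the 3-D 26-neighborhood (one per ± pair), accumulate raw counts per
direction, sum the counts over directions, and normalize once. Summation
(rather than per-direction feature averaging) is the single canonical
aggregation implemented; it is rotation-closed under axis permutations,
which the tests exercise with 90° rotations. When the ROI spans a single
voxel along some axis, the direction set drops that axis automatically, so
a one-slice ROI is handled with the 4 in-plane directions — thick-slice MR
data is effectively near-2-D and forcing out-of-plane offsets would count
nothing. GLCM accumulates symmetrically (each pair in both orders) at
distance 1 by default.

**GLSZM.** Zones are maximal 26-connected components of equal gray level
(scipy.ndimage labelling with a full 3×3×3 structuring element); rows index
gray level, columns zone size. Gray-level variance is
`GLV = Σ_{i,s} p(i,s)·(i − μ)²` with `μ = Σ i·p(i,s)`.

**Run percentage.** With direction-aggregated run counts, run percentage is
normalized per direction: `RP = n_runs / (n_ROI_voxels × n_directions)`, so
a single direction over a constant three-voxel strip gives 1/3.

**First order.** Percentiles use linear interpolation between closest ranks
(the convention is pinned because the 10th percentile and the interquartile
range `P75 − P25` are reportable model features). Variance and standard
deviation use the population (divide-by-N) convention, matching IBSI.
Entropy is computed on the quantized histogram.

**Shape.** Volume is voxel count × voxel volume; surface area comes from
counting exposed voxel faces scaled by the face areas of the (possibly
anisotropic) spacing. Face counting systematically overestimates the area
of smooth shapes, so sphericity `π^(1/3)·(6V)^(2/3)/A` is biased slightly
below 1 even for a perfect ball; the property tests assert only `≤ 1`. The
maximum 3-D diameter is the largest pairwise distance between
boundary-voxel centers in mm; above 2000 boundary voxels the sweep is
subsampled (deterministically) to bound the O(n²) cost.

**Feature count.** The default configuration emits 6 shape features plus 14
first-order, 7 GLCM, 9 GLRLM and 8 GLSZM features per image series. No
claim is made that this matches any particular extractor's default count;
the composition is configurable per family.

## Data preparation

The on-disk dialect is a UTF-8 CSV with the case index in the first column,
a binary `label` column, and numeric feature columns. Loading audits every
cell (null / non-numeric / infinite) into a report that drives one-call
removal of offending cases or features; invalid cells are kept as NaN, not
silently dropped. Categorical text is reported as invalid, never encoded
automatically.

**Stratified split.** Per class the training count is
`round((1 − test_fraction)·n_class)` — nearest integer, ties to even — with
membership from a seeded shuffle. This convention exactly reproduces a
177/75 split with 48 positive / 129 negative training cases from a
68-positive / 184-negative cohort at a 0.7 training fraction, which is the
pinned reference behavior.

**Balancing** applies to the training table only; a table marked as the
held-out test part is refused, since resampling test data would corrupt the
evaluation. Down/upsampling are seeded resampling without/with
replacement. SMOTE synthesises minority rows `x + u·(x_nn − x)` with
`u ~ U(0,1)` and `x_nn` among the k = 5 nearest minority neighbors
(Euclidean; k is the method's canonical default and configurable).
SMOTETomek removes, after SMOTE, every Tomek link (mutual nearest neighbors
of opposite class), dropping both members so class counts stay equal.
These resamplers are implemented directly in the package.

## Pipeline engine

A pipeline is one combination of normalizer × dimension reducer × feature
selector × feature count × classifier; the engine enumerates the Cartesian
product of the configured menus (normalizer-major stable order) and
cross-validates every combination on shared, seeded, stratified folds
(k = 5 or 10).

- Normalizers: z-score `(x−μ)/σ`, min-max `(x−min)/range`, and mean
  normalization defined as `(x−μ)/range` (the conventional meaning of the
  term). Constant features map to zero with a logged warning rather than
  NaN. Normalization statistics are computed inside each training fold and
  reapplied to the held-out fold — never on pooled data — to prevent
  leakage.
- Pearson-correlation filter: feature pairs are visited in a seeded random
  order and one member of any surviving pair with |r| > 0.9 is removed, the
  victim chosen by the same seeded stream; the post-condition (no surviving
  pair above threshold) and seeded determinism are the guaranteed contract,
  since any particular scan order is an arbitrary choice.
- PCA uses a deterministic sign convention (largest-magnitude loading
  positive).
- ANOVA ranking computes the two-group F = MS_between/MS_within with df
  (1, n−2), equal to the squared pooled-variance t statistic; zero
  within-group and zero between-group variance yields F = 0, zero within
  with nonzero between yields +inf (ranked first, logged).
- Relief is the classic single-nearest-hit/miss variant on internally
  min-max-scaled features (ReliefF behavior via `k_neighbors > 1`); weights
  are normalized by the iteration count (default: one pass per case,
  sampled with the seeded generator).
- RFE is an explicit loop — fit a linear estimator (default logistic
  regression), drop the smallest-|coefficient| feature, repeat — so the
  elimination order is recorded and reported as the selector score;
  agreement with scikit-learn's RFE support set is cross-checked in tests.
- Classifiers are scikit-learn estimators with pinned hyper-parameters and
  threaded seeds; every kind exposes a class-1 probability, and linear
  kinds (logistic regression, L1-logistic "lasso", linear SVM, LDA) expose
  per-feature coefficients for the report.
- If fewer features survive reduction than a spec requests, the count is
  clamped (and logged) so a grid sweep never aborts mid-run.

## Evaluation and selection

AUC is the Mann–Whitney identity (ties ½). Confidence intervals are
percentile bootstrap over 1000 class-stratified case resamples (stratified
resampling keeps every replicate two-class); the CI method is a deliberate
simple default. Accuracy/sensitivity/specificity are computed at the cutoff
maximizing Youden's J on the *training* scores — ties to the lowest cutoff
— and that cutoff is reused unchanged for validation and test data.

Models are ranked by mean validation AUC across folds (ties prefer fewer
features, then enumeration order). The AUC-versus-feature-count curve of
the best stage combination feeds the one-standard-error rule: with
`n* = argmax mean AUC` and `SE = sd(per-fold AUCs)/√k`, the selected count
is the smallest `n` with `mean(n) ≥ mean(n*) − SE(n*)`. Validation
statistics are reported both fold-averaged (used for ranking) and pooled
across folds (used for the validation ROC curve and cutoff metrics).

Test metrics are computed exactly once, for the single selected model; the
evaluator refuses to score any other pipeline on a dataset named `test`
unless forced, mirroring a single held-out evaluation protocol.

Every run persists a manifest (config snapshot, seeds, fold assignments,
enumerated specs, ranking, selected model id, tool version) plus per-model
interim results and the refit model artifact, so any model can be reloaded
for inspection and a run can be reproduced bit-for-bit given the same
inputs.

## Synthetic fixtures

Phantoms place a sphere or box lesion in a dark volume with constant,
checkerboard, Gaussian-noise or gradient texture — enough structure to pin
down quantization, matrix construction and shape geometry, but not MR
physics, partial-volume effects, registration error or anatomy. Feature
tables draw informative features from `Normal(±d/2, 1)` by class (default
d = 1.5, 5 informative among 50, 100 cases per class) and noise features
from `Normal(0, 1)`, with an optional equicorrelated block to exercise the
redundancy filter, and a 68/184 imbalance preset for split/balance tests.
Passing tests on these fixtures establish correctness of the computations
and the absence of information leakage; they do not establish that any
particular clinical signal is detectable in real images.

Problem sizes in the test and acceptance runs (200-case tables, 50
features, modest grids of ~12 pipelines, ≤16³ phantoms) are the package's
chosen desk-scale defaults; all generators scale to larger inputs through
their specs.

## Known limitations

- Binary classification only; no regression, multi-label or survival
  targets, and no model ensembling.
- No filtered-image (wavelet / Laplacian-of-Gaussian) features, DICOM
  reading, segmentation or registration.
- Bootstrap CIs are percentile-based; DeLong intervals are not implemented.
- The GLCM aggregation implements matrix summation over directions only;
  per-direction feature averaging would give slightly different values for
  non-uniform ROIs.
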