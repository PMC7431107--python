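# radpipe

Radiomics studies map quantitative features of a lesion's image region onto
a binary clinical outcome, and a typical study must decide between dozens of
reasonable modeling pipelines — which normalization, which redundancy
filter, which feature selector, how many features, which classifier. Picking
one combination by hand is arbitrary; `radpipe` makes the search explicit.
It extracts shape, first-order and texture features from image/ROI volumes,
prepares the feature matrix, **enumerates every combination of the
configured pipeline components**, evaluates each by stratified k-fold
cross-validation with fixed seeds, ranks the models by validation AUC, and
applies the one-standard-error rule to prefer the simplest model whose
score is statistically indistinguishable from the best.

It is aimed at radiologists and imaging researchers running binary-outcome
radiomics analyses (e.g. distinguishing clinically significant from
non-significant prostate cancer on multiparametric MR), headlessly and
reproducibly.

## What it computes

- **Features** (IBSI definitions): shape (volume, surface area, sphericity,
  maximum 3-D diameter), first-order histogram statistics (including the
  10th percentile and interquartile range), and the three texture families
  — gray level co-occurrence matrix (GLCM, e.g. autocorrelation
  Σ i·j·p(i,j)), gray level run length matrix (GLRLM), and gray level size
  zone matrix (GLSZM, e.g. gray-level variance Σ p(i,s)(i−μ)²) — from
  quantized ROI intensities, aggregated over the 13 unique 3-D directions.
- **Preparation**: cell-level validity audit with a log, one-call removal
  of invalid cases/features, stratified train/test split preserving the
  class ratio, and class balancing (down/upsampling, SMOTE, SMOTETomek) of
  the training part only.
- **Model search**: pipelines are the Cartesian product of
  {min-max, z-score, mean} normalization × {Pearson-correlation filter at
  |r| > 0.9, PCA, none} × {ANOVA-F, Relief, RFE, none} × feature count ×
  ten classifiers (logistic regression, LASSO, SVM, LDA, decision tree,
  random forest, AdaBoost, Gaussian process, naive Bayes, MLP). Every stage
  is fit inside each training fold only — no statistic of a held-out fold
  ever enters a transform.
- **Statistics**: AUC (Mann–Whitney), 95% bootstrap confidence intervals,
  and accuracy/sensitivity/specificity at the training Youden cutoff; test
  data is scored once, for the selected model only.

## Worked example

Generate a synthetic 200-case table (5 informative features of standardized
mean difference 1.5 among 50), then split, search and report:

```sh
python -c "
from radpipe.fixtures import TableSpec, make_table
table, _ = make_table(TableSpec(n_positive=100, n_negative=100,
                                n_features=50, n_informative=5,
                                effect_size=1.5, seed=0))
table.save('features.csv')"

cat > config.yaml <<EOF
selectors: [anova, relief, rfe]
classifiers: [lda, logistic_regression]
feature_range: [1, 10]
k_folds: 5
seed: 42
EOF

radpipe prepare features.csv prep --test-fraction 0.3 --seed 42
radpipe run prep/train.csv run --config config.yaml
radpipe report run prep/train.csv --test-csv prep/test.csv --out-dir report
```

which prints:

```
train: 140 cases, test: 60 cases
evaluated 60 pipeline(s); best zscore_pcc_relief_6_logistic_regression (AUC 0.994); selected zscore_pcc_relief_5_logistic_regression
train: AUC=0.994 (95% CI 0.984-0.999)
test: AUC=0.989 (95% CI 0.957-1.000)
validation: AUC=0.992 (95% CI 0.968-0.996)
```

The 60 pipelines are the 3 selectors × 2 classifiers × feature counts 1–10.
The best validation AUC (0.994) needs 6 features, but the one-standard-error
rule selects the 5-feature model, whose mean validation AUC (0.992) is
within one SE of the best — a simpler model at no significant cost. The
report directory contains the ranked table (`results.csv`), ROC points per
dataset, the AUC-versus-feature-count curve, per-class values of the
selected features, and a plain-text model description listing the five
selected features (here exactly the five informative ones) with their
Relief weights and logistic coefficients. Extraction from NIfTI case
folders works the same way via `radpipe extract <root_dir> features.csv`.

Every run writes a `manifest.json` (seeds, fold assignments, enumerated
specs, ranking, selected model) from which any model can be reloaded, and
reruns with the same seed reproduce the ranking exactly.

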