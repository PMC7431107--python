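"""Pipeline enumeration and stratified cross-validation.

A pipeline is one concrete combination of
{normalizer x reducer x selector x feature count x classifier}. The engine
enumerates the Cartesian product of a per-stage menu and evaluates each
combination by stratified k-fold cross-validation in which every fitted
stage — normalization statistics included — is learned on the k-1 training
folds only and applied unchanged to the held-out fold, so no information
leaks from validation labels or values into the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import CLASSIFIERS, fit_classifier, linear_coefficients, predict_scores
from .metrics import roc_auc
from .preprocess import NORMALIZERS, REDUCERS, Normalizer, make_reducer
from .select import SELECTORS, anova_rank, relief_rank, rfe_rank
from .table import FeatureTable

log = logging.getLogger("radpipe.pipeline")


@dataclass(frozen=True)
class PipelineSpec:
    """One concrete pipeline configuration."""

    normalizer: str
    reducer: str
    selector: str
    n_features: int
    classifier: str
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalizer not in NORMALIZERS:
            raise ValueError(f"unknown normalizer {self.normalizer!r}")
        if self.reducer not in REDUCERS:
            raise ValueError(f"unknown reducer {self.reducer!r}")
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    @property
    def model_id(self) -> str:
        return (
            f"{self.normalizer}_{self.reducer}_{self.selector}"
            f"_{self.n_features}_{self.classifier}"
        )


def enumerate_pipelines(
    menu: dict[str, list[str]],
    feature_range: tuple[int, int] | list[int],
    seed: int = 0,
) -> list[PipelineSpec]:
    """Cartesian product of the stage menus and feature counts.

    ``menu`` maps 'normalizers', 'reducers', 'selectors', 'classifiers' to
    nonempty option lists; ``feature_range`` is an inclusive (n_min, n_max)
    pair or an explicit list. Order is stable and normalizer-major.
    """
    keys = ("normalizers", "reducers", "selectors", "classifiers")
    for key in keys:
        if not menu.get(key):
            raise ValueError(f"menu entry {key!r} must be a nonempty list")
    if isinstance(feature_range, tuple):
        counts = list(range(feature_range[0], feature_range[1] + 1))
    else:
        counts = list(feature_range)
    if not counts:
        raise ValueError("feature_range is empty")
    return [
        PipelineSpec(norm, red, sel, n, clf, seed)
        for norm, red, sel, clf, n in product(
            menu["normalizers"], menu["reducers"], menu["selectors"],
            menu["classifiers"], counts,
        )
    ]


@dataclass
class FittedPipeline:
    """All fitted stages of one pipeline plus the report artifacts."""

    spec: PipelineSpec
    normalizer: Normalizer
    reducer: object
    selected_features: list[str]          # names after reduction
    selector_scores: list[float]          # F-values / Relief weights / RFE rank
    selected_indices: np.ndarray = field(repr=False, default=None)
    classifier: object = field(repr=False, default=None)
    coefficients: np.ndarray | None = None  # per selected feature, linear kinds

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.normalizer.transform(X)
        Z = self.reducer.transform(Z)
        return Z[:, self.selected_indices]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(self.classifier, self.transform(X))


def _reduced_names(reducer, feature_names: list[str]) -> list[str]:
    kept = getattr(reducer, "kept_columns", None)
    if kept is not None:
        return [feature_names[i] for i in kept]
    n = reducer._pca.n_components_
    return [f"PC{k + 1}" for k in range(n)]


def fit_pipeline(
    spec: PipelineSpec, X: np.ndarray, y: np.ndarray, feature_names: list[str]
) -> FittedPipeline:
    """Fit every stage on (X, y) in order: normalize, reduce, select, classify.

    If fewer features survive reduction than ``spec.n_features`` requests,
    the count is clamped to what is available (logged), so a grid sweep over
    feature counts never aborts mid-run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    norm = Normalizer(spec.normalizer).fit(X)
    Z = norm.transform(X)
    reducer = make_reducer(spec.reducer, seed=spec.seed)
    Z = reducer.fit_transform(Z)
    names = _reduced_names(reducer, feature_names)
    n_avail = Z.shape[1]
    n_sel = spec.n_features
    if n_sel > n_avail:
        log.info("clamping n_features from %d to %d available", n_sel, n_avail)
        n_sel = n_avail
    if spec.selector == "anova":
        ranked = anova_rank(Z, y)[:n_sel]
        idx = [i for i, _ in ranked]
        scores = [s for _, s in ranked]
    elif spec.selector == "relief":
        ranked = relief_rank(Z, y, seed=spec.seed)[:n_sel]
        idx = [i for i, _ in ranked]
        scores = [s for _, s in ranked]
    elif spec.selector == "rfe":
        idx, eliminated = rfe_rank(Z, y, n_sel, seed=spec.seed)
        # score = elimination rank: later-surviving features rank higher
        rank_of = {f: r for r, f in enumerate(eliminated)}
        scores = [float(rank_of.get(f, len(eliminated))) for f in idx]
    else:  # none
        idx = list(range(n_sel))
        scores = [0.0] * n_sel
    indices = np.array(idx, dtype=int)
    Xs = Z[:, indices]
    clf = fit_classifier(Xs, y, spec.classifier, spec.seed)
    coefs = linear_coefficients(clf, spec.classifier)
    return FittedPipeline(
        spec=spec,
        normalizer=norm,
        reducer=reducer,
        selected_features=[names[i] for i in idx],
        selector_scores=scores,
        selected_indices=indices,
        classifier=clf,
        coefficients=coefs,
    )


@dataclass
class CvResult:
    """Cross-validation outcome for one pipeline."""

    spec: PipelineSpec
    fold_assignments: list[list[int]]      # validation indices per fold
    fold_scores: list[np.ndarray]          # predicted P(class 1) per fold
    fold_truth: list[np.ndarray]
    val_aucs: list[float]
    train_aucs: list[float]

    @property
    def mean_val_auc(self) -> float:
        return float(np.mean(self.val_aucs))

    @property
    def se_val_auc(self) -> float:
        k = len(self.val_aucs)
        return float(np.std(self.val_aucs, ddof=1) / np.sqrt(k))

    @property
    def mean_train_auc(self) -> float:
        return float(np.mean(self.train_aucs))

    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Validation scores and truth pooled over folds (each case once)."""
        return np.concatenate(self.fold_scores), np.concatenate(self.fold_truth)


def make_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignments from a seeded shuffle."""
    y = np.asarray(y)
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} cases")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(y)), y)]


def cross_validate(
    spec: PipelineSpec,
    table: FeatureTable,
    k: int = 5,
    seed: int = 0,
    folds: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation of one pipeline.

    Every stage is refit per fold on the training folds only. ``folds`` may
    be supplied to reuse one fold assignment across many pipelines (the run
    manifest persists it); otherwise folds come from ``make_folds``.
    """
    if k not in (5, 10) and folds is None:
        raise ValueError("k must be 5 or 10")
    X, y = table.X, table.y
    if folds is None:
        folds = make_folds(y, k, seed)
    assignments, scores_list, truth_list, val_aucs, train_aucs = [], [], [], [], []
    for tr, va in folds:
        fitted = fit_pipeline(spec, X[tr], y[tr], table.feature_names)
        val_scores = fitted.predict(X[va])
        train_scores = fitted.predict(X[tr])
        assignments.append([int(i) for i in va])
        scores_list.append(val_scores)
        truth_list.append(y[va])
        val_aucs.append(roc_auc(val_scores, y[va]))
        train_aucs.append(roc_auc(train_scores, y[tr]))
    return CvResult(spec, assignments, scores_list, truth_list, val_aucs, train_aucs)
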