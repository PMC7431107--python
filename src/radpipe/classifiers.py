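"""Classifier menu with a uniform probability-scoring contract.

Every kind yields a fitted scikit-learn estimator whose ``predict_proba``
returns a class-1 probability in [0, 1]; linear kinds additionally expose
per-feature coefficients for the model report. Random seeds are threaded
into every stochastic estimator so refits are reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIERS = (
    "logistic_regression",
    "lasso",
    "svm",
    "lda",
    "decision_tree",
    "random_forest",
    "adaboost",
    "gaussian_process",
    "naive_bayes",
    "mlp",
)

LINEAR_KINDS = ("logistic_regression", "lasso", "svm", "lda")


def make_classifier(kind: str, seed: int = 0):
    """Instantiate an unfitted classifier with pinned hyper-parameters."""
    if kind == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if kind == "lasso":
        # L1-penalized logistic scoring
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=1000, random_state=seed
        )
    if kind == "svm":
        return SVC(kernel="linear", probability=True, random_state=seed)
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if kind == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=1000, random_state=seed)
    raise ValueError(f"unknown classifier {kind!r}")


def fit_classifier(X: np.ndarray, y: np.ndarray, kind: str, seed: int = 0):
    """Fit one classifier; requires both classes in ``y``."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a classifier on a single-class sample")
    clf = make_classifier(kind, seed)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def predict_scores(clf, X: np.ndarray) -> np.ndarray:
    """Class-1 probability for each row."""
    proba = clf.predict_proba(np.asarray(X, dtype=float))
    pos_col = int(np.nonzero(clf.classes_ == 1)[0][0])
    return proba[:, pos_col]


def linear_coefficients(clf, kind: str) -> np.ndarray | None:
    """Per-feature coefficients for linear kinds, else None."""
    if kind in LINEAR_KINDS and hasattr(clf, "coef_"):
        return np.ravel(np.asarray(clf.coef_))
    return None
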