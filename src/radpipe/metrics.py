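"""Clinical statistics: ROC AUC, bootstrap confidence interval, and
threshold metrics at the Youden-optimal cutoff."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


def _check(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    Equals the probability a random positive outscores a random negative,
    with ties contributing 1/2 — identical to the trapezoidal area under
    the empirical ROC curve.
    """
    scores, labels = _check(scores, labels)
    return float(roc_auc_score(labels, scores))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the AUC.

    Cases are resampled with replacement stratified by class (so every
    resample keeps both classes and the class sizes); the interval is the
    (1 - level)/2 and (1 + level)/2 percentiles of the resampled AUCs.
    """
    scores, labels = _check(scores, labels)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 cases per class to resample")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, len(pos), replace=True), rng.choice(neg, len(neg), replace=True)]
        )
        aucs[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    A case is called positive when its score is >= the cutoff; ties in J
    resolve to the lowest cutoff.
    """
    scores, labels = _check(scores, labels)
    candidates = np.unique(scores)
    best_j, best_cut = -np.inf, candidates[0]
    for cut in candidates:  # ascending, so strict > keeps the lowest tie
        pred = scores >= cut
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j:
            best_j, best_cut = j, cut
    return float(best_cut)


def threshold_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    cutoff: float | None = None,
) -> dict[str, float]:
    """Accuracy, sensitivity and specificity at a cutoff.

    When ``cutoff`` is None it is chosen on these scores by Youden's rule;
    pass the training cutoff explicitly to evaluate validation or test data
    at the cutoff learned on training scores.
    """
    scores, labels = _check(scores, labels)
    if cutoff is None:
        cutoff = youden_cutoff(scores, labels)
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / int((labels == 1).sum()),
        "specificity": tn / int((labels == 0).sum()),
        "cutoff": float(cutoff),
    }


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC curve as an (n, 2) array of (FPR, TPR)."""
    scores, labels = _check(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])
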