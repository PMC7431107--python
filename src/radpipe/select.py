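"""Univariate and model-based feature ranking: ANOVA F, Relief, RFE.

Each ranker returns an ordered list of (feature_index, score) pairs,
best feature first, with ties broken by column order. The score is what
the final report shows for the selected features: an F-value for ANOVA,
a Relief weight, or the elimination rank for RFE.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.linear_model import LogisticRegression

log = logging.getLogger("radpipe.select")

SELECTORS = ("anova", "relief", "rfe", "none")


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def anova_rank(X: np.ndarray, y: np.ndarray) -> list[tuple[int, float]]:
    """One-way two-group ANOVA F per feature, descending.

    F = MS_between / MS_within with degrees of freedom (1, n - 2); this is
    the square of the pooled-variance two-sample t statistic. A feature with
    zero between- and within-group variance gets F = 0; zero within- but
    nonzero between-group variance gives +inf (ranked first, logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    n = len(y)
    g0, g1 = X[y == 0], X[y == 1]
    m, m0, m1 = X.mean(axis=0), g0.mean(axis=0), g1.mean(axis=0)
    ss_between = len(g0) * (m0 - m) ** 2 + len(g1) * (m1 - m) ** 2
    ss_within = ((g0 - m0) ** 2).sum(axis=0) + ((g1 - m1) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / 1.0) / (ss_within / (n - 2))
    F = np.where((ss_within == 0) & (ss_between == 0), 0.0, F)
    inf_mask = (ss_within == 0) & (ss_between > 0)
    if inf_mask.any():
        F = np.where(inf_mask, np.inf, F)
        log.warning("%d feature(s) with zero within-group variance (F=+inf)",
                    int(inf_mask.sum()))
    order = np.argsort(-F, kind="stable")
    return [(int(i), float(F[i])) for i in order]


def relief_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int | None = None,
    k_neighbors: int = 1,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Classic Relief feature weighting (k_neighbors > 1 gives ReliefF).

    Features are min-max scaled to [0, 1] internally. For each sampled case
    the nearest hit H (same class) and nearest miss M (other class) are
    found by Euclidean distance and each feature weight is updated by
    |x_f - M_f| - |x_f - H_f|, finally normalized by the iteration count.
    A feature identical across all cases scores 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError("each class needs at least 2 cases")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Z = (X - lo) / span
    n = len(y)
    rng = np.random.default_rng(seed)
    m = n_iterations if n_iterations is not None else n
    samples = rng.integers(n, size=m)
    d = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    w = np.zeros(X.shape[1])
    for i in samples:
        same = np.nonzero(y == y[i])[0]
        other = np.nonzero(y != y[i])[0]
        hits = same[np.argsort(d[i, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(d[i, other], kind="stable")[:k_neighbors]]
        w += np.abs(Z[i] - Z[misses]).mean(axis=0) - np.abs(Z[i] - Z[hits]).mean(axis=0)
    w /= m
    order = np.argsort(-w, kind="stable")
    return [(int(i), float(w[i])) for i in order]


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_features: int,
    base_estimator=None,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Recursive feature elimination with a linear base estimator.

    Repeatedly fits the estimator and drops the feature with the smallest
    coefficient magnitude (ties to the lowest column index) until
    ``n_features`` remain. Returns (selected_indices ordered by descending
    final |coefficient|, elimination_order — first-dropped first).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    p = X.shape[1]
    if n_features > p:
        raise ValueError(f"n_features={n_features} > available features {p}")
    if base_estimator is None:
        base_estimator = LogisticRegression(max_iter=1000, random_state=seed)
    remaining = list(range(p))
    eliminated: list[int] = []
    while len(remaining) > n_features:
        est = base_estimator.fit(X[:, remaining], y)
        coef = np.abs(np.ravel(est.coef_))
        drop_local = int(np.argmin(coef))
        eliminated.append(remaining.pop(drop_local))
    est = base_estimator.fit(X[:, remaining], y)
    coef = np.abs(np.ravel(est.coef_))
    order = np.argsort(-coef, kind="stable")
    selected = [remaining[i] for i in order]
    return selected, eliminated
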