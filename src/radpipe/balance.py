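"""Class balancing of the training table: down/upsampling, SMOTE, SMOTETomek.

Balancing is only meaningful (and only permitted) on the training part:
resampling a held-out test set would corrupt the evaluation, so a table
whose ``role`` is ``'test'`` is refused.

SMOTE synthesises minority points on segments between a minority case and
one of its k nearest minority neighbours: ``x_new = x + u * (x_nn - x)``
with ``u ~ Uniform(0, 1)``. SMOTETomek then removes Tomek links — pairs of
mutually-nearest neighbours with opposite labels — dropping both members of
each link, which preserves the class balance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .table import FeatureTable

METHODS = ("down", "up", "smote", "smotetomek")


def _check(table: FeatureTable) -> None:
    if table.role == "test":
        raise ValueError("refusing to balance a test table")
    neg, pos = table.class_counts()
    if neg == 0 or pos == 0:
        raise ValueError("balancing requires both classes present")
    if table.features.isna().any().any():
        raise ValueError("table has invalid cells; clean it before balancing")


def _smote_rows(
    X_min: np.ndarray, n_new: int, k_neighbors: int, rng: np.random.Generator
) -> np.ndarray:
    if len(X_min) <= k_neighbors:
        raise ValueError(
            f"SMOTE needs minority size > k_neighbors ({len(X_min)} <= {k_neighbors})"
        )
    d = np.sqrt(((X_min[:, None, :] - X_min[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k_neighbors]
    rows = np.empty((n_new, X_min.shape[1]))
    for r in range(n_new):
        i = int(rng.integers(len(X_min)))
        j = int(nn[i, rng.integers(k_neighbors)])
        u = rng.random()
        rows[r] = X_min[i] + u * (X_min[j] - X_min[i])
    return rows


def _tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    links = []
    for i in range(len(X)):
        j = int(nn[i])
        if j > i and nn[j] == i and y[i] != y[j]:
            links.append((i, j))
    return links


def balance(
    table: FeatureTable,
    method: str,
    seed: int,
    k_neighbors: int = 5,
) -> FeatureTable:
    """Return a class-balanced copy of the training table.

    down: subsample the majority without replacement to the minority size.
    up: resample the minority with replacement to the majority size.
    smote / smotetomek: synthetic minority oversampling as described above.
    Original rows are never modified; down/up/smote leave class counts
    exactly equal, smotetomek equal up to the removed links (one case of
    each class per link).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    _check(table)
    rng = np.random.default_rng(seed)
    y = table.labels
    neg, pos = table.class_counts()
    minority, majority = (1, 0) if pos < neg else (0, 1)
    min_idx = np.nonzero(y == minority)[0]
    maj_idx = np.nonzero(y == majority)[0]

    if method == "down":
        kept_maj = np.sort(rng.choice(maj_idx, size=len(min_idx), replace=False))
        keep = np.sort(np.concatenate([min_idx, kept_maj]))
        return table.subset(keep, role=table.role)

    if method == "up":
        extra = rng.choice(min_idx, size=len(maj_idx) - len(min_idx), replace=True)
        ids = list(table.case_ids)
        feats = table.features
        new_ids = [f"{table.case_ids[i]}_up{k}" for k, i in enumerate(extra)]
        out_feats = pd.concat(
            [feats, feats.iloc[extra].set_axis(new_ids)], axis=0
        )
        out_labels = np.concatenate([y, y[extra]])
        return FeatureTable(ids + new_ids, out_labels, out_feats, role=table.role)

    # smote / smotetomek
    X_min = table.features.iloc[min_idx].to_numpy(dtype=float)
    n_new = len(maj_idx) - len(min_idx)
    synth = _smote_rows(X_min, n_new, k_neighbors, rng)
    new_ids = [f"smote_{k}" for k in range(n_new)]
    out_feats = pd.concat(
        [table.features, pd.DataFrame(synth, index=new_ids, columns=table.feature_names)]
    )
    out_labels = np.concatenate([y, np.full(n_new, minority)])
    out = FeatureTable(
        list(table.case_ids) + new_ids, out_labels, out_feats, role=table.role
    )
    if method == "smote":
        return out
    links = _tomek_links(out.X, out.labels)
    drop = {i for pair in links for i in pair}
    keep = np.array([i for i in range(out.n_cases) if i not in drop])
    if keep.size == 0:
        raise ValueError("Tomek-link removal would empty the table")
    return out.subset(keep, role=table.role)
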