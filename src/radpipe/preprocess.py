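"""Feature normalization and dimension reduction.

Normalizers memorise per-feature statistics of the data they were fit on
and reapply them unchanged to new data, so no statistic of a validation or
test fold ever enters the transform. Degenerate features (zero spread) are
mapped to all-zeros and logged rather than producing NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

log = logging.getLogger("radpipe.preprocess")

NORMALIZERS = ("minmax", "zscore", "mean")
REDUCERS = ("pcc", "pca", "none")


@dataclass
class Normalizer:
    """(x - location) / scale with method-dependent statistics.

    zscore: location = mean, scale = population standard deviation.
    minmax: location = min, scale = max - min.
    mean:   location = mean, scale = max - min.
    """

    method: str
    location: np.ndarray | None = None
    scale: np.ndarray | None = None
    degenerate: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.size == 0 or X.shape[0] < 1:
            raise ValueError("cannot fit a normalizer on an empty matrix")
        if self.method == "zscore":
            self.location = X.mean(axis=0)
            self.scale = X.std(axis=0)
        elif self.method == "minmax":
            self.location = X.min(axis=0)
            self.scale = X.max(axis=0) - X.min(axis=0)
        elif self.method == "mean":
            self.location = X.mean(axis=0)
            self.scale = X.max(axis=0) - X.min(axis=0)
        else:
            raise ValueError(f"unknown normalizer {self.method!r}")
        self.degenerate = self.scale == 0
        if self.degenerate.any():
            log.warning(
                "%d constant feature(s) mapped to zero by %s normalization",
                int(self.degenerate.sum()), self.method,
            )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        scale = np.where(self.degenerate, 1.0, self.scale)
        out = (np.asarray(X, dtype=float) - self.location) / scale
        out[:, self.degenerate] = 0.0
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class PccReducer:
    """Redundancy filter on the Pearson correlation of feature pairs.

    Feature pairs are visited in a seeded random order; whenever both
    members of a pair still survive and their |r| exceeds the threshold,
    one of the two — chosen by the same seeded stream — is removed.
    Afterwards no surviving pair has |r| above the threshold, and a fixed
    seed makes the surviving set deterministic.
    """

    threshold: float = 0.9
    seed: int = 0
    kept_columns: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "PccReducer":
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        if p < 2:
            self.kept_columns = np.arange(p)
            return self
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
        rng = np.random.default_rng(self.seed)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        rng.shuffle(pairs)
        alive = np.ones(p, dtype=bool)
        for i, j in pairs:
            if alive[i] and alive[j] and abs(corr[i, j]) > self.threshold:
                alive[(i, j)[int(rng.integers(2))]] = False
        self.kept_columns = np.nonzero(alive)[0]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.kept_columns]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass
class PcaReducer:
    """Principal component analysis with a deterministic sign convention
    (the largest-magnitude loading of every component is made positive)."""

    n_components: int | None = None
    _pca: PCA | None = field(default=None, repr=False)
    _signs: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray) -> "PcaReducer":
        X = np.asarray(X, dtype=float)
        max_rank = min(X.shape[0] - 1, X.shape[1])
        n = self.n_components if self.n_components is not None else max_rank
        if n > max_rank:
            raise ValueError(f"n_components={n} exceeds rank bound {max_rank}")
        self._pca = PCA(n_components=n, svd_solver="full")
        self._pca.fit(X)
        comp = self._pca.components_
        pivot = np.abs(comp).argmax(axis=1)
        self._signs = np.sign(comp[np.arange(len(comp)), pivot])
        self._signs[self._signs == 0] = 1.0
        return self

    @property
    def loadings(self) -> np.ndarray:
        return self._pca.components_ * self._signs[:, None]

    @property
    def explained_variance(self) -> np.ndarray:
        return self._pca.explained_variance_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._pca.transform(np.asarray(X, dtype=float)) * self._signs

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


class IdentityReducer:
    """No-op reducer used when dimension reduction is switched off."""

    kept_columns: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "IdentityReducer":
        self.kept_columns = np.arange(np.asarray(X).shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def make_reducer(kind: str, seed: int = 0, threshold: float = 0.9):
    if kind == "pcc":
        return PccReducer(threshold=threshold, seed=seed)
    if kind == "pca":
        return PcaReducer()
    if kind == "none":
        return IdentityReducer()
    raise ValueError(f"unknown reducer {kind!r}")
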