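"""Synthetic volumes and feature tables with known ground truth.

Every generator is a pure function of its spec (seed included), so tests
and the acceptance script can reconstruct inputs bit-for-bit. Phantoms
emulate a lesion (sphere or box) on a dark background with a controllable
in-lesion texture; feature tables emulate a radiomics matrix with a known
informative subset, optional redundant blocks, and a class-imbalance preset
matching a 68-positive / 184-negative cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .table import FeatureTable
from .volume import CaseVolume

TEXTURES = ("constant", "checkerboard", "noise", "gradient")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (16, 16, 16)
    lesion: str = "sphere"  # sphere | box
    center: tuple[int, int, int] | None = None
    radius: int = 5
    texture: str = "constant"
    mu: float = 100.0
    sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = tuple(s // 2 for s in self.shape)
        if self.texture not in TEXTURES:
            raise ValueError(f"texture must be one of {TEXTURES}")
        for c, s in zip(self.center, self.shape):
            if c - self.radius < 0 or c + self.radius >= s:
                raise ValueError("lesion does not fit inside the volume")


def make_phantom(spec: PhantomSpec, spacing=(1.0, 1.0, 1.0)) -> CaseVolume:
    """Deterministic synthetic lesion volume + mask."""
    rng = np.random.default_rng(spec.seed)
    grid = np.indices(spec.shape)
    offset = grid - np.array(spec.center)[:, None, None, None]
    if spec.lesion == "sphere":
        mask = (offset**2).sum(axis=0) <= spec.radius**2
    elif spec.lesion == "box":
        mask = (np.abs(offset) <= spec.radius).all(axis=0)
    else:
        raise ValueError(f"unknown lesion geometry {spec.lesion!r}")
    image = np.zeros(spec.shape, dtype=float)
    if spec.texture == "constant":
        image[mask] = spec.mu
    elif spec.texture == "checkerboard":
        parity = grid.sum(axis=0) % 2
        image[mask] = np.where(parity[mask] == 0, spec.mu - spec.sigma, spec.mu + spec.sigma)
    elif spec.texture == "noise":
        image[mask] = rng.normal(spec.mu, spec.sigma, size=int(mask.sum()))
    elif spec.texture == "gradient":
        image[mask] = spec.mu + grid[0][mask].astype(float)
    return CaseVolume(f"phantom_seed{spec.seed}", image, mask, spacing)


def write_phantom_case(
    case_dir: Path | str,
    spec: PhantomSpec,
    image_name: str = "image.nii.gz",
    roi_name: str = "roi.nii.gz",
    spacing=(1.0, 1.0, 1.0),
) -> Path:
    """Materialize one phantom as a NIfTI case folder."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    vol = make_phantom(spec, spacing)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.image.astype(np.float32), affine), case_dir / image_name)
    nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), case_dir / roi_name)
    return case_dir


@dataclass
class TableSpec:
    """Synthetic feature-matrix recipe.

    Informative features are Normal(+d/2, 1) in the positive class and
    Normal(-d/2, 1) in the negative class, where d is the standardized mean
    difference ``effect_size``; the remaining features are Normal(0, 1)
    noise. ``block_rho``/``block_size`` optionally append an equicorrelated
    copy-block of the first noise feature to exercise the redundancy filter.
    """

    n_positive: int = 100
    n_negative: int = 100
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 1.5
    block_rho: float = 0.0
    block_size: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def make_table(spec: TableSpec) -> tuple[FeatureTable, list[str]]:
    """Generate a labeled feature table; returns (table, informative names)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positive + spec.n_negative
    y = np.concatenate([np.ones(spec.n_positive, int), np.zeros(spec.n_negative, int)])
    X = rng.normal(0.0, 1.0, size=(n, spec.n_features))
    shift = np.where(y == 1, spec.effect_size / 2, -spec.effect_size / 2)
    X[:, : spec.n_informative] += shift[:, None]
    names = [
        f"informative_{i}" if i < spec.n_informative else f"noise_{i}"
        for i in range(spec.n_features)
    ]
    if spec.block_size > 0:
        base = X[:, spec.n_informative] if spec.n_informative < spec.n_features else X[:, 0]
        rho = spec.block_rho
        extra = rho * base[:, None] + np.sqrt(1 - rho**2) * rng.normal(
            size=(n, spec.block_size)
        )
        X = np.hstack([X, extra])
        names += [f"block_{i}" for i in range(spec.block_size)]
    case_ids = [f"case_{i:04d}" for i in range(n)]
    features = pd.DataFrame(X, index=case_ids, columns=names)
    table = FeatureTable(case_ids, y, features)
    return table, names[: spec.n_informative]


def imbalanced_cohort(seed: int = 0, n_features: int = 20, effect_size: float = 1.0):
    """Preset mirroring the example cohort composition: 68 positive
    (clinically significant) versus 184 negative cases."""
    return make_table(
        TableSpec(
            n_positive=68, n_negative=184, n_features=n_features,
            n_informative=min(5, n_features), effect_size=effect_size, seed=seed,
        )
    )
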