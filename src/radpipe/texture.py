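"""Texture matrices (GLCM, GLRLM, GLSZM) and their scalar features.

All three matrix families follow the IBSI reference definitions. Matrices
are accumulated per spatial direction and aggregated by summing the raw
counts over directions before normalization. In 3-D there are 13 unique
direction vectors (one per +/- pair of the 26-neighborhood); when the ROI
occupies a single slice along some axis the directions collapse to the
in-plane subset, so thick-slice (near 2-D) data is handled in-plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import QuantizedRoi

# One canonical representative of each +/- direction pair in the
# 26-neighborhood: first nonzero component positive.
ALL_DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)
assert len(ALL_DIRECTIONS_3D) == 13


def roi_directions(mask: np.ndarray) -> tuple[tuple[int, int, int], ...]:
    """Direction set adapted to the ROI extent.

    Axes along which the ROI spans a single voxel are dropped from the
    direction vectors, which yields the 4 in-plane directions for a
    single-slice ROI and the full 13 otherwise.
    """
    idx = np.nonzero(mask)
    flat = [len(np.unique(ax)) == 1 for ax in idx]
    dirs = [d for d in ALL_DIRECTIONS_3D if not any(f and d[i] for i, f in enumerate(flat))]
    return tuple(dirs) if dirs else ALL_DIRECTIONS_3D[:1]


@dataclass
class TextureMatrix:
    """A raw count matrix and its normalized probability form."""

    family: str  # GLCM | GLRLM | GLSZM
    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError(f"empty {self.family} matrix")
        return self.counts / total


def _shifted_pairs(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int, int]):
    """Return (level_a, level_b) arrays for voxel pairs separated by offset,
    both inside the ROI."""
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, o in enumerate(offset):
        n = levels.shape[ax]
        if abs(o) >= n:
            return None
        if o >= 0:
            src[ax] = slice(0, n - o)
            dst[ax] = slice(o, n)
        else:
            src[ax] = slice(-o, n)
            dst[ax] = slice(0, n + o)
    a_mask = mask[tuple(src)] & mask[tuple(dst)]
    if not a_mask.any():
        return None
    return levels[tuple(src)][a_mask], levels[tuple(dst)][a_mask]


def glcm(
    q: QuantizedRoi,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] | None = None,
    symmetric: bool = True,
) -> TextureMatrix:
    """Gray level co-occurrence matrix.

    Counts pairs of gray levels at the given voxel distance along each
    direction, accumulated symmetrically (each pair counted in both orders)
    and summed over directions.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if directions is None:
        directions = roi_directions(q.mask)
    if not directions:
        raise ValueError("directions must be nonempty")
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in directions:
        offset = tuple(distance * c for c in d)
        pairs = _shifted_pairs(q.levels, q.mask, offset)
        if pairs is None:
            continue
        la, lb = pairs
        np.add.at(counts, (la - 1, lb - 1), 1)
        if symmetric:
            np.add.at(counts, (lb - 1, la - 1), 1)
    return TextureMatrix("GLCM", counts)


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    """Scalar GLCM features (IBSI definitions).

    Includes autocorrelation sum_ij i*j*p(i,j), contrast, correlation,
    energy (angular second moment), entropy (base 2) and homogeneity
    (inverse difference).
    """
    if m.family != "GLCM":
        raise ValueError("expected a GLCM matrix")
    p = m.normalized
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_x = float((i * px).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    py = p.sum(axis=0)
    mu_y = float((i * py).sum())
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))
    autocorrelation = float((ii * jj * p).sum())
    if sigma_x > 0 and sigma_y > 0:
        correlation = (autocorrelation - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 1.0  # degenerate single-level convention
    nz = p[p > 0]
    return {
        "autocorrelation": autocorrelation,
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": float(correlation),
        "energy": float((p**2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "joint_average": mu_x,
    }


def _runs_along(levels: np.ndarray, mask: np.ndarray, direction: tuple[int, int, int]):
    """Yield (gray_level, run_length) for maximal same-level runs along one
    direction."""
    shape = levels.shape
    d = np.array(direction)
    for start in zip(*np.nonzero(mask)):
        prev = tuple(np.array(start) - d)
        if (
            all(0 <= prev[ax] < shape[ax] for ax in range(3))
            and mask[prev]
            and levels[prev] == levels[start]
        ):
            continue  # not the head of a run
        level = levels[start]
        length = 1
        nxt = tuple(np.array(start) + d)
        while (
            all(0 <= nxt[ax] < shape[ax] for ax in range(3))
            and mask[nxt]
            and levels[nxt] == level
        ):
            length += 1
            nxt = tuple(np.array(nxt) + d)
        yield int(level), length


def glrlm(
    q: QuantizedRoi,
    directions: tuple[tuple[int, int, int], ...] | None = None,
) -> TextureMatrix:
    """Gray level run length matrix, run counts summed over directions.

    Rows index gray level, columns index run length (1-based).
    """
    if directions is None:
        directions = roi_directions(q.mask)
    n_voxels = int(q.mask.sum())
    counts = np.zeros((q.n_levels, n_voxels), dtype=np.int64)
    for d in directions:
        for level, length in _runs_along(q.levels, q.mask, d):
            counts[level - 1, length - 1] += 1
    max_len = max(int(np.nonzero(counts.any(axis=0))[0].max()) + 1, 1)
    return TextureMatrix("GLRLM", counts[:, :max_len])


def glrlm_features(
    q: QuantizedRoi,
    directions: tuple[tuple[int, int, int], ...] | None = None,
) -> dict[str, float]:
    """Run-length features: SRE, LRE, GLN, RLN, RP, low/high gray-level
    run emphasis.

    Run percentage uses the aggregated convention
    ``RP = n_runs / (n_roi_voxels * n_directions)``, so a single direction
    over a constant strip of three voxels gives 1/3.
    """
    if directions is None:
        directions = roi_directions(q.mask)
    m = glrlm(q, directions)
    r = m.counts.astype(float)
    nr = r.sum()
    p = r / nr
    i = np.arange(1, r.shape[0] + 1)[:, None]
    j = np.arange(1, r.shape[1] + 1)[None, :]
    n_voxels = int(q.mask.sum())
    return {
        "short_run_emphasis": float((p / j**2).sum()),
        "long_run_emphasis": float((p * j**2).sum()),
        "gray_level_nonuniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        "run_length_nonuniformity": float((r.sum(axis=0) ** 2).sum() / nr),
        "run_percentage": float(nr / (n_voxels * len(directions))),
        "low_gray_level_run_emphasis": float((p / i**2).sum()),
        "high_gray_level_run_emphasis": float((p * i**2).sum()),
        "run_variance": _marginal_variance(p.sum(axis=0)),
        "gray_level_variance_glrlm": _marginal_variance(p.sum(axis=1)),
    }


def _marginal_variance(marginal: np.ndarray) -> float:
    k = np.arange(1, marginal.size + 1)
    mu = float((k * marginal).sum())
    return float(((k - mu) ** 2 * marginal).sum())


def glszm(q: QuantizedRoi) -> TextureMatrix:
    """Gray level size zone matrix.

    A zone is a maximal 26-connected component of equal gray level inside
    the ROI. Rows index gray level, columns index zone size (1-based).
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    n_voxels = int(q.mask.sum())
    counts = np.zeros((q.n_levels, n_voxels), dtype=np.int64)
    for level in range(1, q.n_levels + 1):
        region = (q.levels == level) & q.mask
        if not region.any():
            continue
        labeled, n_zones = ndimage.label(region, structure=structure)
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            counts[level - 1, s - 1] += 1
    max_size = max(int(np.nonzero(counts.any(axis=0))[0].max()) + 1, 1)
    return TextureMatrix("GLSZM", counts[:, :max_size])


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """Size-zone features including gray-level variance
    GLV = sum_{i,s} p(i,s) * (i - mu)^2 with mu = sum_{i,s} i * p(i,s)."""
    m = glszm(q)
    z = m.counts.astype(float)
    nz = z.sum()
    p = z / nz
    i = np.arange(1, z.shape[0] + 1)[:, None]
    s = np.arange(1, z.shape[1] + 1)[None, :]
    mu = float((i * p).sum())
    nonzero = p[p > 0]
    n_voxels = int(q.mask.sum())
    return {
        "gray_level_variance": float(((i - mu) ** 2 * p).sum()),
        "small_area_emphasis": float((p / s**2).sum()),
        "large_area_emphasis": float((p * s**2).sum()),
        "gray_level_nonuniformity": float((z.sum(axis=1) ** 2).sum() / nz),
        "size_zone_nonuniformity": float((z.sum(axis=0) ** 2).sum() / nz),
        "zone_percentage": float(nz / n_voxels),
        "zone_size_variance": _marginal_variance(p.sum(axis=0)),
        "zone_entropy": float(-(nonzero * np.log2(nonzero)).sum()),
    }
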