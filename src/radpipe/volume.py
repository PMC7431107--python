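"""Image volumes, ROI masks and gray-level quantization.

A :class:`CaseVolume` couples one scalar image volume with a binary region
of interest (ROI) mask on the same voxel grid. All texture features operate
on a :class:`QuantizedRoi`, obtained by equal-width binning of the in-ROI
intensities into a fixed number of gray levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmptyRoiError(ValueError):
    """Raised when an operation requires a non-empty ROI."""


@dataclass
class CaseVolume:
    """One image volume plus an aligned binary ROI mask.

    Parameters
    ----------
    case_id : str
        Identifier of the case (usually the folder name).
    image : ndarray, 3-D
        Scalar intensities in arbitrary units.
    mask : ndarray, 3-D
        Binary ROI; any value > 0 is foreground. Must match ``image.shape``.
    spacing : tuple of float
        Voxel edge lengths in millimetres, one per axis, strictly positive.
    """

    case_id: str
    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.mask = np.asarray(self.mask) > 0
        if self.image.ndim != 3 or self.mask.ndim != 3:
            raise ValueError("image and mask must be 3-D arrays")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if not self.mask.any():
            raise EmptyRoiError("empty ROI")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three strictly positive lengths")
        self.spacing = spacing

    @property
    def roi_values(self) -> np.ndarray:
        """In-ROI intensities as a flat array."""
        return self.image[self.mask]


@dataclass
class QuantizedRoi:
    """ROI intensities discretized to integer gray levels 1..Ng.

    ``levels`` is a full-grid integer array: in-ROI voxels carry their gray
    level, voxels outside the ROI are 0. ``n_levels`` is the nominal number
    of levels Ng (rows of every texture matrix); some levels may be empty.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise EmptyRoiError("empty ROI")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValueError("gray levels must lie in [1, n_levels]")


def quantize(volume: CaseVolume, n_bins: int = 32) -> QuantizedRoi:
    """Discretize in-ROI intensities into ``n_bins`` equal-width gray levels.

    Bins span ``[min, max]`` of the in-ROI intensities; the maximum intensity
    is assigned to the last bin. A constant ROI collapses to a single level
    (Ng = 1) regardless of ``n_bins``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = volume.roi_values
    lo, hi = float(values.min()), float(values.max())
    levels = np.zeros(volume.image.shape, dtype=np.int32)
    if hi == lo:
        levels[volume.mask] = 1
        edges = np.array([lo, hi])
        return QuantizedRoi(levels, volume.mask, 1, edges)
    width = (hi - lo) / n_bins
    lv = np.floor((volume.image[volume.mask] - lo) / width).astype(np.int32) + 1
    np.clip(lv, 1, n_bins, out=lv)
    levels[volume.mask] = lv
    edges = np.linspace(lo, hi, n_bins + 1)
    return QuantizedRoi(levels, volume.mask, n_bins, edges)
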