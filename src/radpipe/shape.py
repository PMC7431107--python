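"""Shape features of the ROI mask (voxel-based, spacing aware).

Volume is the voxel count times the voxel volume. Surface area comes from
face counting: every mask-voxel face exposed to background (or to the grid
boundary) contributes the area of that face. Face counting over-estimates
the area of smooth shapes, which biases sphericity slightly downward; the
bias is documented rather than corrected.
"""

from __future__ import annotations

import numpy as np

from .volume import CaseVolume


def _exposed_faces(mask: np.ndarray, axis: int) -> int:
    """Number of faces perpendicular to ``axis`` between mask and non-mask."""
    padded = np.pad(mask, [(1, 1) if ax == axis else (0, 0) for ax in range(3)])
    return int(np.abs(np.diff(padded.astype(np.int8), axis=axis)).sum())


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of mask voxels with at least one 6-neighbor outside."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(padded)
    for ax in range(3):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=ax)
    boundary = padded & ~interior
    return np.argwhere(boundary[1:-1, 1:-1, 1:-1])


def shape_features(volume: CaseVolume) -> dict[str, float]:
    """Voxel volume, surface area, sphericity and maximum 3-D diameter.

    Sphericity = pi^(1/3) * (6V)^(2/3) / A, at most 1 for a perfect sphere.
    The maximum 3-D diameter is the largest pairwise distance between
    boundary-voxel centers in physical (mm) coordinates.
    """
    mask = volume.mask
    sp = np.asarray(volume.spacing, dtype=float)
    n = int(mask.sum())
    voxel_volume = float(np.prod(sp))
    vol = n * voxel_volume
    area = 0.0
    for ax in range(3):
        face_area = float(np.prod(np.delete(sp, ax)))
        area += _exposed_faces(mask, ax) * face_area
    sphericity = float(np.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area)
    coords = boundary_voxels(mask) * sp
    if len(coords) == 1:
        max_diam = 0.0
    else:
        if len(coords) > 2000:  # cap the O(n^2) pairwise sweep
            rng = np.random.default_rng(0)
            coords = coords[rng.choice(len(coords), 2000, replace=False)]
        diff = coords[:, None, :] - coords[None, :, :]
        max_diam = float(np.sqrt((diff**2).sum(axis=2)).max())
    return {
        "voxel_count": float(n),
        "volume": vol,
        "surface_area": area,
        "surface_to_volume_ratio": area / vol,
        "sphericity": sphericity,
        "maximum_3d_diameter": max_diam,
    }
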