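"""Batch radiomics feature extraction from case folders of NIfTI volumes.

Layout: a root folder holds one sub-folder per case; each case folder holds
one or more image volumes plus a binary ROI mask, all in NIfTI-1 format
(.nii or .nii.gz). Shape features depend only on the ROI and are computed
once per case; first-order and texture features are computed per image
series and prefixed with the series name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .firstorder import first_order_features
from .shape import shape_features
from .texture import glcm, glcm_features, glrlm_features, glszm_features
from .volume import CaseVolume, quantize

log = logging.getLogger("radpipe.extract")

ALL_FAMILIES = ("shape", "firstorder", "glcm", "glrlm", "glszm")


@dataclass
class ExtractionConfig:
    """Feature-extraction settings.

    ``image_names``/``roi_name`` are file names inside each case folder
    (extension optional; .nii and .nii.gz both resolve). ``n_bins`` is the
    gray-level count for quantization, ``distance`` the GLCM offset length.
    ``mode`` selects the direction set: 'auto' uses in-plane directions when
    the ROI spans a single slice and all 13 3-D directions otherwise.
    """

    image_names: list[str] = field(default_factory=lambda: ["image"])
    roi_name: str = "roi"
    n_bins: int = 32
    distance: int = 1
    families: tuple[str, ...] = ALL_FAMILIES
    mode: str = "auto"  # auto | 3d


def _resolve(case_dir: Path, name: str) -> Path:
    for cand in (name, name + ".nii", name + ".nii.gz"):
        p = case_dir / cand
        if p.exists():
            return p
    raise FileNotFoundError(f"{case_dir}: no NIfTI file named {name!r}")


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def compute_features(volume: CaseVolume, config: ExtractionConfig) -> dict[str, float]:
    """All enabled non-shape feature families for one image series."""
    out: dict[str, float] = {}
    if "firstorder" in config.families:
        for k, v in first_order_features(volume, config.n_bins).items():
            out[f"firstorder_{k}"] = v
    needs_texture = {"glcm", "glrlm", "glszm"} & set(config.families)
    if needs_texture:
        q = quantize(volume, config.n_bins)
        directions = None  # roi-adapted by default ('auto')
        if config.mode == "3d":
            from .texture import ALL_DIRECTIONS_3D

            directions = ALL_DIRECTIONS_3D
        if "glcm" in config.families:
            m = glcm(q, distance=config.distance, directions=directions)
            for k, v in glcm_features(m).items():
                out[f"glcm_{k}"] = v
        if "glrlm" in config.families:
            for k, v in glrlm_features(q, directions=directions).items():
                out[f"glrlm_{k}"] = v
        if "glszm" in config.families:
            for k, v in glszm_features(q).items():
                out[f"glszm_{k}"] = v
    return out


def extract_case(case_dir: Path | str, config: ExtractionConfig) -> dict[str, float]:
    """Feature vector for one case folder; raises on missing/corrupt files."""
    case_dir = Path(case_dir)
    roi_path = _resolve(case_dir, config.roi_name)
    mask_data, spacing = _load_nifti(roi_path)
    features: dict[str, float] = {}
    first = True
    for name in config.image_names:
        img_path = _resolve(case_dir, name)
        image, img_spacing = _load_nifti(img_path)
        volume = CaseVolume(case_dir.name, image, mask_data, img_spacing or spacing)
        if first and "shape" in config.families:
            for k, v in shape_features(volume).items():
                features[f"shape_{k}"] = v
        first = False
        series = name.removesuffix(".nii.gz").removesuffix(".nii")
        for k, v in compute_features(volume, config).items():
            features[f"{series}_{k}"] = v
    return features


def extract_batch(
    root_dir: Path | str,
    config: ExtractionConfig,
    labels: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Extract features for every case sub-folder under ``root_dir``.

    Returns a DataFrame (rows sorted by case id, a ``label`` column first —
    empty unless ``labels`` provides values) and a list of per-case failure
    log lines. Failing cases are skipped, never abort the batch.
    """
    root = Path(root_dir)
    case_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not case_dirs:
        raise ValueError(f"{root}: no case sub-folders found")
    rows: dict[str, dict[str, float]] = {}
    failures: list[str] = []
    for case_dir in case_dirs:
        try:
            rows[case_dir.name] = extract_case(case_dir, config)
        except Exception as exc:  # noqa: BLE001 — any per-case failure is logged
            msg = f"{case_dir.name}: {exc}"
            failures.append(msg)
            log.warning("extraction failed for %s", msg)
    if not rows:
        raise ValueError(f"{root}: no case produced features ({len(failures)} failures)")
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "CaseID"
    label_col = pd.Series(
        [labels.get(c, np.nan) if labels else np.nan for c in table.index],
        index=table.index,
    )
    table.insert(0, "label", label_col)
    return table, failures


def write_feature_csv(table: pd.DataFrame, path: Path | str) -> None:
    """Write the feature matrix in the standard dialect: first column the
    case index, then the label column, then feature columns."""
    table.to_csv(path, lineterminator="\n")
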