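"""Feature-matrix loading, validity auditing, cleaning and splitting.

The on-disk dialect is a UTF-8 comma-separated file: first column the case
index, one column headed ``label`` with binary outcomes (1 = positive
class), every other column a numeric feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("radpipe.table")


@dataclass
class ValidityReport:
    """Cells that failed the validity audit, with derived case/feature sets."""

    bad_cells: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def bad_cases(self) -> list[str]:
        seen: dict[str, None] = {}
        for case, _, _ in self.bad_cells:
            seen.setdefault(case, None)
        return list(seen)

    @property
    def bad_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, feat, _ in self.bad_cells:
            seen.setdefault(feat, None)
        return list(seen)

    @property
    def clean(self) -> bool:
        return not self.bad_cells

    def to_log(self) -> str:
        if self.clean:
            return "validity audit: all cells valid\n"
        lines = [f"validity audit: {len(self.bad_cells)} invalid cell(s)"]
        lines += [f"  case={c} feature={f} reason={r}" for c, f, r in self.bad_cells]
        return "\n".join(lines) + "\n"


@dataclass
class FeatureTable:
    """Case x feature matrix with case identifiers and binary labels.

    ``features`` keeps invalid cells as NaN so the audit can point at them;
    modeling requires a clean table (use :func:`drop_invalid`). ``role``
    marks a table as the training or held-out test part after a split.
    """

    case_ids: list[str]
    labels: np.ndarray
    features: pd.DataFrame
    role: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.case_ids) != len(self.labels) or len(self.case_ids) != len(self.features):
            raise ValueError("case_ids, labels and features must have equal length")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValueError("duplicate case ids")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be binary 0/1, got {sorted(bad)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def to_frame(self) -> pd.DataFrame:
        frame = self.features.copy()
        frame.insert(0, "label", self.labels)
        frame.index = pd.Index(self.case_ids, name="CaseID")
        return frame

    def save(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, lineterminator="\n")

    def subset(self, indices: np.ndarray, role: str | None = None) -> "FeatureTable":
        return FeatureTable(
            [self.case_ids[i] for i in indices],
            self.labels[indices],
            self.features.iloc[indices].copy(),
            role=role,
        )


def load_table(path: Path | str) -> tuple[FeatureTable, ValidityReport]:
    """Load a feature CSV and audit every cell.

    The label column is located by the exact header ``label``; a
    case-insensitive match is accepted with a logged warning. Invalid cells
    (empty, non-numeric text, infinite) are kept as NaN and recorded in the
    report, never silently dropped.
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate case ids: {dupes}")
    label_col = None
    if "label" in raw.columns:
        label_col = "label"
    else:
        for col in raw.columns:
            if col.lower() == "label":
                label_col = col
                log.warning("label column matched case-insensitively as %r", col)
                break
    if label_col is None:
        raise ValueError("no column headed 'label' found")
    labels_num = pd.to_numeric(raw[label_col], errors="coerce")
    bad_labels = sorted(
        set(raw[label_col][labels_num.isna() | ~labels_num.isin([0, 1])])
    )
    if bad_labels:
        raise ValueError(f"labels must be binary 0/1; offending values: {bad_labels}")
    case_ids = [str(c) for c in raw.index]
    feats_raw = raw.drop(columns=[label_col])
    report = ValidityReport()
    parsed = {}
    for col in feats_raw.columns:
        num = pd.to_numeric(feats_raw[col], errors="coerce")
        for case, original, value in zip(case_ids, feats_raw[col], num):
            if original.strip() == "" or original.strip().lower() in ("na", "nan", "null", "none"):
                report.bad_cells.append((case, col, "null"))
            elif np.isnan(value):
                report.bad_cells.append((case, col, "non-numeric"))
            elif np.isinf(value):
                report.bad_cells.append((case, col, "infinite"))
        parsed[col] = num.replace([np.inf, -np.inf], np.nan)
    features = pd.DataFrame(parsed, index=case_ids)
    table = FeatureTable(case_ids, labels_num.astype(int).to_numpy(), features)
    return table, report


def drop_invalid(table: FeatureTable, report: ValidityReport, mode: str) -> FeatureTable:
    """Remove all cases (``mode='cases'``) or features (``mode='features'``)
    that the audit flagged. Idempotent on a clean table."""
    if mode not in ("cases", "features"):
        raise ValueError("mode must be 'cases' or 'features'")
    if mode == "cases":
        bad = set(report.bad_cases)
        keep = [i for i, c in enumerate(table.case_ids) if c not in bad]
        if not keep:
            raise ValueError("removing invalid cases would empty the table")
        for c in bad:
            log.info("dropping case %s (invalid values)", c)
        return table.subset(np.array(keep), role=table.role)
    bad_feats = set(report.bad_features)
    keep_cols = [c for c in table.features.columns if c not in bad_feats]
    if not keep_cols:
        raise ValueError("removing invalid features would empty the table")
    for c in bad_feats:
        log.info("dropping feature %s (invalid values)", c)
    return FeatureTable(
        list(table.case_ids), table.labels.copy(), table.features[keep_cols].copy(),
        role=table.role,
    )


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Split into train/test parts preserving the class ratio.

    Per class, the training count is ``round((1 - test_fraction) * n_class)``
    (nearest integer, ties to even); membership comes from a seeded shuffle.
    A 68-positive / 184-negative table at test_fraction 0.3 therefore yields
    a training part of 48 + 129 = 177 cases and a test part of 75.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        members = np.nonzero(table.labels == cls)[0]
        if len(members) < 2:
            raise ValueError(f"class {cls} has fewer than 2 cases")
        n_train = round((1 - test_fraction) * len(members))
        if n_train == 0 or n_train == len(members):
            raise ValueError(f"class {cls} would be empty in one part")
        order = rng.permutation(len(members))
        train_idx.extend(members[order[:n_train]])
        test_idx.extend(members[order[n_train:]])
    train_idx.sort()
    test_idx.sort()
    return (
        table.subset(np.array(train_idx), role="train"),
        table.subset(np.array(test_idx), role="test"),
    )
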