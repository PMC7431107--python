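"""Model ranking, the one-standard-error rule, and report generation.

Models are ordered by mean validation AUC (ties broken toward fewer
features, then stable enumeration order). The one-standard-error rule picks
the smallest feature count whose mean validation AUC is within one standard
error of the best point on the AUC-versus-feature-count curve, trading a
negligible score loss for a simpler, more robust model.

Test metrics are computed exactly once, for the single selected model; the
evaluator refuses to score any other pipeline on the test set unless
explicitly forced, mirroring a single held-out evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import bootstrap_auc_ci, roc_auc, roc_points, threshold_metrics, youden_cutoff
from .pipeline import CvResult, FittedPipeline, PipelineSpec
from .table import FeatureTable


@dataclass
class DatasetStats:
    auc: float
    ci_low: float
    ci_high: float
    accuracy: float
    sensitivity: float
    specificity: float
    cutoff: float


@dataclass
class ModelResult:
    """Per-pipeline statistics on each dataset plus the report artifacts."""

    spec: PipelineSpec
    stats: dict[str, DatasetStats] = field(default_factory=dict)
    roc: dict[str, np.ndarray] = field(default_factory=dict)
    selected_features: list[str] = field(default_factory=list)
    selector_scores: list[float] = field(default_factory=list)
    coefficients: list[float] | None = None


def rank_models(results: list[CvResult]) -> list[CvResult]:
    """Order by descending mean validation AUC; ties prefer fewer features,
    then the original (enumeration) order."""
    if not results:
        raise ValueError("no results to rank")
    order = sorted(
        range(len(results)),
        key=lambda i: (-results[i].mean_val_auc, results[i].spec.n_features, i),
    )
    return [results[i] for i in order]


def auc_curve(results: list[CvResult]) -> dict[int, tuple[float, float]]:
    """n_features -> (mean validation AUC, SE) for results sharing all other
    stages; raises if the results mix different stage choices."""
    combos = {
        (r.spec.normalizer, r.spec.reducer, r.spec.selector, r.spec.classifier)
        for r in results
    }
    if len(combos) != 1:
        raise ValueError("auc_curve needs results from a single stage combination")
    return {r.spec.n_features: (r.mean_val_auc, r.se_val_auc) for r in results}


def one_se_select(curve: dict[int, tuple[float, float]]) -> int:
    """One-standard-error rule on an AUC-versus-feature-count curve.

    Let n* maximize the mean AUC; return the smallest n whose mean AUC is
    >= mean(n*) - SE(n*). Never exceeds n*; a flat curve returns the
    smallest n.
    """
    if not curve:
        raise ValueError("empty curve")
    n_star = max(curve, key=lambda n: (curve[n][0], -n))
    floor = curve[n_star][0] - curve[n_star][1]
    eligible = [n for n, (mean, _) in curve.items() if mean >= floor and n <= n_star]
    return min(eligible)


def evaluate_model(
    fitted: FittedPipeline,
    datasets: dict[str, FeatureTable],
    cv_result: CvResult | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    selected: bool = True,
) -> ModelResult:
    """Clinical statistics for one fitted pipeline on named datasets.

    The Youden cutoff is learned on the 'train' dataset scores and reused
    for every other dataset. Scoring a dataset named 'test' is refused
    unless ``selected`` is True (the single final model).
    """
    result = ModelResult(
        spec=fitted.spec,
        selected_features=list(fitted.selected_features),
        selector_scores=list(fitted.selector_scores),
        coefficients=None if fitted.coefficients is None else list(fitted.coefficients),
    )
    if "test" in datasets and not selected:
        raise ValueError("test scoring is reserved for the selected model")
    cutoff = None
    ordered = sorted(datasets, key=lambda d: d != "train")  # train first
    for name in ordered:
        table = datasets[name]
        scores = fitted.predict(table.X)
        labels = table.y
        if name == "train":
            cutoff = youden_cutoff(scores, labels)
        tm = threshold_metrics(scores, labels, cutoff)
        lo, hi = bootstrap_auc_ci(scores, labels, n_boot=n_boot, seed=seed)
        result.stats[name] = DatasetStats(
            auc=roc_auc(scores, labels), ci_low=lo, ci_high=hi,
            accuracy=tm["accuracy"], sensitivity=tm["sensitivity"],
            specificity=tm["specificity"], cutoff=tm["cutoff"],
        )
        result.roc[name] = roc_points(scores, labels)
    if cv_result is not None:
        scores, truth = cv_result.pooled_scores()
        tm = threshold_metrics(scores, truth, cutoff)
        lo, hi = bootstrap_auc_ci(scores, truth, n_boot=n_boot, seed=seed)
        result.stats["validation"] = DatasetStats(
            auc=cv_result.mean_val_auc, ci_low=lo, ci_high=hi,
            accuracy=tm["accuracy"], sensitivity=tm["sensitivity"],
            specificity=tm["specificity"], cutoff=tm["cutoff"],
        )
        result.roc["validation"] = roc_points(scores, truth)
    return result


def describe_model(result: ModelResult, k: int = 5) -> str:
    """One-paragraph plain-text description of the selected model."""
    s = result.spec
    lines = [
        f"The model normalizes features with {s.normalizer} normalization, "
        f"reduces dimensionality with {s.reducer}, selects {s.n_features} "
        f"feature(s) by {s.selector}, and classifies with {s.classifier}. "
        f"Hyper-parameters were evaluated by stratified {k}-fold "
        f"cross-validation with fixed random seeds (seed={s.seed}).",
        "",
        "Selected features (selector score; classifier coefficient):",
    ]
    coefs = result.coefficients or [float("nan")] * len(result.selected_features)
    for name, score, coef in zip(result.selected_features, result.selector_scores, coefs):
        lines.append(f"  {name}: score={score:.4f}, coefficient={coef:.4f}")
    for dataset, st in result.stats.items():
        lines.append(
            f"{dataset}: AUC={st.auc:.3f} (95% CI {st.ci_low:.3f}-{st.ci_high:.3f}), "
            f"accuracy={st.accuracy:.3f}, sensitivity={st.sensitivity:.3f}, "
            f"specificity={st.specificity:.3f}, cutoff={st.cutoff:.4f}"
        )
    return "\n".join(lines) + "\n"


def results_table(ranked: list[CvResult]) -> pd.DataFrame:
    rows = []
    for r in ranked:
        rows.append({
            "model_id": r.spec.model_id,
            "normalizer": r.spec.normalizer,
            "reducer": r.spec.reducer,
            "selector": r.spec.selector,
            "n_features": r.spec.n_features,
            "classifier": r.spec.classifier,
            "mean_val_auc": r.mean_val_auc,
            "se_val_auc": r.se_val_auc,
            "mean_train_auc": r.mean_train_auc,
        })
    return pd.DataFrame(rows)


def export_report(
    out_dir: Path | str,
    ranked: list[CvResult],
    selected: ModelResult | None = None,
    curve: dict[int, tuple[float, float]] | None = None,
    feature_data: pd.DataFrame | None = None,
    labels: np.ndarray | None = None,
) -> list[Path]:
    """Write the report files: ranked statistics, ROC points per dataset of
    the selected model, the AUC-vs-feature-count curve, per-class histogram
    data for the selected features, and the model description. Idempotent."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    path = out / "results.csv"
    results_table(ranked).to_csv(path, index=False, lineterminator="\n")
    written.append(path)
    if curve is not None:
        path = out / "auc_curve.csv"
        pd.DataFrame(
            [(n, m, se) for n, (m, se) in sorted(curve.items())],
            columns=["n_features", "mean_val_auc", "se_val_auc"],
        ).to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    if selected is not None:
        for dataset, pts in selected.roc.items():
            path = out / f"roc_{selected.spec.model_id}_{dataset}.csv"
            pd.DataFrame(pts, columns=["fpr", "tpr"]).to_csv(
                path, index=False, lineterminator="\n"
            )
            written.append(path)
        path = out / "description.txt"
        path.write_text(describe_model(selected))
        written.append(path)
        stats_rows = [
            {"dataset": d, **vars(st)} for d, st in selected.stats.items()
        ]
        path = out / "selected_model_stats.csv"
        pd.DataFrame(stats_rows).to_csv(path, index=False, lineterminator="\n")
        written.append(path)
        if feature_data is not None and labels is not None:
            cols = [c for c in selected.selected_features if c in feature_data.columns]
            if cols:
                hist = feature_data[cols].copy()
                hist["label"] = np.asarray(labels)
                path = out / "selected_feature_values.csv"
                hist.to_csv(path, lineterminator="\n")
                written.append(path)
    return written
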