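"""Run orchestration: execute an enumerated grid, persist every model with
its interim results, select the final model, and export reports.

A run directory holds one sub-folder per pipeline (cross-validation scores
as JSON plus the refit model as a joblib artifact) and a machine-readable
``manifest.json`` capturing the config snapshot, seeds, fold assignments,
ranking and selected model id — enough to reload any model or reproduce the
run bit-for-bit given the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np

from . import __version__
from .evaluation import (
    ModelResult,
    auc_curve,
    evaluate_model,
    export_report,
    one_se_select,
    rank_models,
)
from .pipeline import CvResult, cross_validate, enumerate_pipelines, fit_pipeline, make_folds
from .table import FeatureTable, load_table

log = logging.getLogger("radpipe.runner")

DEFAULT_CONFIG = {
    "normalizers": ["zscore"],
    "reducers": ["pcc"],
    "selectors": ["anova"],
    "classifiers": ["lda"],
    "feature_range": [1, 10],
    "k_folds": 5,
    "seed": 42,
    "pcc_threshold": 0.9,
    "selection_rule": "one_se",  # one_se | best
}


def run_grid(
    train_table: FeatureTable,
    config: dict,
    out_dir: Path | str,
) -> dict:
    """Cross-validate every pipeline in the menu and persist the run.

    Returns the manifest dict. Fold assignments are computed once from the
    run seed and shared by every pipeline so models are compared on
    identical folds.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    k = int(cfg["k_folds"])
    menu = {key: list(cfg[key]) for key in
            ("normalizers", "reducers", "selectors", "classifiers")}
    fr = cfg["feature_range"]
    feature_range = tuple(fr) if len(fr) == 2 else list(fr)
    specs = enumerate_pipelines(menu, feature_range, seed=seed)
    folds = make_folds(train_table.y, k, seed)
    results: list[CvResult] = []
    for spec in specs:
        model_dir = out / spec.model_id
        model_dir.mkdir(exist_ok=True)
        cv = cross_validate(spec, train_table, k=k, seed=seed, folds=folds)
        results.append(cv)
        fitted = fit_pipeline(spec, train_table.X, train_table.y, train_table.feature_names)
        joblib.dump(fitted, model_dir / "model.joblib")
        interim = {
            "spec": asdict(spec),
            "val_aucs": cv.val_aucs,
            "train_aucs": cv.train_aucs,
            "mean_val_auc": cv.mean_val_auc,
            "se_val_auc": cv.se_val_auc,
            "fold_scores": [s.tolist() for s in cv.fold_scores],
            "fold_truth": [t.tolist() for t in cv.fold_truth],
            "selected_features": fitted.selected_features,
            "selector_scores": fitted.selector_scores,
            "coefficients": None if fitted.coefficients is None
            else [float(c) for c in fitted.coefficients],
        }
        (model_dir / "cv_result.json").write_text(json.dumps(interim, indent=1))
        log.info("%s: mean validation AUC %.3f", spec.model_id, cv.mean_val_auc)

    ranked = rank_models(results)
    best = ranked[0]
    combo_results = [
        r for r in results
        if (r.spec.normalizer, r.spec.reducer, r.spec.selector, r.spec.classifier)
        == (best.spec.normalizer, best.spec.reducer, best.spec.selector,
            best.spec.classifier)
    ]
    curve = auc_curve(combo_results)
    if cfg["selection_rule"] == "one_se":
        chosen_n = one_se_select(curve)
    else:
        chosen_n = best.spec.n_features
    selected_id = next(
        r.spec.model_id for r in combo_results if r.spec.n_features == chosen_n
    )
    manifest = {
        "tool_version": __version__,
        "config": cfg,
        "seed": seed,
        "k_folds": k,
        "n_pipelines": len(specs),
        "specs": [asdict(s) for s in specs],
        "fold_assignments": [[int(i) for i in va] for _, va in folds],
        "ranking": [r.spec.model_id for r in ranked],
        "mean_val_aucs": {r.spec.model_id: r.mean_val_auc for r in results},
        "se_val_aucs": {r.spec.model_id: r.se_val_auc for r in results},
        "auc_curve": {str(n): list(v) for n, v in sorted(curve.items())},
        "selected_model_id": selected_id,
        "best_model_id": best.spec.model_id,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_run(run_dir: Path | str) -> tuple[dict, dict[str, dict]]:
    """Reload the manifest and every per-model interim result."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{run_dir} is not a run directory (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    interim = {}
    for model_id in manifest["ranking"]:
        interim[model_id] = json.loads((run_dir / model_id / "cv_result.json").read_text())
    return manifest, interim


def _rebuild_cv(entry: dict) -> CvResult:
    from .pipeline import PipelineSpec

    return CvResult(
        spec=PipelineSpec(**entry["spec"]),
        fold_assignments=[],
        fold_scores=[np.array(s) for s in entry["fold_scores"]],
        fold_truth=[np.array(t) for t in entry["fold_truth"]],
        val_aucs=entry["val_aucs"],
        train_aucs=entry["train_aucs"],
    )


def report_run(
    run_dir: Path | str,
    train_table: FeatureTable,
    test_csv: Path | str | None = None,
    out_dir: Path | str | None = None,
    n_boot: int = 1000,
) -> ModelResult:
    """Generate report files for a finished run.

    Test metrics are computed only for the selected model; other pipelines
    are reported with training/validation statistics alone.
    """
    run_dir = Path(run_dir)
    manifest, interim = load_run(run_dir)
    results = [_rebuild_cv(interim[mid]) for mid in manifest["ranking"]]
    ranked = rank_models(results)
    selected_id = manifest["selected_model_id"]
    fitted = joblib.load(run_dir / selected_id / "model.joblib")
    datasets: dict[str, FeatureTable] = {"train": train_table}
    if test_csv is not None:
        test_table, report = load_table(test_csv)
        if not report.clean:
            raise ValueError("test table has invalid cells:\n" + report.to_log())
        datasets["test"] = test_table
    cv_sel = next(r for r in results if r.spec.model_id == selected_id)
    model_result = evaluate_model(
        fitted, datasets, cv_result=cv_sel, n_boot=n_boot,
        seed=manifest["seed"], selected=True,
    )
    curve = {int(n): tuple(v) for n, v in manifest["auc_curve"].items()}
    export_report(
        out_dir or run_dir / "report", ranked, selected=model_result, curve=curve,
        feature_data=train_table.features, labels=train_table.y,
    )
    return model_result
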