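"""End-to-end orchestration: train a model from a single-cell table, score
new profiles with a trained model. Each run writes its artifacts plus a JSON
run manifest (config snapshot, seed, package version, output hashes,
timestamps) for provenance.

These functions are the library-level equivalent of a train/score command
pair: every stage error is re-raised annotated with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .aggregate import aggregate_per_field, apply_robustize, fit_robustize
from .config import PipelineConfig, feature_columns
from .features import (
    DEFAULT_BLOCKLIST,
    bulk_filter,
    prune_redundant,
    rank_by_permutation_importance,
)
from .score import (
    compare_groups,
    emt_score,
    predict_probabilities,
    remove_outliers,
    summarize_by_well,
)
from .train import (
    TrainedEMTModel,
    cross_validate_suite,
    default_classifier_suite,
    fit_final,
    load_model,
    save_model,
    split_train_test,
)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # annotate and re-raise
        raise StageError(stage, exc) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: PipelineConfig,
                    artifacts: list[Path]) -> Path:
    from . import __version__  # deferred: pipeline is imported by __init__

    manifest = {
        "orgemt_version": __version__,
        "seed": config.random_seed,
        "config": config.fingerprint(),
        "outputs": {p.name: _sha256(p) for p in artifacts},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


@dataclass
class TrainResult:
    model: TrainedEMTModel
    model_path: Path
    cv_summary: pd.DataFrame
    selection_report: pd.DataFrame
    panel: list[str]
    profiles: pd.DataFrame  # normalized, bulk-filtered profiles
    manifest_path: Path


def run_train(
    cells: pd.DataFrame,
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    class_order: list[str] | None = None,
    blocklist=DEFAULT_BLOCKLIST,
    cv_specs=None,
) -> TrainResult:
    """Full training chain on a labeled SingleCellTable.

    aggregate -> robustize -> bulk filter -> train/test split -> CV suite ->
    permutation importance -> redundancy pruning -> final fit -> save.
    Writes ``model.cpamodel``, ``cv_report.csv``, ``selection_report.csv``
    and ``run_manifest.json`` under ``out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles = _run_stage("aggregate", aggregate_per_field, cells)
    stats = _run_stage("fit_robustize", fit_robustize, profiles)
    normalized = _run_stage("apply_robustize", apply_robustize, profiles,
                            stats)
    filtered, report = _run_stage("bulk_filter", bulk_filter, normalized,
                                  config, blocklist)

    labels = filtered["condition"]
    X_tr, X_te, y_tr, y_te = _run_stage("split", split_train_test, filtered,
                                        labels, config)
    specs = cv_specs or default_classifier_suite(config.random_seed)
    cv = _run_stage("cross_validate", cross_validate_suite, X_tr, y_tr,
                    X_te, y_te, specs, config)

    feats = feature_columns(filtered)
    hgb = [s for s in specs if s.family == "hist_gradient_boosting"]
    ranker = (hgb[0] if hgb
              else default_classifier_suite(config.random_seed)[-1]).build()
    ranker.fit(X_tr[feats], y_tr)

    ranking = _run_stage("permutation_importance",
                         rank_by_permutation_importance, ranker,
                         X_tr[feats], y_tr, config)
    panel = _run_stage("prune_redundant", prune_redundant, ranking,
                       X_tr[feats], config)

    order = class_order or list(dict.fromkeys(cells["condition"]))
    model = _run_stage("fit_final", fit_final, X_tr, y_tr, panel, config,
                       order)

    model_path = out / "model.cpamodel"
    _run_stage("save_model", save_model, model, model_path)
    cv_path = out / "cv_report.csv"
    cv.summary.to_csv(cv_path, index=False)
    sel_path = out / "selection_report.csv"
    report.to_frame().to_csv(sel_path, index=False)
    stats_path = out / "normalization_stats.json"
    stats.to_json(stats_path)
    manifest = _write_manifest(out, config,
                               [model_path, cv_path, sel_path, stats_path])
    return TrainResult(model=model, model_path=model_path,
                       cv_summary=cv.summary,
                       selection_report=report.to_frame(), panel=panel,
                       profiles=filtered, manifest_path=manifest)


@dataclass
class ScoreResult:
    scores: pd.DataFrame
    well_summary: pd.DataFrame
    comparison: object | None
    flagged: list = dc_field(default_factory=list)
    manifest_path: Path | None = None


def run_score(
    model: TrainedEMTModel | str | os.PathLike,
    profiles: pd.DataFrame,
    out_dir: str | os.PathLike | None = None,
    config: PipelineConfig | None = None,
    weights: dict[str, float] | None = None,
) -> ScoreResult:
    """Scoring chain on normalized aggregated profiles.

    outlier removal -> probabilities -> EMT scores -> well summaries ->
    group comparison (skipped when condition labels are absent). ``weights``
    override the model's embedded progression weights.
    """
    config = config or PipelineConfig()
    if not isinstance(model, TrainedEMTModel):
        model = _run_stage("load_model", load_model, model)
    w = weights or model.weights

    kept, flagged = _run_stage("remove_outliers", remove_outliers, profiles,
                               model.panel, config)
    probs = _run_stage("predict", predict_probabilities, model, kept)
    scores = _run_stage("emt_score", emt_score, probs, w)
    wells = _run_stage("summarize", summarize_by_well, scores)
    comparison = None
    has_labels = ("condition" in scores.columns
                  and scores["condition"].notna().any()
                  and scores["condition"].nunique() >= 2)
    if has_labels:
        comparison = _run_stage("compare_groups", compare_groups, scores)

    manifest_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        score_path = out / "scores.csv"
        scores.to_csv(score_path, index=False)
        well_path = out / "well_summary.csv"
        wells.to_csv(well_path, index=False)
        artifacts = [score_path, well_path]
        if comparison is not None:
            cmp_path = out / "group_comparison.csv"
            comparison.to_csv(cmp_path)
            artifacts.append(cmp_path)
        manifest_path = _write_manifest(out, config, artifacts)
    return ScoreResult(scores=scores, well_summary=wells,
                       comparison=comparison, flagged=flagged,
                       manifest_path=manifest_path)
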