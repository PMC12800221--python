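"""Classifier suite evaluation and the final gradient-boosting EMT model.

Six classifier families are compared with repeated stratified cross-validation
on the training split; the final model — the only one required to emit class
probabilities — is a histogram-based gradient-boosting classifier fitted on
the selected feature panel. The fitted model, its ordered class labels,
feature panel and progression weights are persisted together as a `.cpamodel`
archive (a zip holding a JSON manifest and a joblib blob).
"""

from __future__ import annotations

import hashlib
import io
import json
import os
import zipfile
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, LinearSVC

from .config import PipelineConfig, feature_columns

ARCHIVE_FORMAT_VERSION = 1

_FAMILIES = ("knn", "linear_svc", "sgd", "rbf_svc", "random_forest",
             "hist_gradient_boosting")


@dataclass
class ClassifierSpec:
    """One classifier family with hyperparameters (library defaults unless
    overridden) and a seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"expected one of {_FAMILIES}")

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "knn":
            return KNeighborsClassifier(**hp)
        if self.family == "linear_svc":
            return LinearSVC(random_state=self.seed, **hp)
        if self.family == "sgd":
            return SGDClassifier(random_state=self.seed, **hp)
        if self.family == "rbf_svc":
            return SVC(kernel="rbf", random_state=self.seed, **hp)
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=self.seed, **hp)
        return HistGradientBoostingClassifier(random_state=self.seed, **hp)


def default_classifier_suite(seed: int = 0) -> list[ClassifierSpec]:
    """The six families compared in the pipeline, with default settings."""
    return [ClassifierSpec(family=f, seed=seed) for f in _FAMILIES]


@dataclass
class CVReport:
    """Cross-validation and test accuracies per classifier family.

    ``fold_scores`` maps family -> array of folds x repeats accuracies;
    ``summary`` is one row per family with mean, sd and test accuracy.
    """

    fold_scores: dict[str, np.ndarray]
    summary: pd.DataFrame

    def to_csv(self, path: str | os.PathLike) -> None:
        self.summary.to_csv(path, index=False)


def split_train_test(
    profiles: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Seeded stratified 80/20 (by default) train/test split."""
    config = config or PipelineConfig()
    labels = pd.Series(np.asarray(labels), index=profiles.index)
    counts = labels.value_counts()
    if (counts < 2).any():
        singles = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with a single sample cannot be "
                         f"stratified: {singles}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        profiles, labels, test_size=config.test_fraction,
        stratify=labels, random_state=config.random_seed, shuffle=True)
    return X_tr, X_te, y_tr, y_te


def cross_validate_suite(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame,
    y_test,
    specs: list[ClassifierSpec] | None = None,
    config: PipelineConfig | None = None,
) -> CVReport:
    """Repeated stratified k-fold CV for every family, plus test accuracy
    after refitting each on the full training set.

    Only feature columns of ``X_train``/``X_test`` are used, so metadata
    columns may be present.
    """
    config = config or PipelineConfig()
    specs = specs or default_classifier_suite(config.random_seed)
    feats = feature_columns(X_train)
    y_train = np.asarray(y_train)
    counts = pd.Series(y_train).value_counts()
    if (counts < config.cv_folds).any():
        raise ValueError("every class needs at least cv_folds samples")
    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds, n_repeats=config.cv_repeats,
        random_state=config.random_seed)
    fold_scores: dict[str, np.ndarray] = {}
    rows = []
    for spec in specs:
        scores = cross_val_score(spec.build(), X_train[feats].to_numpy(),
                                 y_train, cv=cv, scoring="accuracy")
        fitted = spec.build().fit(X_train[feats].to_numpy(), y_train)
        test_acc = float(fitted.score(X_test[feats].to_numpy(),
                                      np.asarray(y_test)))
        fold_scores[spec.family] = scores
        rows.append({"family": spec.family,
                     "cv_mean": float(scores.mean()),
                     "cv_sd": float(scores.std(ddof=1)),
                     "n_folds": len(scores),
                     "test_accuracy": test_acc})
    return CVReport(fold_scores=fold_scores, summary=pd.DataFrame(rows))


@dataclass
class TrainedEMTModel:
    """The deliverable of training: fitted probabilistic classifier, ordered
    class labels, feature panel, and per-class progression weights."""

    classifier: HistGradientBoostingClassifier
    class_labels: list[str]
    panel: list[str]
    weights: dict[str, float]
    config_fingerprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("feature panel must be nonempty")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ValueError("class labels must be unique")
        if set(self.weights) != set(self.class_labels):
            raise ValueError("weights must cover exactly the model classes")


def fit_final(
    X_train: pd.DataFrame,
    y_train,
    panel: list[str],
    config: PipelineConfig | None = None,
    class_order: list[str] | None = None,
    weights: dict[str, float] | None = None,
) -> TrainedEMTModel:
    """Fit the final histogram-gradient-boosting model on the panel.

    ``class_order`` fixes the label order recorded in the model (defaults to
    order of first appearance in ``y_train``); ``weights`` default to the
    published progression weights when the class count matches, else 1.0 per
    class (to be replaced by a calibration run).
    """
    from .score import DEFAULT_WEIGHTS  # local import to avoid a cycle

    config = config or PipelineConfig()
    missing = [f for f in panel if f not in X_train.columns]
    if missing:
        raise KeyError(f"panel features missing from training data: {missing}")
    y_train = np.asarray(y_train).astype(str)
    labels_seen = list(pd.unique(y_train))
    class_order = [str(c) for c in (class_order or labels_seen)]
    if set(class_order) != set(labels_seen):
        raise ValueError("class_order must contain exactly the labels "
                         "present in y_train")
    if weights is None:
        if len(class_order) == len(DEFAULT_WEIGHTS):
            weights = dict(zip(class_order, DEFAULT_WEIGHTS.values()))
        else:
            weights = {c: 1.0 for c in class_order}
    clf = HistGradientBoostingClassifier(random_state=config.random_seed)
    clf.fit(X_train[panel].to_numpy(), y_train)
    return TrainedEMTModel(classifier=clf, class_labels=class_order,
                           panel=list(panel), weights=dict(weights),
                           config_fingerprint=config.fingerprint())


class ModelArchiveError(ValueError):
    """Corrupt, inconsistent or version-incompatible .cpamodel archive."""


def save_model(model: TrainedEMTModel, path: str | os.PathLike) -> None:
    """Write a .cpamodel zip: manifest.json + joblib model blob."""
    blob = io.BytesIO()
    joblib.dump(model.classifier, blob)
    blob_bytes = blob.getvalue()
    manifest = {
        "format_version": ARCHIVE_FORMAT_VERSION,
        "class_labels": model.class_labels,
        "panel": model.panel,
        "weights": model.weights,
        "config_fingerprint": model.config_fingerprint,
        "blob_sha256": hashlib.sha256(blob_bytes).hexdigest(),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        zf.writestr("model.bin", blob_bytes)


def load_model(path: str | os.PathLike) -> TrainedEMTModel:
    """Load a .cpamodel archive; predictions are bit-identical to pre-save."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        if not {"manifest.json", "model.bin"} <= names:
            raise ModelArchiveError("archive must contain manifest.json "
                                    "and model.bin")
        manifest = json.loads(zf.read("manifest.json"))
        blob_bytes = zf.read("model.bin")
    if manifest.get("format_version") != ARCHIVE_FORMAT_VERSION:
        raise ModelArchiveError(
            f"unsupported archive version {manifest.get('format_version')!r}; "
            f"expected {ARCHIVE_FORMAT_VERSION}")
    if hashlib.sha256(blob_bytes).hexdigest() != manifest.get("blob_sha256"):
        raise ModelArchiveError("model blob does not match manifest checksum")
    clf = joblib.load(io.BytesIO(blob_bytes))
    n_features = getattr(clf, "n_features_in_", None)
    if n_features is not None and n_features != len(manifest["panel"]):
        raise ModelArchiveError(
            f"manifest panel has {len(manifest['panel'])} features but the "
            f"fitted model expects {n_features}")
    return TrainedEMTModel(
        classifier=clf,
        class_labels=list(manifest["class_labels"]),
        panel=list(manifest["panel"]),
        weights={k: float(v) for k, v in manifest["weights"].items()},
        config_fingerprint=manifest.get("config_fingerprint", {}),
    )
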