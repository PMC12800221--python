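"""Probability-weighted EMT scoring of aggregated profiles.

A trained model assigns each field-level profile a probability of belonging
to each EMT time-course condition; the EMT score is the weighted sum
score = sum_n p_n * w_n, with condition weights w_n derived from the fold
change of the transcriptomic hallmark EMT score versus control. Before
prediction, per-condition Isolation-Forest outlier removal (contamination 5%)
discards anomalous fields. Field scores roll up to per-well means with
t-based 95% confidence intervals, and conditions are compared by one-way
ANOVA with Tukey's correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import IsolationForest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import METADATA_COLUMNS, PipelineConfig
from .train import TrainedEMTModel

log = logging.getLogger(__name__)

#: Published default progression weights: fold change of the hallmark EMT
#: transcriptomic score at each TGF-beta1 time point relative to control.
DEFAULT_WEIGHTS: dict[str, float] = {
    "Control": 1.0,
    "TGFb_24h": 2.92,
    "TGFb_48h": 4.39,
    "TGFb_4d": 4.92,
    "TGFb_8d": 6.07,
}


@dataclass
class ProgressionWeights:
    """Ordered condition -> weight map (w_n)."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.weights.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("weights must be finite")

    @property
    def classes(self) -> list[str]:
        return list(self.weights)

    def vector(self, class_order: list[str]) -> np.ndarray:
        missing = set(class_order) ^ set(self.weights)
        if missing:
            raise KeyError(f"weight/class key mismatch: {sorted(missing)}")
        return np.asarray([self.weights[c] for c in class_order], dtype=float)


def remove_outliers(
    profiles: pd.DataFrame,
    panel: list[str],
    config: PipelineConfig | None = None,
    min_group_size: int = 20,
) -> tuple[pd.DataFrame, list]:
    """Per-condition Isolation-Forest outlier removal on panel features.

    Within each condition group (including the control; profiles without a
    condition label form a single group) an Isolation Forest seeded from the
    config is fitted on the panel features and the floor(contamination * n)
    most anomalous profiles are flagged, thresholding at the contamination
    quantile of the anomaly scores with ties broken by row index. Groups
    smaller than ``min_group_size`` are skipped with a warning.

    Returns the table without the flagged rows, plus the flagged row indices.
    """
    config = config or PipelineConfig()
    missing = [f for f in panel if f not in profiles.columns]
    if missing:
        raise KeyError(f"panel features missing from profiles: {missing}")
    flagged: list = []
    groups = profiles.groupby("condition", dropna=False, observed=True)
    for cond, grp in groups:
        n = len(grp)
        k = int(np.floor(config.contamination * n))
        if n < min_group_size:
            log.warning("condition %r has %d < %d profiles; outlier "
                        "removal skipped", cond, n, min_group_size)
            continue
        if k == 0:
            continue
        forest = IsolationForest(random_state=config.random_seed)
        forest.fit(grp[panel].to_numpy())
        anomaly = forest.score_samples(grp[panel].to_numpy())  # low = anomalous
        order = np.lexsort((np.arange(n), anomaly))  # score, then row position
        flagged.extend(grp.index[order[:k]].tolist())
    return profiles.drop(index=flagged), flagged


def predict_probabilities(model: TrainedEMTModel,
                          profiles: pd.DataFrame) -> pd.DataFrame:
    """Class-probability table for aggregated profiles.

    Columns follow the model's recorded class order (not sklearn's internal
    sorted order); each row sums to 1. Metadata columns are carried through.
    """
    missing = [f for f in model.panel if f not in profiles.columns]
    if missing:
        raise KeyError(f"profiles lack panel features: {missing}")
    raw = model.classifier.predict_proba(
        profiles[model.panel].to_numpy())
    clf_order = [str(c) for c in model.classifier.classes_]
    reorder = [clf_order.index(c) for c in model.class_labels]
    probs = raw[:, reorder]
    meta = [c for c in METADATA_COLUMNS if c in profiles.columns]
    out = profiles[meta].copy()
    for j, c in enumerate(model.class_labels):
        out[c] = probs[:, j]
    return out


def emt_score(probs: pd.DataFrame,
              weights: ProgressionWeights | dict[str, float]) -> pd.DataFrame:
    """EMT score per profile: score = sum_n p_n * w_n.

    ``probs`` must carry one column per weight key (extra metadata columns
    are preserved). The score is bounded by [min w, max w].
    """
    if isinstance(weights, dict):
        weights = ProgressionWeights(weights)
    classes = weights.classes
    missing = [c for c in classes if c not in probs.columns]
    if missing:
        raise KeyError(f"probability table lacks classes: {missing}")
    w = weights.vector(classes)
    p = probs[classes].to_numpy(dtype=float)
    out = probs.copy()
    out["emt_score"] = p @ w
    return out


def summarize_by_well(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-well mean EMT score with a t-based 95% CI over field scores.

    A well with a single field gets mean only (CI half-width NaN).
    """
    keys = [c for c in ("plate_id", "well_id", "condition")
            if c in scores.columns]
    rows = []
    for key, grp in scores.groupby(keys, dropna=False, observed=True):
        vals = grp["emt_score"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sem = vals.std(ddof=1) / np.sqrt(n)
            half = float(stats.t.ppf(0.975, df=n - 1) * sem)
        else:
            half = float("nan")
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update({"mean_score": mean, "ci95_half_width": half,
                    "n_fields": n})
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One-way ANOVA over condition groups plus Tukey-adjusted pairs."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj

    def to_csv(self, path) -> None:
        self.tukey.assign(anova_F=self.f_statistic,
                          anova_p=self.p_value).to_csv(path, index=False)


def compare_groups(scores: pd.DataFrame,
                   value_col: str = "emt_score",
                   group_col: str = "condition") -> GroupComparison:
    """One-way ANOVA followed by Tukey HSD on scores grouped by condition."""
    groups = [g[value_col].to_numpy(dtype=float)
              for _, g in scores.groupby(group_col, observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(g) == 0 for g in groups) and len(
            {g[0] for g in groups}) == 1:
        raise ValueError("zero within-group variance in all groups and "
                         "identical means: comparison is degenerate")
    means = np.array([g.mean() for g in groups])
    if all(np.var(g) == 0 for g in groups) and np.ptp(means) > 0:
        raise ValueError("zero within-group variance in all groups")
    F, p = stats.f_oneway(*groups)
    if np.isnan(F):  # identical groups: no between- or within-variance signal
        F, p = 0.0, 1.0
    tk = pairwise_tukeyhsd(scores[value_col].to_numpy(dtype=float),
                           scores[group_col].to_numpy())
    table = pd.DataFrame(tk.summary().data[1:],
                         columns=[str(c) for c in tk.summary().data[0]])
    tukey = pd.DataFrame({
        "group1": table["group1"].astype(str),
        "group2": table["group2"].astype(str),
        "mean_diff": table["meandiff"].astype(float),
        "p_adj": table["p-adj"].astype(float),
    })
    return GroupComparison(f_statistic=float(F), p_value=float(p),
                           tukey=tukey)
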