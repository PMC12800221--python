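"""Two-stage feature selection for aggregated morphological profiles.

Stage one (``bulk_filter``) removes, in order: features with missing values,
low-variance features (< 0.01 after normalization), one member of every
highly Pearson-correlated pair (|r| > 0.9), and blocklisted name patterns.
Stage two ranks the surviving features by permutation importance of a fitted
classifier (mean accuracy drop over seeded shuffles) and greedily prunes
Spearman-redundant features (|rho| > 0.75) from the top of the ranking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.inspection import permutation_importance

from .config import PipelineConfig, feature_columns

#: Cross-correlation/colocalization metrics known to be unstable in
#: aggregated profiles; overridable wherever a blocklist is accepted.
DEFAULT_BLOCKLIST = ("Costes", "Manders", "RWC")


class FeatureSelectionError(ValueError):
    """Raised when a selection stage leaves nothing usable."""

    def __init__(self, message: str, report: "FeatureSelectionReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class FeatureSelectionReport:
    """One record per input feature: kept or dropped, and by which rule."""

    records: list[dict] = field(default_factory=list)

    def add(self, feature: str, action: str, rule: str, detail: str = "") -> None:
        self.records.append({"feature": feature, "action": action,
                             "rule": rule, "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["feature", "action", "rule", "detail"])

    @property
    def kept(self) -> list[str]:
        return [r["feature"] for r in self.records if r["action"] == "kept"]

    @property
    def dropped(self) -> list[str]:
        return [r["feature"] for r in self.records if r["action"] == "dropped"]


def _correlation_drops(X: pd.DataFrame, threshold: float) -> list[str]:
    """Iteratively drop one member of each |r| > threshold pair.

    Of a correlated pair, the member with the greater mean absolute
    correlation to all remaining features goes; ties break lexicographically.
    """
    dropped: list[str] = []
    cols = list(X.columns)
    corr = X.corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    while True:
        sub = corr.loc[cols, cols]
        if sub.size == 0 or sub.values.max() <= threshold:
            break
        # all features involved in any violating pair
        viol = sub.gt(threshold)
        candidates = [c for c in cols if viol[c].any()]
        mean_abs = sub[candidates].mean(axis=0)
        worst = max(candidates,
                    key=lambda c: (mean_abs[c], -_lex_rank(c, candidates)))
        dropped.append(worst)
        cols.remove(worst)
    return dropped


def _lex_rank(name: str, names: list[str]) -> int:
    return sorted(names).index(name)


def bulk_filter(
    profiles: pd.DataFrame,
    config: PipelineConfig | None = None,
    blocklist: tuple[str, ...] | list[str] = DEFAULT_BLOCKLIST,
) -> tuple[pd.DataFrame, FeatureSelectionReport]:
    """Apply the NA / low-variance / high-correlation / blocklist cascade.

    Returns the filtered profile matrix (metadata columns untouched) and a
    report listing every input feature exactly once.
    """
    config = config or PipelineConfig()
    report = FeatureSelectionReport()
    feats = feature_columns(profiles)
    X = profiles[feats]

    na_drop = [c for c in feats if X[c].isna().any()]
    for c in na_drop:
        report.add(c, "dropped", "na", "contains missing values")
    keep = [c for c in feats if c not in na_drop]

    variances = X[keep].var(ddof=1)
    lv = [c for c in keep if variances[c] < config.variance_threshold]
    for c in lv:
        report.add(c, "dropped", "low_variance",
                   f"variance {variances[c]:.3g} < {config.variance_threshold}")
    keep = [c for c in keep if c not in lv]

    corr_drop = _correlation_drops(X[keep], config.correlation_threshold)
    for c in corr_drop:
        report.add(c, "dropped", "high_correlation",
                   f"|r| > {config.correlation_threshold}")
    keep = [c for c in keep if c not in corr_drop]

    patterns = [re.compile(p) for p in blocklist]
    bl = [c for c in keep if any(p.search(c) for p in patterns)]
    for c in bl:
        report.add(c, "dropped", "blocklist", "matches blocklist pattern")
    keep = [c for c in keep if c not in bl]

    for c in keep:
        report.add(c, "kept", "", "")

    if not keep:
        raise FeatureSelectionError("bulk filter dropped every feature",
                                    report)
    meta = [c for c in profiles.columns if c not in feats]
    return profiles[meta + keep], report


@dataclass
class ImportanceRanking:
    """Permutation-importance ranking on the training set.

    ``table`` has one row per feature with ``mean_importance`` (baseline
    accuracy minus mean accuracy over shuffles) and per-repeat columns
    ``repeat_0..repeat_{N-1}``; rows sorted by descending mean importance,
    ties by feature name.
    """

    table: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def mean_importance(self, feature: str) -> float:
        row = self.table.loc[self.table["feature"] == feature]
        return float(row["mean_importance"].iloc[0])


def rank_by_permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    config: PipelineConfig | None = None,
) -> ImportanceRanking:
    """Rank features by mean accuracy drop when each column is shuffled.

    ``model`` must already be fitted on (X, y); ranking is computed on the
    same (training) data, seeded from the config.
    """
    config = config or PipelineConfig()
    if len(pd.unique(np.asarray(y))) < 2:
        raise ValueError("permutation importance needs >= 2 classes")
    result = permutation_importance(
        model, X, y, scoring="accuracy",
        n_repeats=config.permutation_repeats,
        random_state=config.random_seed)
    table = pd.DataFrame({
        "feature": list(X.columns),
        "mean_importance": result.importances_mean,
    })
    for r in range(config.permutation_repeats):
        table[f"repeat_{r}"] = result.importances[:, r]
    table = table.sort_values(
        ["mean_importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    return ImportanceRanking(table=table)


def prune_redundant(
    ranking: ImportanceRanking,
    X: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[str]:
    """Greedy Spearman-redundancy pruning of the importance ranking.

    Only features with strictly positive mean importance are eligible; the
    top ``importance_top_k`` of those are scanned in descending importance,
    and a feature is kept iff its Spearman |rho| with every already-kept
    feature stays at or below the redundancy threshold. The panel size is
    data-driven, capped at ``panel_size_cap``.
    """
    config = config or PipelineConfig()
    eligible = ranking.table.loc[ranking.table["mean_importance"] > 0,
                                 "feature"].tolist()
    if not eligible:
        raise FeatureSelectionError(
            "no feature has positive permutation importance")
    candidates = eligible[: config.importance_top_k]

    if len(candidates) == 1:
        return candidates
    rho = X[candidates].corr(method="spearman")
    panel: list[str] = []
    for f in candidates:
        if len(panel) >= config.panel_size_cap:
            break
        ok = all(abs(rho.loc[f, k]) <= config.spearman_redundancy_threshold
                 for k in panel)
        if ok:
            panel.append(f)
    return panel
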