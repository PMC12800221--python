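"""Feature selection: bulk filter cascade, permutation importance,
Spearman-redundancy pruning — each checked against independent brute-force
oracles on small instances."""

import numpy as np
import pandas as pd
import pytest

import orgemt as og
from orgemt.config import PipelineConfig, feature_columns
from orgemt.features import (
    FeatureSelectionError,
    bulk_filter,
    prune_redundant,
    rank_by_permutation_importance,
)
from sklearn.ensemble import HistGradientBoostingClassifier


def greedy_correlation_oracle(X: pd.DataFrame, threshold: float) -> list[str]:
    """Independent re-statement of the drop rule: while any |r| > threshold
    pair exists, drop the involved feature with the largest mean absolute
    correlation (lexicographically first on ties)."""
    cols = list(X.columns)
    while True:
        corr = X[cols].corr().abs()
        for c in cols:
            corr.loc[c, c] = 0.0
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]
                 if corr.loc[a, b] > threshold]
        if not pairs:
            return cols
        involved = sorted({f for p in pairs for f in p})
        best, best_key = None, None
        for c in involved:
            key = (corr.loc[cols, c].mean(), )  # vs all remaining features
            if best is None or key > best_key or (
                    key == best_key and c < best):
                best, best_key = c, key
        cols.remove(best)


def _profiles(X: pd.DataFrame) -> pd.DataFrame:
    meta = pd.DataFrame({"plate_id": "p1", "well_id": "B02",
                         "field_id": np.arange(len(X)) + 1,
                         "condition": "Control"})
    return pd.concat([meta, X.reset_index(drop=True)], axis=1)


class TestBulkFilter:
    def test_constant_feature_dropped_low_variance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"A_cells": rng.normal(size=30),
                          "B_cells": np.full(30, 3.0)})
        out, report = bulk_filter(_profiles(X))
        frame = report.to_frame()
        assert frame.loc[frame.feature == "B_cells", "rule"].iloc[0] == \
            "low_variance"
        assert "B_cells" not in out.columns

    def test_duplicated_column_drops_exactly_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        X = pd.DataFrame({"A_cells": a, "B_cells": a.copy(),
                          "C_cells": rng.normal(size=40)})
        out, report = bulk_filter(_profiles(X))
        kept = set(feature_columns(out))
        assert len(kept & {"A_cells", "B_cells"}) == 1
        dropped = report.to_frame().query("rule == 'high_correlation'")
        assert len(dropped) == 1

    def test_blocklist_pattern(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({
            "Intensity_Mean_cells": rng.normal(size=30),
            "Correlation_Costes_DNA_cells": rng.normal(size=30)})
        out, report = bulk_filter(_profiles(X))
        frame = report.to_frame()
        assert frame.loc[frame.feature.str.contains("Costes"),
                         "rule"].iloc[0] == "blocklist"

    def test_na_feature_dropped_first(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"A_cells": rng.normal(size=30),
                          "B_cells": rng.normal(size=30)})
        X.loc[5, "B_cells"] = np.nan
        _, report = bulk_filter(_profiles(X))
        frame = report.to_frame()
        assert frame.loc[frame.feature == "B_cells", "rule"].iloc[0] == "na"

    def test_report_covers_every_feature_once(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 6)),
                         columns=[f"F{i}_cells" for i in range(6)])
        X["F1_cells"] = X["F0_cells"] + rng.normal(scale=1e-3, size=50)
        _, report = bulk_filter(_profiles(X))
        frame = report.to_frame()
        assert sorted(frame["feature"]) == sorted(X.columns)
        assert set(report.kept) | set(report.dropped) == set(X.columns)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(60, 8)),
                         columns=[f"F{i}_cells" for i in range(8)])
        X["F7_cells"] = -X["F2_cells"] + rng.normal(scale=0.01, size=60)
        once, _ = bulk_filter(_profiles(X))
        twice, _ = bulk_filter(once)
        assert feature_columns(once) == feature_columns(twice)

    @pytest.mark.parametrize("seed", range(5))
    def test_correlation_stage_matches_bruteforce(self, seed):
        """Kept set equals exhaustive greedy elimination on 6-feature toys
        with correlated blocks."""
        rng = np.random.default_rng(seed)
        n = 80
        base = rng.normal(size=(n, 3))
        X = pd.DataFrame({
            "A_cells": base[:, 0],
            "B_cells": base[:, 0] * 0.98 + rng.normal(scale=0.1, size=n),
            "C_cells": base[:, 1],
            "D_cells": -base[:, 1] + rng.normal(scale=0.05, size=n),
            "E_cells": base[:, 2],
            "F_cells": base[:, 0] + base[:, 1],
        })
        out, _ = bulk_filter(_profiles(X))
        expected = greedy_correlation_oracle(X, 0.9)
        assert feature_columns(out) == expected

    def test_all_dropped_raises_with_report(self):
        X = pd.DataFrame({"A_cells": np.full(30, 1.0)})
        with pytest.raises(FeatureSelectionError) as exc:
            bulk_filter(_profiles(X))
        assert exc.value.report is not None


def _separable_five_class(n_per=100, n_noise=4, seed=0):
    """One feature carries the 5-class signal; the rest are noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(5), n_per)
    signal = y * 3.0 + rng.normal(scale=0.3, size=len(y))
    X = pd.DataFrame({"signal": signal})
    for j in range(n_noise):
        X[f"noise{j}"] = rng.normal(size=len(y))
    return X, y


@pytest.fixture(scope="module")
def fitted():
    X, y = _separable_five_class()
    clf = HistGradientBoostingClassifier(random_state=0).fit(X, y)
    return clf, X, y


class TestPermutationImportance:
    def test_no_signal_feature_near_zero(self, fitted):
        clf, X, y = fitted
        ranking = rank_by_permutation_importance(
            clf, X, y, PipelineConfig(random_seed=0))
        for j in range(4):
            assert abs(ranking.mean_importance(f"noise{j}")) < 0.05

    def test_sole_informative_feature_drops_to_chance(self, fitted):
        """Permuting the only informative feature of a 5-class balanced
        problem sends accuracy to ~1/5, so importance ~ baseline - 0.2."""
        clf, X, y = fitted
        ranking = rank_by_permutation_importance(
            clf, X, y, PipelineConfig(random_seed=0))
        baseline = clf.score(X, y)
        imp = ranking.mean_importance("signal")
        assert imp == pytest.approx(baseline - 0.2, abs=0.07)

    def test_seeded_determinism(self, fitted):
        clf, X, y = fitted
        cfg = PipelineConfig(random_seed=42)
        a = rank_by_permutation_importance(clf, X, y, cfg)
        b = rank_by_permutation_importance(clf, X, y, cfg)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_repeat_count_and_sorting(self, fitted):
        clf, X, y = fitted
        cfg = PipelineConfig(random_seed=0, permutation_repeats=5)
        ranking = rank_by_permutation_importance(clf, X, y, cfg)
        assert [c for c in ranking.table.columns
                if c.startswith("repeat_")] == [f"repeat_{r}"
                                                for r in range(5)]
        imp = ranking.table["mean_importance"].to_numpy()
        assert (np.diff(imp) <= 1e-12).all()

    def test_single_class_rejected(self, fitted):
        clf, X, _ = fitted
        with pytest.raises(ValueError):
            rank_by_permutation_importance(clf, X, np.zeros(len(X)))


def greedy_prune_oracle(order, rho, threshold):
    """Brute-force greedy scan used to check prune_redundant."""
    panel = []
    for f in order:
        if all(abs(rho.loc[f, k]) <= threshold for k in panel):
            panel.append(f)
    return panel


class _FakeRanking:
    def __init__(self, importances):
        self.table = pd.DataFrame(
            {"feature": list(importances), "mean_importance":
             list(importances.values())}).sort_values(
            ["mean_importance", "feature"], ascending=[False, True]
        ).reset_index(drop=True)


class TestPruneRedundant:
    def test_hand_example(self):
        """f1 and f2 strongly rank-correlated -> f2 pruned, f3 kept."""
        rng = np.random.default_rng(0)
        n = 200
        f1 = rng.normal(size=n)
        f2 = f1 + rng.normal(scale=0.3, size=n)     # rho ~ 0.95
        f3 = rng.normal(size=n)
        X = pd.DataFrame({"f1": f1, "f2": f2, "f3": f3})
        rho = X.corr(method="spearman")
        assert abs(rho.loc["f1", "f2"]) > 0.75  # construction check
        ranking = _FakeRanking({"f1": 0.3, "f2": 0.2, "f3": 0.1})
        panel = prune_redundant(ranking, X, PipelineConfig(random_seed=0))
        assert panel == ["f1", "f3"]
        assert panel == greedy_prune_oracle(["f1", "f2", "f3"], rho, 0.75)

    def test_uncorrelated_keeps_topk(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(300, 6)),
                         columns=[f"f{i}" for i in range(6)])
        ranking = _FakeRanking({f"f{i}": 0.6 - 0.1 * i for i in range(6)})
        cfg = PipelineConfig(random_seed=1, importance_top_k=4)
        panel = prune_redundant(ranking, X, cfg)
        assert panel == ["f0", "f1", "f2", "f3"]

    def test_duplicate_pairs_reduced_to_single_members(self):
        rng = np.random.default_rng(2)
        n = 250
        parents = {f"p{i}": rng.normal(size=n) for i in range(5)}
        X = pd.DataFrame(parents)
        for i in range(5):
            X[f"d{i}"] = parents[f"p{i}"] + rng.normal(scale=0.01, size=n)
        imp = {c: 0.5 - 0.01 * j for j, c in enumerate(X.columns)}
        panel = prune_redundant(_FakeRanking(imp), X,
                                PipelineConfig(random_seed=2))
        for i in range(5):
            assert len({f"p{i}", f"d{i}"} & set(panel)) <= 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bruteforce_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 150, 7
        base = rng.normal(size=(n, 3))
        X = pd.DataFrame({
            f"g{j}": base[:, j % 3] * rng.uniform(0.5, 1)
            + rng.normal(scale=rng.uniform(0.2, 2), size=n)
            for j in range(k)})
        imp = {f"g{j}": float(rng.uniform(0.01, 0.5)) for j in range(k)}
        ranking = _FakeRanking(imp)
        cfg = PipelineConfig(random_seed=seed)
        panel = prune_redundant(ranking, X, cfg)
        rho = X.corr(method="spearman")
        assert panel == greedy_prune_oracle(ranking.table["feature"], rho,
                                            0.75)
        # direct invariant: panel max pairwise |rho| <= threshold
        for i, a in enumerate(panel):
            for b in panel[i + 1:]:
                assert abs(rho.loc[a, b]) <= 0.75

    def test_no_positive_importance_errors(self):
        X = pd.DataFrame({"f0": np.arange(10.0), "f1": np.arange(10.0)})
        with pytest.raises(FeatureSelectionError):
            prune_redundant(_FakeRanking({"f0": -0.1, "f1": 0.0}), X)


class TestPanelRecoveryProperty:
    def test_panel_prefers_informative_block_over_noise(self):
        """Across seeded runs on scaled plates, the selected panel contains
        signal-bearing features (informative block or their redundant
        copies) and no pure-noise feature in >= 95% of runs."""
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            cfg = og.SyntheticPlateConfig(
                wells_per_condition=6, fields_per_well=5, cells_per_field=60,
                n_informative=12, n_redundant=12, n_noise=40, seed=seed)
            cells = og.simulate_plate(cfg)
            prof = og.aggregate_per_field(cells)
            norm = og.apply_robustize(prof, og.fit_robustize(prof))
            pc = PipelineConfig(random_seed=seed)
            filt, _ = bulk_filter(norm, pc)
            X_tr, _, y_tr, _ = og.split_train_test(filt, filt["condition"],
                                                   pc)
            feats = feature_columns(filt)
            clf = HistGradientBoostingClassifier(
                random_state=seed).fit(X_tr[feats], y_tr)
            ranking = rank_by_permutation_importance(clf, X_tr[feats],
                                                     y_tr, pc)
            panel = prune_redundant(ranking, X_tr[feats], pc)
            has_signal = any("Informative" in f or "Redundant" in f
                             for f in panel)
            has_noise = any("Noise" in f for f in panel)
            hits += has_signal and not has_noise
        assert hits / n_runs >= 0.95
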