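"""Shared fixtures: tiny CellProfiler-style CSV exports, scaled synthetic
plates, and a trained model on clearly separable data."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import orgemt as og

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")
from orgemt.config import PipelineConfig, feature_columns


def write_compartment_csvs(tmp_path, nuclei, cytoplasm, cells):
    """Write three compartment DataFrames to CSVs and return their paths."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("nuclei", nuclei), ("cytoplasm", cytoplasm),
                     ("cells", cells)):
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths.append(p)
    return tuple(paths)


def toy_compartments(n=4):
    """Aligned 3-compartment toy exports with 2/2/2 features, n cells."""
    base = {
        "ImageNumber": [1] * (n // 2) + [2] * (n - n // 2),
        "ObjectNumber": list(range(1, n // 2 + 1)) + list(
            range(1, n - n // 2 + 1)),
        "Metadata_Plate": ["p1"] * n,
        "Metadata_Well": ["B02"] * (n // 2) + ["B03"] * (n - n // 2),
        "Metadata_Field": [1] * n,
    }
    rng = np.random.default_rng(0)
    nuc = pd.DataFrame({**base, "Area": rng.normal(size=n),
                        "Intensity": rng.normal(size=n)})
    cyt = pd.DataFrame({**base, "Area": rng.normal(size=n),
                        "Texture": rng.normal(size=n)})
    cel = pd.DataFrame({**base, "Area": rng.normal(size=n),
                        "Granularity": rng.normal(size=n)})
    return nuc, cyt, cel


@pytest.fixture(scope="session")
def small_plate_config():
    """A scaled-down plate keeping the 5-condition time-course structure."""
    return og.SyntheticPlateConfig(
        wells_per_condition=6, fields_per_well=5, cells_per_field=60,
        n_informative=12, n_redundant=12, n_noise=40, seed=11)


@pytest.fixture(scope="session")
def small_cells(small_plate_config):
    return og.simulate_plate(small_plate_config)


@pytest.fixture(scope="session")
def small_profiles(small_cells):
    """Aggregated + robustized + bulk-filtered small-plate profiles."""
    prof = og.aggregate_per_field(small_cells)
    norm = og.apply_robustize(prof, og.fit_robustize(prof))
    filt, _ = og.bulk_filter(norm, PipelineConfig(random_seed=11))
    return filt


@pytest.fixture(scope="session")
def trained_small(small_profiles, small_plate_config):
    """Trained final model + split on the small plate."""
    cfg = PipelineConfig(random_seed=11)
    X_tr, X_te, y_tr, y_te = og.split_train_test(
        small_profiles, small_profiles["condition"], cfg)
    feats = feature_columns(small_profiles)
    clf = og.default_classifier_suite(11)[-1].build().fit(X_tr[feats], y_tr)
    ranking = og.rank_by_permutation_importance(clf, X_tr[feats], y_tr, cfg)
    panel = og.prune_redundant(ranking, X_tr[feats], cfg)
    model = og.fit_final(X_tr, y_tr, panel, cfg,
                         class_order=list(small_plate_config.conditions))
    return {"model": model, "X_tr": X_tr, "X_te": X_te, "y_tr": y_tr,
            "y_te": y_te, "panel": panel, "config": cfg}
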