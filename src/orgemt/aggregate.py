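"""Per-field median aggregation and per-plate robustize normalization.

Single cells are collapsed to one profile per imaging field (the median of
each feature over the cells in that field); fields are the unit every later
stage consumes. Profiles are then normalized per plate with the robust scaler
x' = (x - median) / IQR, with the median and IQR taken per feature across all
conditions of the plate. The robust scaler is preferred over z-scoring for
aggregated profiles because it limits the influence of outlier fields.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import METADATA_COLUMNS, feature_columns

log = logging.getLogger(__name__)


def aggregate_per_field(cells: pd.DataFrame) -> pd.DataFrame:
    """Median-aggregate single cells to one profile per (plate, well, field).

    Metadata (including the condition label) is propagated; a field with zero
    cells simply produces no row. Quartile-free: the median of an even count
    is the mean of the middle pair.
    """
    feats = feature_columns(cells)
    grouped = cells.groupby(list(METADATA_COLUMNS), dropna=False, sort=True,
                            observed=True)
    out = grouped[feats].median().reset_index()
    return out


@dataclass
class NormalizationStats:
    """Per-plate, per-feature median and IQR (Q3 - Q1).

    ``medians`` and ``iqrs`` are DataFrames indexed by plate_id with one
    column per feature. Quartiles use linear interpolation between order
    statistics (numpy's default), fixed so normalization is bit-reproducible.
    """

    medians: pd.DataFrame
    iqrs: pd.DataFrame

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "medians": {p: self.medians.loc[p].to_dict()
                        for p in self.medians.index},
            "iqrs": {p: self.iqrs.loc[p].to_dict() for p in self.iqrs.index},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "NormalizationStats":
        with open(path) as fh:
            payload = json.load(fh)
        medians = pd.DataFrame(payload["medians"]).T
        iqrs = pd.DataFrame(payload["iqrs"]).T
        medians.index.name = iqrs.index.name = "plate_id"
        return cls(medians=medians, iqrs=iqrs)


def fit_robustize(profiles: pd.DataFrame) -> NormalizationStats:
    """Fit per-plate median/IQR over all profiles of each plate."""
    feats = feature_columns(profiles)
    grouped = profiles.groupby("plate_id", observed=True)[feats]
    medians = grouped.median()
    q3 = grouped.quantile(0.75)
    q1 = grouped.quantile(0.25)
    return NormalizationStats(medians=medians, iqrs=q3 - q1)


def apply_robustize(profiles: pd.DataFrame,
                    stats: NormalizationStats) -> pd.DataFrame:
    """Apply x' = (x - median)/IQR per plate and feature.

    Features with IQR = 0 on a plate map to 0 (they are removed later by the
    low-variance filter; zeros keep the matrix finite).
    """
    feats = feature_columns(profiles)
    missing_plates = set(profiles["plate_id"].unique()) - set(
        stats.medians.index)
    if missing_plates:
        raise KeyError(f"no normalization stats for plates {missing_plates}")
    missing_feats = set(feats) - set(stats.medians.columns)
    if missing_feats:
        raise KeyError(f"no normalization stats for features "
                       f"{sorted(missing_feats)[:5]}...")

    out = profiles.copy()
    values = out[feats].to_numpy(dtype=float)
    plates = out["plate_id"].to_numpy()
    for plate in np.unique(plates):
        rows = plates == plate
        med = stats.medians.loc[plate, feats].to_numpy(dtype=float)
        iqr = stats.iqrs.loc[plate, feats].to_numpy(dtype=float)
        centered = values[rows] - med
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(iqr > 0, centered / iqr, 0.0)
        values[rows] = scaled
    out[feats] = values
    return out
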