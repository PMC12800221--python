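"""Pipeline configuration and the single-cell / profile table conventions.

Tables throughout the package are plain :class:`pandas.DataFrame` objects with
a fixed set of metadata columns followed by real-valued feature columns whose
names end in a compartment suffix (``_nuclei``, ``_cytoplasm``, ``_cells``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Metadata columns of a SingleCellTable / AggregatedProfileMatrix, in order.
METADATA_COLUMNS = ("plate_id", "well_id", "field_id", "condition")

#: Valid compartment suffixes for feature names.
COMPARTMENTS = ("nuclei", "cytoplasm", "cells")


def feature_columns(df) -> list[str]:
    """Feature columns of a table: everything that is not metadata."""
    return [c for c in df.columns if c not in METADATA_COLUMNS]


@dataclass
class ColumnMap:
    """Names of the CellProfiler export columns, to absorb dialect drift
    (``Metadata_Well`` vs ``Image_Metadata_Well`` and so on)."""

    image_key: str = "ImageNumber"
    object_key: str = "ObjectNumber"
    plate: str = "Metadata_Plate"
    well: str = "Metadata_Well"
    field: str = "Metadata_Field"


@dataclass
class PipelineConfig:
    """Thresholds, counts and the seed that drive the whole pipeline.

    Parameters
    ----------
    variance_threshold:
        Features with variance below this (after normalization) are dropped.
    correlation_threshold:
        Pairwise Pearson |r| above this marks a feature pair as duplicated;
        one member of each such pair is dropped in the bulk filter.
    spearman_redundancy_threshold:
        During panel pruning a candidate is rejected if its Spearman |rho|
        with any already-kept feature exceeds this.
    importance_top_k:
        Number of top-ranked features entering redundancy pruning.
    panel_size_cap:
        Hard upper bound on the final panel size; the retained count is
        data-driven (typically well below the cap after pruning).
    permutation_repeats:
        Shuffles per feature in the permutation-importance test.
    cv_folds, cv_repeats:
        Stratified k-fold cross-validation design.
    test_fraction:
        Held-out fraction of the stratified train/test split.
    contamination:
        Expected outlier fraction for per-condition Isolation Forest removal.
    random_seed:
        Sole source of randomness; equal configs give identical runs.
    """

    variance_threshold: float = 0.01
    correlation_threshold: float = 0.9
    spearman_redundancy_threshold: float = 0.75
    importance_top_k: int = 25
    panel_size_cap: int = 25
    permutation_repeats: int = 5
    cv_folds: int = 5
    cv_repeats: int = 3
    test_fraction: float = 0.2
    contamination: float = 0.05
    random_seed: int = 0
    columns: ColumnMap = field(default_factory=ColumnMap)

    def __post_init__(self) -> None:
        for name in ("variance_threshold", "correlation_threshold",
                     "spearman_redundancy_threshold", "test_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must lie in [0, 1)")
        for name in ("importance_top_k", "panel_size_cap",
                     "permutation_repeats", "cv_folds", "cv_repeats"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")

    def fingerprint(self) -> dict:
        """JSON-serializable snapshot used in model manifests."""
        d = asdict(self)
        d["columns"] = asdict(self.columns)
        return d
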