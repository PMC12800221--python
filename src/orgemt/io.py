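"""Reading and merging CellProfiler-style per-compartment feature exports.

CellProfiler writes one CSV per segmented compartment (nuclei, cytoplasm,
whole cells), keyed by image and object number. The pipeline consumes a single
wide table: the three exports are suffixed by compartment, inner-joined on the
(image, object) key, and rows with any missing value are dropped at ingestion
(never imputed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

from .config import METADATA_COLUMNS, ColumnMap


class FormatError(ValueError):
    """A required key/metadata column is absent from an input table."""


class SchemaError(ValueError):
    """Feature names collide after compartment suffixing."""


class EmptyDataError(ValueError):
    """No rows survive merging and missing-value removal."""


class LabelingError(ValueError):
    """Wells in the table are not covered by the plate layout."""


@dataclass
class PlateLayout:
    """Mapping of wells to condition labels for one plate.

    ``conditions`` is the declared ordered list of labels; every mapped well
    must use one of them.
    """

    plate_id: str
    wells: dict[str, str]
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.conditions:
            bad = {w: c for w, c in self.wells.items()
                   if c not in self.conditions}
            if bad:
                raise LabelingError(
                    f"wells mapped to undeclared conditions: {bad}")
        else:
            # preserve first-appearance order
            seen: list[str] = []
            for c in self.wells.values():
                if c not in seen:
                    seen.append(c)
            self.conditions = seen

    @classmethod
    def from_csv(cls, path: str | os.PathLike, plate_id: str = "plate1",
                 conditions: list[str] | None = None) -> "PlateLayout":
        """Read a two-column ``well,condition`` CSV."""
        df = pd.read_csv(path, dtype=str)
        for col in ("well", "condition"):
            if col not in df.columns:
                raise FormatError(f"layout CSV must have a '{col}' column")
        return cls(plate_id=plate_id,
                   wells=dict(zip(df["well"], df["condition"])),
                   conditions=conditions or [])


def _read_one(path: str | os.PathLike, compartment: str,
              cols: ColumnMap) -> pd.DataFrame:
    df = pd.read_csv(path)
    for key in (cols.image_key, cols.object_key):
        if key not in df.columns:
            raise FormatError(
                f"{compartment} table {path!s} lacks key column {key!r}")
    meta = [c for c in df.columns if c.startswith("Metadata_")
            or "_Metadata_" in c]
    keys = [cols.image_key, cols.object_key]
    features = [c for c in df.columns if c not in meta and c not in keys]
    # columns already carrying a compartment suffix are kept verbatim
    from .config import COMPARTMENTS

    def suffixed(c: str) -> str:
        if any(c.endswith(f"_{comp}") for comp in COMPARTMENTS):
            return c
        return f"{c}_{compartment}"

    renamed = df[keys + meta + features].rename(
        columns={c: suffixed(c) for c in features})
    return renamed, [suffixed(c) for c in features], meta


def read_compartment_tables(
    nuclei_path: str | os.PathLike,
    cytoplasm_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    columns: ColumnMap | None = None,
) -> pd.DataFrame:
    """Merge the three per-compartment CSV exports into one SingleCellTable.

    Feature columns are suffixed ``_nuclei`` / ``_cytoplasm`` / ``_cells``;
    rows are inner-joined on (image number, object number), so a cell absent
    from any compartment table is dropped, and any row still containing a
    missing value is removed.

    Returns a DataFrame with metadata columns ``plate_id, well_id, field_id,
    condition`` (condition unset until :func:`attach_layout`) followed by the
    suffixed features.
    """
    cols = columns or ColumnMap()
    paths = {"nuclei": nuclei_path, "cytoplasm": cytoplasm_path,
             "cells": cells_path}
    frames: dict[str, pd.DataFrame] = {}
    feats: list[str] = []
    meta_cols: list[str] = []
    for comp, path in paths.items():
        frame, f, meta = _read_one(path, comp, cols)
        frames[comp] = frame
        feats.extend(f)
        if meta:
            meta_cols = meta
    if len(set(feats)) != len(feats):
        dupes = sorted({f for f in feats if feats.count(f) > 1})
        raise SchemaError(f"duplicate feature names after suffixing: {dupes}")

    keys = [cols.image_key, cols.object_key]
    merged = frames["nuclei"]
    for comp in ("cytoplasm", "cells"):
        other = frames[comp].drop(
            columns=[c for c in frames[comp].columns
                     if (c.startswith("Metadata_") or "_Metadata_" in c)
                     and c in merged.columns])
        merged = merged.merge(other, on=keys, how="inner")
    merged = merged.dropna(axis=0, how="any")
    if merged.empty:
        raise EmptyDataError("no cells survive merging and NA removal")

    # map CellProfiler metadata onto the pipeline's metadata columns
    def _meta(name: str) -> pd.Series:
        if name in merged.columns:
            return merged[name]
        raise FormatError(f"metadata column {name!r} absent from inputs")

    out = pd.DataFrame({
        "plate_id": _meta(cols.plate).astype(str),
        "well_id": _meta(cols.well).astype(str),
        "field_id": _meta(cols.field).astype(int),
        "condition": pd.Series([None] * len(merged), index=merged.index,
                               dtype=object),
    })
    feature_frame = merged[[c for c in merged.columns
                            if c not in keys and c not in meta_cols]]
    out = pd.concat([out, feature_frame.astype(float)], axis=1)
    return out.reset_index(drop=True)


def attach_layout(table: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Populate the condition column from a plate layout.

    Every well in the table must be mapped; unmapped wells raise
    :class:`LabelingError` naming them. Extra wells in the layout are ignored.
    """
    wells = set(table["well_id"].unique())
    unmapped = sorted(wells - set(layout.wells))
    if unmapped:
        raise LabelingError(f"wells without a condition label: {unmapped}")
    out = table.copy()
    out["condition"] = out["well_id"].map(layout.wells)
    return out
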