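"""Synthetic Cell Painting plates and EMT time-course expression matrices.

The plate generator emulates the statistical structure the pipeline assumes:
an ordered EMT time course mapped to latent positions t in [0, 1]; a block of
informative features responding linearly to t with mixed signs; redundant
features that copy informative parents plus small noise (to exercise the
correlation filters); pure-noise features; nested well and cell noise; and
optional shifted outlier wells. The expression generator produces log2
matrices in which hallmark genes are induced along a programmed log2
fold-change trajectory over a flat background.

Both generators are fully seeded: the same config yields a byte-identical
table. Feature responses are linear in the latent position — a deliberate
simplification of the nonlinear trajectory of a real time course, sufficient
for testing monotone score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COMPARTMENTS, METADATA_COLUMNS

_DEFAULT_CONDITIONS = ("Control", "TGFb_24h", "TGFb_48h", "TGFb_4d", "TGFb_8d")
_DEFAULT_POSITIONS = (0.0, 0.25, 0.45, 0.7, 1.0)
_DEFAULT_LOG2FC = (0.0, np.log2(2.92), np.log2(4.39), np.log2(4.92),
                   np.log2(6.07))


@dataclass
class SyntheticPlateConfig:
    """Design of one synthetic plate.

    Defaults mirror the reference experimental design: 5 time-course
    conditions, 10 wells per condition, 9 fields of view per well, about 120
    cells per field. Latent positions place the conditions along the EMT
    axis; effect_size scales how strongly informative features respond.
    """

    conditions: tuple[str, ...] = _DEFAULT_CONDITIONS
    latent_positions: tuple[float, ...] = _DEFAULT_POSITIONS
    wells_per_condition: int = 10
    fields_per_well: int = 9
    cells_per_field: int = 120  # Poisson mean, min 1 cell drawn
    n_informative: int = 50
    n_redundant: int = 100
    n_noise: int = 250
    effect_size: float = 1.0
    well_sd: float = 0.1
    cell_sd: float = 1.0
    redundant_sd: float = 0.05
    outlier_well_fraction: float = 0.0
    plate_id: str = "plate1"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.latent_positions):
            raise ValueError("one latent position per condition required")
        if not np.all(np.diff(self.latent_positions) > 0):
            raise ValueError("latent positions must be strictly increasing")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name in ("wells_per_condition", "fields_per_well",
                     "cells_per_field", "n_informative", "n_noise"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _feature_names(config: SyntheticPlateConfig) -> tuple[list[str], list[str], list[str]]:
    def names(prefix: str, n: int) -> list[str]:
        return [f"{prefix}_{j:03d}_{COMPARTMENTS[j % 3]}" for j in range(n)]

    return (names("Intensity_Informative", config.n_informative),
            names("Texture_Redundant", config.n_redundant),
            names("Granularity_Noise", config.n_noise))


def simulate_plate(config: SyntheticPlateConfig | None = None) -> pd.DataFrame:
    """Generate a SingleCellTable for one plate.

    Informative feature j of a cell in condition c:
    x = beta_j * t_c + well effect (Normal, well_sd) + cell noise
    (Normal, cell_sd), with beta_j = effect_size * s_j, s_j of alternating
    sign and magnitude drawn once per feature from Uniform(0.5, 1.5).
    Redundant features copy a cyclically-assigned informative parent plus
    Normal(0, redundant_sd) noise; noise features are pure Normal(0, cell_sd).
    A fraction of wells, chosen per condition, is shifted by 10 * cell_sd in
    every feature to act as outliers.
    """
    config = config or SyntheticPlateConfig()
    rng = np.random.default_rng(config.seed)
    inf_names, red_names, noise_names = _feature_names(config)
    n_inf = config.n_informative

    signs = np.where(np.arange(n_inf) % 2 == 0, 1.0, -1.0)
    beta = config.effect_size * signs * rng.uniform(0.5, 1.5, size=n_inf)
    parents = np.arange(config.n_redundant) % n_inf

    rows_meta = []
    blocks = []
    well_counter = 0
    for cond, t in zip(config.conditions, config.latent_positions):
        n_outlier = int(round(config.outlier_well_fraction
                              * config.wells_per_condition))
        outlier_wells = set(
            rng.choice(config.wells_per_condition, size=n_outlier,
                       replace=False).tolist()) if n_outlier else set()
        for w in range(config.wells_per_condition):
            well_counter += 1
            well_id = f"{chr(ord('B') + well_counter // 12)}" \
                      f"{2 + well_counter % 12:02d}"
            well_effect = rng.normal(0.0, config.well_sd, size=n_inf)
            shift = 10.0 * config.cell_sd if w in outlier_wells else 0.0
            for f in range(1, config.fields_per_well + 1):
                n_cells = max(1, rng.poisson(config.cells_per_field))
                inf = (beta * t + well_effect
                       + rng.normal(0.0, config.cell_sd, (n_cells, n_inf))
                       + shift)
                red = (inf[:, parents]
                       + rng.normal(0.0, config.redundant_sd,
                                    (n_cells, config.n_redundant)))
                noise = rng.normal(0.0, config.cell_sd,
                                   (n_cells, config.n_noise)) + shift
                blocks.append(np.hstack([inf, red, noise]))
                rows_meta.append((config.plate_id, well_id, f, cond, n_cells))

    meta = pd.DataFrame(
        [(p, w, f, c) for p, w, f, c, n in rows_meta for _ in range(n)],
        columns=list(METADATA_COLUMNS))
    values = pd.DataFrame(np.vstack(blocks),
                          columns=inf_names + red_names + noise_names)
    return pd.concat([meta, values], axis=1)


@dataclass
class SyntheticExpressionConfig:
    """Design of a synthetic log2 expression time course.

    Hallmark genes follow the programmed per-timepoint mean log2 fold change
    (default: the published hallmark fold-change trajectory 1 / 2.92 / 4.39 /
    4.92 / 6.07 on the linear scale) plus Normal noise; background genes stay
    flat. ``replicates`` samples per timepoint, named ``<label>_r<i>``.
    """

    timepoints: tuple[str, ...] = _DEFAULT_CONDITIONS
    log2fc: tuple[float, ...] = _DEFAULT_LOG2FC
    n_hallmark: int = 122
    n_background: int = 500
    baseline_log2: float = 5.0
    noise_sd: float = 0.1
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.log2fc):
            raise ValueError("one log2FC per timepoint required")
        if self.log2fc[0] != 0.0:
            raise ValueError("control log2FC must be 0")
        for name in ("n_hallmark", "n_background", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def simulate_expression(
    config: SyntheticExpressionConfig | None = None,
) -> tuple[pd.DataFrame, "GeneSet"]:
    """Generate a log2 genes x samples matrix and its hallmark gene set.

    Returns ``(expr, hallmark_set)`` where ``expr.attrs['scale'] == 'log2'``
    and samples are ordered by timepoint then replicate.
    """
    from .calibrate import GeneSet  # deferred to avoid import cycle

    config = config or SyntheticExpressionConfig()
    rng = np.random.default_rng(config.seed)
    hallmark = [f"HEMT{j:03d}" for j in range(config.n_hallmark)]
    background = [f"BG{j:04d}" for j in range(config.n_background)]
    samples = [f"{tp}_r{i + 1}" for tp in config.timepoints
               for i in range(config.replicates)]
    fc = np.repeat(np.asarray(config.log2fc), config.replicates)

    hm = (config.baseline_log2 + fc[None, :]
          + rng.normal(0.0, config.noise_sd,
                       (config.n_hallmark, len(samples))))
    bg = (config.baseline_log2
          + rng.normal(0.0, config.noise_sd,
                       (config.n_background, len(samples))))
    expr = pd.DataFrame(np.vstack([hm, bg]), index=hallmark + background,
                        columns=samples)
    expr.attrs["scale"] = "log2"
    return expr, GeneSet(name="HALLMARK_EMT_SYNTHETIC", genes=hallmark)
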