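"""Transcriptomic EMT scores used to calibrate the progression weights.

The hallmark score is the geometric mean of hallmark-EMT gene expression on
the linear scale; progression weights are its per-timepoint fold change
versus control. Two established reference scores are provided for
comparison: the KS score (signed Kolmogorov-Smirnov-type distance between
epithelial- and mesenchymal-set expression distributions within a sample;
positive = mesenchymal-shifted) and the 76GS score (weighted sum of 76
EMT-related genes with weights equal to each gene's correlation with CDH1;
higher = more epithelial).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .score import ProgressionWeights


@dataclass
class GeneSet:
    """A named list of unique gene symbols."""

    name: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene symbols must be unique")


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            # de-duplicate preserving order
            seen: list[str] = []
            for g in genes:
                if g not in seen:
                    seen.append(g)
            sets.append(GeneSet(name=name, genes=seen))
    return sets


def read_expression(path: str | os.PathLike, scale: str = "log2",
                    sep: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix (first column gene symbols).

    ``scale`` is recorded in ``df.attrs['scale']`` ('log2' or 'linear').
    Rows with any missing value are dropped; duplicate symbols are an error.
    """
    if scale not in ("log2", "linear"):
        raise ValueError("scale must be 'log2' or 'linear'")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.dropna(axis=0, how="any").astype(float)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
    df.attrs["scale"] = scale
    return df


def _linear(expr: pd.DataFrame) -> pd.DataFrame:
    scale = expr.attrs.get("scale", "log2")
    if scale == "log2":
        return 2.0 ** expr
    return expr


def hallmark_score(expr: pd.DataFrame,
                   gene_set: GeneSet) -> tuple[pd.Series, list[str]]:
    """Per-sample geometric mean of linear-scale expression over the set.

    log2 input (``expr.attrs['scale'] == 'log2'``, the default) is
    exponentiated internally. Returns the per-sample scores and the list of
    set genes missing from the matrix. Non-positive linear values are an
    error — no silent offset is applied.
    """
    present = [g for g in gene_set.genes if g in expr.index]
    missing = [g for g in gene_set.genes if g not in expr.index]
    if not present:
        raise ValueError(f"no gene of set {gene_set.name!r} is in the matrix")
    lin = _linear(expr.loc[present])
    if (lin.to_numpy() <= 0).any():
        raise ValueError("non-positive linear expression; geometric mean "
                         "undefined (no offset is applied)")
    scores = pd.Series(gmean(lin.to_numpy(), axis=0), index=expr.columns,
                       name="hallmark_score")
    return scores, missing


def derive_weights(scores: pd.Series | dict[str, float],
                   control: str) -> ProgressionWeights:
    """Progression weights: fold change of per-timepoint score vs control.

    w_t = score(t) / score(control), so w(control) = 1 exactly.
    """
    scores = pd.Series(scores, dtype=float)
    if control not in scores.index:
        raise KeyError(f"control label {control!r} not among timepoints")
    ref = scores[control]
    if ref == 0:
        raise ValueError("control score is zero; fold change undefined")
    w = (scores / ref).to_dict()
    w[control] = 1.0
    return ProgressionWeights(weights=w)


def ks_score(expr: pd.DataFrame, epithelial: GeneSet,
             mesenchymal: GeneSet) -> pd.Series:
    """Signed two-sided KS statistic per sample, in [-1, 1].

    With F_E and F_M the empirical CDFs of the epithelial- and
    mesenchymal-set expression values within a sample,
    score = max(F_E - F_M) - max(F_M - F_E): positive means the mesenchymal
    genes sit higher (mesenchymal-shifted sample). No hypothesis-test gating
    is applied — the statistic itself is the score.
    """
    epi = [g for g in epithelial.genes if g in expr.index]
    mes = [g for g in mesenchymal.genes if g in expr.index]
    if not epi or not mes:
        raise ValueError("both gene-set intersections must be nonempty")
    out = {}
    for sample in expr.columns:
        e = np.sort(expr.loc[epi, sample].to_numpy(dtype=float))
        m = np.sort(expr.loc[mes, sample].to_numpy(dtype=float))
        grid = np.concatenate([e, m])
        F_e = np.searchsorted(e, grid, side="right") / len(e)
        F_m = np.searchsorted(m, grid, side="right") / len(m)
        out[sample] = float(np.max(F_e - F_m) - np.max(F_m - F_e))
    return pd.Series(out, name="ks_score")


def gs76_score(expr: pd.DataFrame, genes76: GeneSet,
               anchor: str = "CDH1") -> pd.Series:
    """76GS-style epithelial score per sample.

    Each set gene g gets weight w_g = Pearson correlation with the anchor
    gene (CDH1) across samples (constant genes get w_g = 0); expression is
    mean-centered per gene and the score is the weighted sum
    score_s = sum_g w_g * x~_{g,s}. Higher = more epithelial.
    """
    if anchor not in expr.index:
        raise KeyError(f"anchor gene {anchor!r} not in the matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation weights")
    present = [g for g in genes76.genes if g in expr.index]
    if not present:
        raise ValueError("no set gene present in the matrix")
    X = expr.loc[present].to_numpy(dtype=float)
    a = expr.loc[anchor].to_numpy(dtype=float)
    a_c = a - a.mean()
    X_c = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((X_c ** 2).sum(axis=1)) * np.sqrt((a_c ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, (X_c @ a_c) / denom, 0.0)
    scores = w @ X_c
    return pd.Series(scores, index=expr.columns, name="gs76_score")
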