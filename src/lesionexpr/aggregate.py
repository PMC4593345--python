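"""Gene-panel filtering and quality-weighted probe-set → gene aggregation.

A curated panel of epithelial-identity / mammary-remodeling genes is first
restricted to the genes actually mappable on the target array (those with
at least one scored probe set).  Probe-set expression is then collapsed to
one gene-level value per sample, weighting each probe set's log2 value by
its semi-sum quality weight.

Two collapse rules are provided:

* ``literal`` (default) — the gene value is the arithmetic mean of
  ``weight × expression`` over the gene's probe sets.  Low-quality probe
  sets shrink the gene value toward 0.
* ``normalized`` — a weighted mean, ``Σ(weight × expression) / Σ weight``,
  which leaves a gene measured by a single perfect probe set unchanged and
  does not shrink low-quality genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import normalize_symbol

__all__ = ["GenePanel", "FilterReport", "filter_panel", "aggregate_to_genes"]


@dataclass(frozen=True)
class GenePanel:
    """An ordered gene-symbol manifest (symbols unique after normalization)."""

    genes: tuple[str, ...]

    def __post_init__(self):
        normed = tuple(normalize_symbol(g) for g in self.genes)
        if len(set(normed)) != len(normed):
            dupes = sorted({g for g in normed if normed.count(g) > 1})
            raise ValueError(f"duplicate gene symbols in panel after normalization: {dupes}")
        object.__setattr__(self, "genes", normed)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes


@dataclass(frozen=True)
class FilterReport:
    n_panel: int
    n_retained: int
    n_dropped: int
    n_probe_sets: int
    dropped_genes: tuple[str, ...]


def filter_panel(panel: GenePanel, weights: pd.DataFrame) -> tuple[GenePanel, FilterReport]:
    """Restrict a panel to genes with at least one quality-weight record.

    Mirrors the platform-mapping bookkeeping of the study design: genes
    with no probe set on the array are dropped before analysis.
    """
    if len(panel) == 0:
        raise ValueError("empty gene panel")
    mapped = {normalize_symbol(g) for g in weights["gene"]}
    retained = tuple(g for g in panel.genes if g in mapped)
    dropped = tuple(g for g in panel.genes if g not in mapped)
    if not retained:
        raise ValueError("no panel gene has a probe set on this platform")
    n_probe_sets = weights.loc[
        weights["gene"].map(normalize_symbol).isin(retained), "probe_set_id"
    ].nunique()
    report = FilterReport(
        n_panel=len(panel),
        n_retained=len(retained),
        n_dropped=len(dropped),
        n_probe_sets=int(n_probe_sets),
        dropped_genes=dropped,
    )
    return GenePanel(retained), report


def aggregate_to_genes(
    expr: pd.DataFrame,
    weights: pd.DataFrame,
    mode: str = "literal",
    panel: GenePanel | None = None,
) -> pd.DataFrame:
    """Collapse a probe-set × sample matrix to a gene × sample matrix.

    Parameters
    ----------
    expr
        Probe-set × sample log2 expression matrix (NaN allowed).
    weights
        Quality-weight records (``probe_set_id``, ``gene``, ``weight``);
        a probe set mapping to several genes contributes to each with its
        own per-gene weight.
    mode
        ``"literal"`` or ``"normalized"`` (see module docstring).
    panel
        Optional panel restricting (and ordering) the output genes;
        default: all genes in *weights*, alphabetically.

    Missing probe-set values are excluded pairwise; a gene × sample cell
    with no observed probe set is NaN in the output.  Genes with no probe
    set present in the matrix are dropped with a warning.
    """
    if mode not in ("literal", "normalized"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("expression matrix has duplicated row or column labels")

    w = weights.copy()
    w["gene"] = w["gene"].map(normalize_symbol)
    genes = tuple(panel.genes) if panel is not None else tuple(sorted(w["gene"].unique()))
    w = w[w["gene"].isin(genes)]

    in_matrix = w["probe_set_id"].isin(expr.index)
    missing_genes = sorted(set(w.loc[~in_matrix, "gene"]) - set(w.loc[in_matrix, "gene"]))
    usable = [g for g in genes if g not in missing_genes and g in set(w["gene"])]
    absent = [g for g in genes if g not in set(w["gene"])]
    if missing_genes or absent:
        warnings.warn(
            f"dropping {len(missing_genes) + len(absent)} gene(s) with no probe set "
            f"in the expression matrix: {sorted(missing_genes + absent)[:10]}...",
            stacklevel=2,
        )
    w = w[in_matrix & w["gene"].isin(usable)]
    if w.empty:
        raise ValueError("no (probe set, gene) weight record overlaps the expression matrix")

    sub = expr.loc[w["probe_set_id"].to_numpy()].to_numpy(dtype=float)
    wv = w["weight"].to_numpy(dtype=float)[:, None]
    wx = pd.DataFrame(sub * wv, index=pd.Index(w["gene"], name="gene"), columns=expr.columns)
    if mode == "literal":
        out = wx.groupby(level=0).mean()
    else:
        observed = ~np.isnan(sub)
        wsum = pd.DataFrame(
            observed * wv, index=pd.Index(w["gene"], name="gene"), columns=expr.columns
        ).groupby(level=0).sum()
        out = wx.groupby(level=0).sum(min_count=1) / wsum.where(wsum > 0)
    return out.reindex([g for g in genes if g in usable])
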