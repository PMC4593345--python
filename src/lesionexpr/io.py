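"""Readers and writers for the pipeline's tab-separated artifacts.

Everything on disk is UTF-8, LF-terminated TSV.  Writers can prepend
``#``-prefixed metadata lines (tool version, config hash, seed) which all
readers skip.  Undefined confidence bounds are serialized as the literal
token ``ND``.  Expression matrices are additionally readable in the GEO
series-matrix dialect (header lines prefixed ``!``, data between
``!series_matrix_table_begin`` / ``!series_matrix_table_end``).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import GenePanel
from .de import DEResultTable, StudyDesign

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_panel",
    "write_panel",
    "read_weights",
    "write_weights",
    "write_match_table",
    "read_gene_list",
    "write_gene_list",
    "write_de_table",
    "read_de_table",
    "write_forest_data",
    "write_overlap_report",
]

ND_TOKEN = "ND"


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    pairs = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# lesionexpr={__version__} {pairs}\n"


def _write_frame(df: pd.DataFrame, path, meta: dict | None, index: bool, float_fmt=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_lines(meta))
        df.to_csv(fh, sep="\t", index=index, float_format=float_fmt, lineterminator="\n")


def read_expression(path, dialect: str = "tsv", log2_transform: bool = False) -> pd.DataFrame:
    """Read a probe-set × sample expression matrix.

    ``dialect="tsv"`` expects row labels in the first column; ``dialect=
    "series_matrix"`` parses the GEO series-matrix export.  With
    ``log2_transform`` the (strictly positive) values are log2-transformed
    on read, for files deposited on the linear scale.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif dialect == "series_matrix":
        df = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown expression dialect {dialect!r}")

    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicated probe-set row label(s): {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError("duplicated sample column label(s)")
    if df.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 samples")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        nonnum = df[col].notna() & bad.isna()
        if nonnum.any():
            row = df.index[nonnum.to_numpy().argmax()]
            raise ValueError(f"non-numeric expression value at row {row!r}, column {col!r}")
        df[col] = bad
    df = df.astype(float)
    if log2_transform:
        if (df.to_numpy() <= 0).any():
            raise ValueError("log2 transform requested but matrix has values ≤ 0")
        df = np.log2(df)
    df.index = df.index.map(str)
    df.index.name = "probe_set_id"
    return df


def _read_series_matrix(path) -> pd.DataFrame:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    data: list[str] = []
    in_table = False
    for line in lines:
        stripped = line.strip()
        if stripped.lower() == "!series_matrix_table_begin":
            in_table = True
            continue
        if stripped.lower() == "!series_matrix_table_end":
            in_table = False
            continue
        if in_table:
            data.append(line)
        elif stripped.startswith("!") or not stripped:
            continue
        else:
            data.append(line)  # tolerate files without explicit table markers
    if not data:
        raise ValueError(f"no data table found in series-matrix file {path!s}")
    buf = _io.StringIO("\n".join(data))
    df = pd.read_csv(buf, sep="\t", index_col=0)
    df.index = df.index.map(lambda s: str(s).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def write_expression(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_frame(df, path, meta, index=True)


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return StudyDesign(df)


def write_design(design: StudyDesign, path, meta: dict | None = None) -> None:
    _write_frame(design.table, path, meta, index=False)


def read_panel(path) -> GenePanel:
    """Read a gene-panel manifest: TSV with a ``gene`` column, or one symbol per line."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty gene panel file {path!s}")
    if "\t" in lines[0] or lines[0].strip().lower() == "gene":
        df = pd.read_csv(_io.StringIO("\n".join(lines)), sep="\t", dtype=str)
        if "gene" not in df.columns:
            raise ValueError(f"panel file {path!s} has no 'gene' column")
        genes = list(df["gene"])
    else:
        genes = [ln.strip() for ln in lines]
    return GenePanel(tuple(genes))


def write_panel(panel: GenePanel, path, meta: dict | None = None) -> None:
    _write_frame(pd.DataFrame({"gene": list(panel.genes)}), path, meta, index=False)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_set_id": str, "gene": str})
    required = ["probe_set_id", "gene", "sensitivity", "specificity", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weights table {path!s} is missing columns: {missing}")
    return df


def write_weights(weights: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_frame(weights, path, meta, index=False, float_fmt="%.6f")


def write_match_table(table, path, meta: dict | None = None) -> None:
    """Write a :class:`~lesionexpr.annotation.ProbeMatchTable` as tidy TSV."""
    rows = [
        {"probe_set_id": ps, "probe_id": probe, "matched_genes": ";".join(sorted(genes))}
        for ps in table.probe_set_ids
        for probe, genes in table.matches[ps].items()
    ]
    _write_frame(pd.DataFrame(rows), path, meta, index=False)


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path, meta: dict | None = None) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(_meta_lines(meta))
        for g in genes:
            fh.write(f"{g}\n")


def write_de_table(table: DEResultTable, path, meta: dict | None = None) -> None:
    """Write one contrast's per-gene results; undefined CI bounds become ``ND``."""
    df = table.results.reset_index()
    for col in ("ci_low", "ci_high"):
        df[col] = [f"{v:.6g}" if np.isfinite(v) else ND_TOKEN for v in df[col]]
    full_meta = {"contrast": table.contrast, "fdr_cutoff": table.cutoff,
                 "n_significant": table.n_significant}
    full_meta.update(meta or {})
    _write_frame(df, path, full_meta, index=False, float_fmt="%.6g")


def read_de_table(path, cutoff: float = 0.1) -> DEResultTable:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[ND_TOKEN], dtype={"gene": str})
    if "reason" in df.columns:
        df["reason"] = df["reason"].fillna("")
    else:
        df["reason"] = ""
    contrast = Path(path).stem
    return DEResultTable(contrast=contrast, results=df.set_index("gene"), cutoff=cutoff)


def write_forest_data(table: DEResultTable, path, meta: dict | None = None) -> None:
    """Export forest-plot rows (gene, estimate, lower, upper, direction) for a contrast."""
    res = table.results.loc[table.results["significant"]]
    df = pd.DataFrame(
        {
            "gene": res.index,
            "estimate": res["fold_change"].to_numpy(),
            "lower": [f"{v:.6g}" if np.isfinite(v) else ND_TOKEN for v in res["ci_low"]],
            "upper": [f"{v:.6g}" if np.isfinite(v) else ND_TOKEN for v in res["ci_high"]],
            "direction": np.where(res["fold_change"] > 0, "up", "down"),
        }
    ).sort_values("estimate", kind="stable")
    _write_frame(df, path, meta, index=False, float_fmt="%.6g")


def write_overlap_report(report, path, meta: dict | None = None) -> None:
    df = report.to_frame()
    full_meta = {
        "lists": f"{report.list_labels[0]}|{report.list_labels[1]}",
        "n_common": report.n_common,
        "n_exclusive_first": report.n_exclusive_first,
        "n_exclusive_second": report.n_exclusive_second,
    }
    full_meta.update(meta or {})
    _write_frame(df, path, full_meta, index=False)
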