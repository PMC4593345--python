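"""End-to-end pipeline: score → filter → aggregate → DE → overlap.

A :class:`PipelineConfig` names the four inputs (probe match table,
probe-set expression matrix, study design, gene panel) and the analysis
settings; :func:`run_pipeline` executes the stages in order and writes
every artifact as TSV with a metadata header (tool version, config hash,
seed), so a rerun with the same config is file-identical.  Progress and
per-stage gene counts go to the logger (stderr by default), never into
result files.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import annotation, io
from .aggregate import aggregate_to_genes, filter_panel
from .de import run_de
from .overlap import classify_overlap

logger = logging.getLogger("lesionexpr")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    matrix: str
    matches: str
    design: str
    panel: str
    outdir: str = "results"
    mode: str = "literal"
    dialect: str = "tsv"
    log2_transform: bool = False
    paired: bool = False
    fdr_cutoff: float = 0.1
    contrasts: tuple[tuple[str, str], ...] = ()
    seed: int | None = None
    log_level: str = "INFO"
    _extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not 0.0 < self.fdr_cutoff < 1.0:
            raise ValueError(f"fdr_cutoff must lie in (0, 1); got {self.fdr_cutoff}")
        if self.mode not in ("literal", "normalized"):
            raise ValueError(f"unknown aggregation mode {self.mode!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file (``#`` comments allowed)."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line (expected key = value): {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            kv[key] = value
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        kwargs: dict = {}
        extra: dict = {}
        for key, value in kv.items():
            if key not in known:
                extra[key] = value
                continue
            if key in ("log2_transform", "paired"):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif key == "fdr_cutoff":
                kwargs[key] = float(value)
            elif key == "seed":
                kwargs[key] = int(value)
            elif key == "contrasts":
                kwargs[key] = tuple(
                    tuple(pair.split(":", 1)) for pair in value.split(",") if pair.strip()
                )
            else:
                kwargs[key] = value
        cfg = cls(**kwargs)
        cfg._extra = extra
        return cfg

    def config_hash(self) -> str:
        items = sorted(
            (f.name, getattr(self, f.name)) for f in fields(self) if not f.name.startswith("_")
        )
        digest = hashlib.sha256(repr(items).encode("utf-8")).hexdigest()
        return digest[:12]

    def validate_paths(self) -> None:
        for name in ("matrix", "matches", "design", "panel"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and return the paths of the written artifacts."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.config_hash(), "seed": config.seed if config.seed is not None else "-"}
    written: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    t = stage("score")
    table = annotation.parse_probe_match_table(config.matches)
    weights = annotation.compute_quality_weights(table)
    written["weights"] = outdir / "quality_weights.tsv"
    io.write_weights(weights, written["weights"], meta)
    logger.info(
        "stage score: %d probe sets, %d (probe set, gene) records [%.2fs]",
        len(table.probe_set_ids), len(weights), time.perf_counter() - t,
    )

    t = stage("aggregate")
    panel = io.read_panel(config.panel)
    kept, report = filter_panel(panel, weights)
    logger.info(
        "panel: %d genes, %d retained, %d dropped (no probe set), %d probe sets",
        report.n_panel, report.n_retained, report.n_dropped, report.n_probe_sets,
    )
    expr = io.read_expression(config.matrix, config.dialect, config.log2_transform)
    gene_matrix = aggregate_to_genes(expr, weights, mode=config.mode, panel=kept)
    written["gene_matrix"] = outdir / "gene_expression.tsv"
    io.write_expression(gene_matrix, written["gene_matrix"], meta)
    logger.info(
        "stage aggregate: %d genes × %d samples [%.2fs]",
        *gene_matrix.shape, time.perf_counter() - t,
    )

    t = stage("de")
    design = io.read_design(config.design)
    contrasts = list(config.contrasts) if config.contrasts else None
    de_tables = run_de(
        gene_matrix, design, contrasts=contrasts,
        cutoff=config.fdr_cutoff, paired=config.paired,
    )
    for label, table_ in de_tables.items():
        written[f"de_{label}"] = outdir / f"de_{label}.tsv"
        io.write_de_table(table_, written[f"de_{label}"], meta)
        written[f"forest_{label}"] = outdir / f"forest_{label}.tsv"
        io.write_forest_data(table_, written[f"forest_{label}"], meta)
        logger.info(
            "contrast %s: %d/%d genes significant at FDR < %s",
            label, table_.n_significant, len(table_.results), config.fdr_cutoff,
        )
    logger.info("stage de done [%.2fs]", time.perf_counter() - t)

    if len(de_tables) >= 2:
        t = stage("overlap")
        labels = list(de_tables)
        first, second = de_tables[labels[0]], de_tables[labels[1]]
        report_ = classify_overlap(
            first.significant_genes(), second.significant_genes(),
            labels=(labels[0], labels[1]),
            changes_a=first.signed_changes(), changes_b=second.signed_changes(),
        )
        written["overlap"] = outdir / "overlap_report.tsv"
        io.write_overlap_report(report_, written["overlap"], meta)
        logger.info(
            "overlap %s vs %s: %d common / %d / %d exclusive [%.2fs]",
            labels[0], labels[1], report_.n_common,
            report_.n_exclusive_first, report_.n_exclusive_second,
            time.perf_counter() - t,
        )
    return written
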