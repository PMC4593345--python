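"""Synthetic microarray studies with known ground truth.

Generates probe-level studies carrying the statistical structure the
pipeline assumes — multiple probe sets per gene, cross-hybridizing probes,
patient-matched samples with a shared patient random effect, planted log2
fold changes and Gaussian noise — so that every analysis stage can be
exercised end to end with a known answer.

Generative model for probe set *ps* of gene *g*, sample *s* of patient *i*
in tissue class *c* (all on the log2 scale):

    x[ps, s] = mu_g + a_ps + b_i + delta_{g,c} + eps[ps, s]

with gene baseline mu_g ~ N(8, 1), probe-set offset a_ps ~ N(0,
probe_set_offset_sd²), patient effect b_i ~ N(0, patient_sd²) shared by
all of a patient's samples, planted effect delta zero for the reference
class and for non-DE genes, and noise eps ~ N(0, noise_sd²).  The shared
b_i induces within-patient correlation, so paired and unpaired analyses
are distinguishable.  A configurable fraction of probes additionally
matches a random second gene (driving specificity below 1), and a
configurable fraction of panel genes receives no probe sets at all
(driving panel-filter drops).  All draws flow from a single seeded
generator stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aggregate import GenePanel
from .annotation import ProbeMatchTable
from .de import DEResultTable, StudyDesign

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "SimulatedStudy",
    "RecoveryReport",
    "simulate_study",
    "evaluate_recovery",
]

PAIRED_CLASSES = ("TDLU", "HELU")
MATCHED_CLASSES = ("HN", "ADH", "DCIS")


@dataclass(frozen=True)
class SimulationParams:
    """Study-generator settings; defaults mirror the paired HELU design.

    The first entry of ``classes`` is the reference tissue; every other
    class receives the planted effect of a DE gene.  ``effect_size`` is a
    log2 difference; with ``signed_effects`` each DE gene is up- or
    down-regulated with equal probability.
    """

    n_patients: int = 8
    classes: tuple[str, ...] = PAIRED_CLASSES
    n_genes: int = 369
    probe_sets_per_gene: tuple[int, int] = (1, 3)
    probes_per_set: tuple[int, int] = (8, 11)
    frac_promiscuous_probes: float = 0.1
    frac_unmatched_genes: float = 8 / 369
    n_de_genes: int = 30
    effect_size: float = 2.0
    signed_effects: bool = True
    noise_sd: float = 0.5
    patient_sd: float = 0.5
    probe_set_offset_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if len(self.classes) < 2 or len(set(self.classes)) != len(self.classes):
            raise ValueError("classes must be ≥2 distinct tissue labels")
        if not 0 <= self.n_de_genes <= self.n_genes:
            raise ValueError("n_de_genes must lie in [0, n_genes]")
        for name in ("noise_sd", "patient_sd", "probe_set_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        for name in ("frac_promiscuous_probes", "frac_unmatched_genes"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("probe_sets_per_gene", "probes_per_set"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a (low ≥ 1, high ≥ low) range")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth aligned with the emitted study artifacts.

    ``genes`` is indexed by gene symbol with columns ``mapped`` (has ≥1
    probe set), ``is_de``, ``effect`` (signed planted log2 change, 0 for
    non-DE genes) and ``baseline``; ``probe_sets`` is indexed by
    probe_set_id with columns ``gene`` and ``offset``.
    """

    genes: pd.DataFrame
    probe_sets: pd.DataFrame
    reference_class: str

    def effect_of(self, gene: str) -> float:
        return float(self.genes.loc[gene, "effect"])

    @property
    def de_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["is_de"]])

    @property
    def mapped_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["mapped"]])


@dataclass(frozen=True)
class SimulatedStudy:
    expression: pd.DataFrame
    match_table: ProbeMatchTable
    design: StudyDesign
    panel: GenePanel
    truth: SimulationTruth
    params: SimulationParams = field(repr=False, default=None)


def simulate_study(params: SimulationParams) -> SimulatedStudy:
    """Draw one complete synthetic study from the generative model."""
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i + 1:04d}" for i in range(params.n_genes)]

    n_unmatched = int(round(params.frac_unmatched_genes * params.n_genes))
    unmatched = set(rng.choice(genes, size=n_unmatched, replace=False)) if n_unmatched else set()
    mapped = [g for g in genes if g not in unmatched]
    if params.n_de_genes > len(mapped):
        raise ValueError("n_de_genes exceeds the number of platform-mapped genes")
    de_genes = set(rng.choice(mapped, size=params.n_de_genes, replace=False))

    baseline = dict(zip(genes, params.baseline_mean + params.baseline_sd * rng.standard_normal(params.n_genes)))
    signs = {
        g: (rng.choice([-1.0, 1.0]) if params.signed_effects else 1.0) if g in de_genes else 0.0
        for g in genes
    }

    # probe sets and probe-level match records
    records: list[tuple[str, str, list[str]]] = []
    ps_rows = []
    lo_ps, hi_ps = params.probe_sets_per_gene
    lo_pr, hi_pr = params.probes_per_set
    for g in mapped:
        n_ps = int(rng.integers(lo_ps, hi_ps + 1))
        for j in range(n_ps):
            ps_id = f"{g}_ps{j + 1}"
            offset = params.probe_set_offset_sd * rng.standard_normal()
            ps_rows.append({"probe_set_id": ps_id, "gene": g, "offset": offset})
            n_probes = int(rng.integers(lo_pr, hi_pr + 1))
            for q in range(n_probes):
                matches = [g]
                # cross-hybridization targets another *mapped* gene: a gene with
                # no probe sets on the array has no annotation record to match
                if rng.random() < params.frac_promiscuous_probes and len(mapped) > 1:
                    other = g
                    while other == g:
                        other = mapped[int(rng.integers(len(mapped)))]
                    matches.append(other)
                records.append((ps_id, f"{ps_id}_p{q + 1}", matches))
    probe_sets = pd.DataFrame(ps_rows).set_index("probe_set_id")
    match_table = ProbeMatchTable.from_records(records)

    # design: one sample per patient per class
    patients = [f"P{i + 1:02d}" for i in range(params.n_patients)]
    design_rows = [
        {"sample_id": f"{p}_{c}", "patient_id": p, "tissue_class": c}
        for p in patients
        for c in params.classes
    ]
    design = StudyDesign(pd.DataFrame(design_rows))
    sample_ids = [r["sample_id"] for r in design_rows]
    patient_effect = dict(zip(patients, params.patient_sd * rng.standard_normal(len(patients))))
    reference = params.classes[0]

    ps_ids = list(probe_sets.index)
    ps_gene = probe_sets["gene"].to_numpy()
    ps_offset = probe_sets["offset"].to_numpy()
    mu = np.array([baseline[g] for g in ps_gene])
    effect = np.array([signs[g] * params.effect_size for g in ps_gene])
    cols = {}
    for row in design_rows:
        delta = effect if row["tissue_class"] != reference else 0.0
        cols[row["sample_id"]] = (
            mu
            + ps_offset
            + patient_effect[row["patient_id"]]
            + delta
            + params.noise_sd * rng.standard_normal(len(ps_ids))
        )
    expression = pd.DataFrame(cols, index=pd.Index(ps_ids, name="probe_set_id"))[sample_ids]

    genes_df = pd.DataFrame(
        {
            "mapped": [g not in unmatched for g in genes],
            "is_de": [g in de_genes for g in genes],
            "effect": [signs[g] * params.effect_size for g in genes],
            "baseline": [baseline[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    truth = SimulationTruth(genes=genes_df, probe_sets=probe_sets, reference_class=reference)
    return SimulatedStudy(
        expression=expression,
        match_table=match_table,
        design=design,
        panel=GenePanel(tuple(genes)),
        truth=truth,
        params=params,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion counts of a DE analysis against the planted truth."""

    tp: int
    fp: int
    fn: int
    tn: int
    empirical_fdr: float
    power: float
    ci_coverage: float
    n_ci_defined: int
    mean_fc_error: float

    @property
    def n_discoveries(self) -> int:
        return self.tp + self.fp


def evaluate_recovery(results: DEResultTable, truth: SimulationTruth) -> RecoveryReport:
    """Score one contrast's results against the simulation ground truth.

    Empirical FDR is FP / max(1, discoveries); power is TP / planted;
    CI coverage is the fraction of defined intervals containing the true
    planted effect (0 for non-DE genes); ``mean_fc_error`` averages
    (estimate − truth) over planted DE genes.
    """
    res = results.results
    result_genes = set(res.index)
    if result_genes != truth.mapped_genes:
        raise ValueError(
            "result table and simulation truth cover different gene universes "
            f"({len(result_genes)} vs {len(truth.mapped_genes)} genes)"
        )
    true_effect = truth.genes.loc[res.index, "effect"].to_numpy()
    is_de = truth.genes.loc[res.index, "is_de"].to_numpy()
    called = res["significant"].to_numpy()

    tp = int(np.sum(called & is_de))
    fp = int(np.sum(called & ~is_de))
    fn = int(np.sum(~called & is_de))
    tn = int(np.sum(~called & ~is_de))

    lo = res["ci_low"].to_numpy(dtype=float)
    hi = res["ci_high"].to_numpy(dtype=float)
    defined = np.isfinite(lo) & np.isfinite(hi)
    covered = defined & (lo <= true_effect) & (true_effect <= hi)
    n_def = int(defined.sum())

    fc = res["fold_change"].to_numpy(dtype=float)
    de_mask = is_de & np.isfinite(fc)
    mean_err = float(np.mean(fc[de_mask] - true_effect[de_mask])) if de_mask.any() else float("nan")

    return RecoveryReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        empirical_fdr=fp / max(1, tp + fp),
        power=tp / max(1, tp + fn),
        ci_coverage=float(covered.sum() / n_def) if n_def else float("nan"),
        n_ci_defined=n_def,
        mean_fc_error=mean_err,
    )
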