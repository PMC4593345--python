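"""Patient-matched differential expression with BH-FDR control.

Per-gene contrasts between tissue classes (e.g. HELU vs TDLU, ADH vs HN,
DCIS vs HN) are summarized by a log2 fold change — the difference of class
means on the log2 scale — with a 95% t confidence interval, a p-value, and
a Benjamini–Hochberg adjusted q-value.  Significance uses a strict
``q < cutoff`` with the study's conventional cutoff of 0.1.

Two analysis modes are exposed, since both study designs sample lesion and
reference tissue from the same patient:

* unpaired (default) — one-way ANOVA across the classes of the contrast;
  the F statistic for two classes equals the square of the pooled
  two-sample t statistic.  Conservative when a shared patient effect is
  present.
* paired — within-patient differences (lesion minus reference), tested
  with a one-sample t; removes the patient random effect.

FDR is applied per contrast, across all analysis genes of that contrast's
list.  Confidence intervals that cannot be estimated (zero standard error
or fewer than one degree of freedom) are reported as not determined (ND).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StudyDesign",
    "AnovaResult",
    "ContrastEstimate",
    "DEResultTable",
    "anova_f",
    "contrast_estimate",
    "bh_adjust",
    "run_de",
]

#: smallest representable positive p-value, reported for degenerate tests
#: (zero within-class variance with a nonzero between-class difference)
TINY_P = float(np.nextafter(0.0, 1.0))

PAIRED_LAYOUT = frozenset({"TDLU", "HELU"})
MATCHED_LAYOUT = frozenset({"HN", "ADH", "DCIS"})


@dataclass(frozen=True)
class StudyDesign:
    """Sample → patient → tissue-class mapping.

    ``table`` has columns ``sample_id``, ``patient_id``, ``tissue_class``;
    each sample belongs to exactly one class.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = ["sample_id", "patient_id", "tissue_class"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"study design is missing columns: {missing}")
        t = self.table[required].astype(str).reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            dupes = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"duplicate sample ids in design: {dupes}")
        object.__setattr__(self, "table", t)

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["tissue_class"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in_class(self, tissue_class: str) -> list[str]:
        sel = self.table["tissue_class"] == tissue_class
        return list(self.table.loc[sel, "sample_id"])

    def class_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"unknown sample {sample_id!r}")
        return row["tissue_class"].iloc[0]

    def complete_pairs(self, case_class: str, ref_class: str) -> list[tuple[str, str, str]]:
        """Patients with exactly one sample in each of the two classes.

        Returns (patient_id, case_sample, ref_sample) triples in patient order.
        """
        out = []
        for patient, grp in self.table.groupby("patient_id", sort=True):
            case = grp.loc[grp["tissue_class"] == case_class, "sample_id"]
            ref = grp.loc[grp["tissue_class"] == ref_class, "sample_id"]
            if len(case) == 1 and len(ref) == 1:
                out.append((patient, case.iloc[0], ref.iloc[0]))
        return out

    def default_contrasts(self) -> list[tuple[str, str]]:
        """Lesion-vs-reference contrasts implied by the tissue classes."""
        classes = set(self.classes)
        if classes == PAIRED_LAYOUT:
            return [("HELU", "TDLU")]
        if classes == MATCHED_LAYOUT:
            return [("ADH", "HN"), ("DCIS", "HN")]
        raise ValueError(
            f"cannot infer contrasts for tissue classes {sorted(classes)}; "
            "specify them explicitly as (case, reference) pairs"
        )


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    degenerate: bool = False


@dataclass(frozen=True)
class ContrastEstimate:
    """Log2 fold change (case − reference) with a t confidence interval.

    ``ci_low``/``ci_high`` are NaN when the interval is not determined
    (zero standard error or df < 1).
    """

    fold_change: float
    ci_low: float
    ci_high: float
    se: float
    df: int

    @property
    def ci_defined(self) -> bool:
        return math.isfinite(self.ci_low) and math.isfinite(self.ci_high)


def _f_stat(groups: list[np.ndarray]) -> tuple[float, int, int, bool]:
    """One-way ANOVA F with (k−1, N−k) df; flags the zero-within-variance case."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(float(g.sum()) for g in groups) / n_total
    ss_between = sum(len(g) * (float(g.mean()) - grand) ** 2 for g in groups)
    ss_within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within <= 0.0:
        if ss_between <= 0.0:
            return 0.0, df_b, df_w, False  # all values identical
        return math.inf, df_b, df_w, True
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w, False


def anova_f(values: pd.Series, design: StudyDesign) -> AnovaResult:
    """One-way ANOVA of one gene's expression across tissue classes.

    *values* is indexed by sample id; classes are taken from the design.
    Requires ≥2 classes with ≥2 samples each among the non-missing values.
    """
    values = values.dropna()
    labels = np.array([design.class_of(s) for s in values.index])
    groups = [values.to_numpy(dtype=float)[labels == c] for c in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two tissue classes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires at least two samples per class")
    f, df_b, df_w, degenerate = _f_stat(groups)
    if degenerate:
        return AnovaResult(f, TINY_P, df_b, df_w, degenerate=True)
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f, p, df_b, df_w)


def _unpaired_estimate(case: np.ndarray, ref: np.ndarray, conf: float) -> ContrastEstimate:
    fc = float(case.mean() - ref.mean())
    n1, n2 = len(case), len(ref)
    df = n1 + n2 - 2
    if df < 1:
        return ContrastEstimate(fc, math.nan, math.nan, math.nan, df)
    pooled_var = (
        ((case - case.mean()) ** 2).sum() + ((ref - ref.mean()) ** 2).sum()
    ) / df
    se = math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return ContrastEstimate(fc, math.nan, math.nan, 0.0, df)
    half = float(stats.t.ppf(0.5 + conf / 2.0, df)) * se
    return ContrastEstimate(fc, fc - half, fc + half, se, df)


def _paired_estimate(diffs: np.ndarray, conf: float) -> ContrastEstimate:
    fc = float(diffs.mean())
    df = len(diffs) - 1
    if df < 1:
        return ContrastEstimate(fc, math.nan, math.nan, math.nan, df)
    se = float(diffs.std(ddof=1) / math.sqrt(len(diffs)))
    if se == 0.0:
        return ContrastEstimate(fc, math.nan, math.nan, 0.0, df)
    half = float(stats.t.ppf(0.5 + conf / 2.0, df)) * se
    return ContrastEstimate(fc, fc - half, fc + half, se, df)


def contrast_estimate(
    values: pd.Series,
    design: StudyDesign,
    case_class: str,
    reference_class: str,
    paired: bool = False,
    conf: float = 0.95,
) -> ContrastEstimate:
    """Estimate the log2 fold change of one gene for a two-class contrast.

    Unpaired: difference of class means with a pooled-SE t interval on
    n1 + n2 − 2 df.  Paired: mean of within-patient (case − reference)
    differences with an SE from those differences on n − 1 df.
    """
    values = values.dropna()
    if paired:
        pairs = design.complete_pairs(case_class, reference_class)
        pairs = [
            (pt, cs, rs) for pt, cs, rs in pairs if cs in values.index and rs in values.index
        ]
        if not pairs:
            raise ValueError(
                f"paired contrast {case_class} vs {reference_class}: no complete patient pairs"
            )
        diffs = np.array([values[cs] - values[rs] for _, cs, rs in pairs], dtype=float)
        return _paired_estimate(diffs, conf)
    case = values[[s for s in values.index if design.class_of(s) == case_class]]
    ref = values[[s for s in values.index if design.class_of(s) == reference_class]]
    if case.empty or ref.empty:
        raise ValueError(f"both classes must be present: {case_class} vs {reference_class}")
    return _unpaired_estimate(case.to_numpy(dtype=float), ref.to_numpy(dtype=float), conf)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    ``q_(i) = min_{j ≥ i} p_(j)·m/j`` over the order statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResultTable:
    """Per-gene results of one contrast.

    ``results`` is indexed by gene with columns ``fold_change``, ``ci_low``,
    ``ci_high``, ``p_value``, ``q_value``, ``significant``, ``reason``
    (empty for clean rows; e.g. ``too_few_samples`` for ND rows excluded
    from the FDR adjustment).
    """

    contrast: str
    results: pd.DataFrame
    cutoff: float = 0.1

    @property
    def n_significant(self) -> int:
        return int(self.results["significant"].sum())

    def significant_genes(self) -> set[str]:
        return set(self.results.index[self.results["significant"]])

    def signed_changes(self) -> dict[str, float]:
        sig = self.results.loc[self.results["significant"], "fold_change"]
        return {g: float(v) for g, v in sig.items()}


def _contrast_core(
    case_mat: np.ndarray,
    ref_mat: np.ndarray,
    paired: bool,
    conf: float,
) -> tuple[list[ContrastEstimate], np.ndarray, np.ndarray, list[str]]:
    """Per-gene estimates and test statistics for one contrast.

    Returns estimates, a t-or-F statistic array, a df array (df2 for F),
    and a per-gene reason code ("" = testable).
    """
    n_genes = case_mat.shape[0]
    estimates: list[ContrastEstimate] = []
    stat = np.full(n_genes, np.nan)
    dfs = np.full(n_genes, np.nan)
    reasons = [""] * n_genes
    for i in range(n_genes):
        if paired:
            d = case_mat[i] - ref_mat[i]
            d = d[~np.isnan(d)]
            if len(d) < 2:
                reasons[i] = "too_few_samples"
                estimates.append(
                    ContrastEstimate(
                        float(np.nanmean(case_mat[i]) - np.nanmean(ref_mat[i]))
                        if len(d) > 0
                        else math.nan,
                        math.nan, math.nan, math.nan, len(d) - 1,
                    )
                )
                continue
            est = _paired_estimate(d, conf)
            estimates.append(est)
            if est.se == 0.0 or not math.isfinite(est.se):
                reasons[i] = "zero_variance" if est.fold_change != 0.0 else "constant"
                continue
            stat[i] = est.fold_change / est.se
            dfs[i] = est.df
        else:
            cv = case_mat[i][~np.isnan(case_mat[i])]
            rv = ref_mat[i][~np.isnan(ref_mat[i])]
            if len(cv) < 2 or len(rv) < 2:
                reasons[i] = "too_few_samples"
                fc = float(cv.mean() - rv.mean()) if len(cv) and len(rv) else math.nan
                estimates.append(ContrastEstimate(fc, math.nan, math.nan, math.nan, 0))
                continue
            estimates.append(_unpaired_estimate(cv, rv, conf))
            f, _, df_w, degenerate = _f_stat([cv, rv])
            if degenerate:
                reasons[i] = "zero_variance"
            elif f == 0.0 and not np.isfinite(estimates[-1].se):
                reasons[i] = "constant"
            else:
                stat[i] = f
                dfs[i] = df_w
    return estimates, stat, dfs, reasons


def run_de(
    matrix: pd.DataFrame,
    design: StudyDesign,
    contrasts: list[tuple[str, str]] | None = None,
    cutoff: float = 0.1,
    paired: bool = False,
    conf: float = 0.95,
) -> dict[str, DEResultTable]:
    """Differential expression for each contrast of a gene × sample matrix.

    For every contrast, per-gene p-values come from a one-way ANOVA
    restricted to the two classes (or a paired t when ``paired``);
    q-values from a BH adjustment across all testable genes of that
    contrast; fold changes and CIs from :func:`contrast_estimate`.  Genes
    with fewer than two usable samples in a class get an ND row with a
    reason code and are excluded from the adjustment.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"FDR cutoff must lie in (0, 1); got {cutoff}")
    if contrasts is None:
        contrasts = design.default_contrasts()
    known = set(design.classes)
    for case, ref in contrasts:
        if case not in known or ref not in known:
            raise ValueError(f"contrast {case} vs {ref} references unknown tissue classes")

    out: dict[str, DEResultTable] = {}
    genes = list(matrix.index)
    for case, ref in contrasts:
        if paired:
            pairs = design.complete_pairs(case, ref)
            if not pairs:
                raise ValueError(f"paired contrast {case} vs {ref}: no complete patient pairs")
            case_cols = [cs for _, cs, _ in pairs]
            ref_cols = [rs for _, _, rs in pairs]
        else:
            case_cols = [s for s in design.samples_in_class(case) if s in matrix.columns]
            ref_cols = [s for s in design.samples_in_class(ref) if s in matrix.columns]
        case_mat = matrix[case_cols].to_numpy(dtype=float)
        ref_mat = matrix[ref_cols].to_numpy(dtype=float)

        estimates, stat, dfs, reasons = _contrast_core(case_mat, ref_mat, paired, conf)
        p = np.full(len(genes), np.nan)
        testable = np.isfinite(stat)
        if paired:
            p[testable] = 2.0 * stats.t.sf(np.abs(stat[testable]), dfs[testable])
        else:
            p[testable] = stats.f.sf(stat[testable], 1, dfs[testable])
        # degenerate tests: perfectly separated classes with zero within-class
        # variance get the smallest representable p rather than an exact zero
        for i, reason in enumerate(reasons):
            if reason == "zero_variance":
                p[i] = TINY_P
            elif reason == "constant":
                p[i] = 1.0
        p = np.where(np.isfinite(p), np.clip(p, TINY_P, 1.0), np.nan)

        q = np.full(len(genes), np.nan)
        adjustable = np.isfinite(p)
        if adjustable.any():
            q[adjustable] = bh_adjust(p[adjustable])
        frame = pd.DataFrame(
            {
                "fold_change": [e.fold_change for e in estimates],
                "ci_low": [e.ci_low for e in estimates],
                "ci_high": [e.ci_high for e in estimates],
                "p_value": p,
                "q_value": q,
                "significant": [bool(qv < cutoff) if math.isfinite(qv) else False for qv in q],
                "reason": reasons,
            },
            index=pd.Index(genes, name="gene"),
        )
        label = f"{case}_vs_{ref}"
        out[label] = DEResultTable(contrast=label, results=frame, cutoff=cutoff)
    return out
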