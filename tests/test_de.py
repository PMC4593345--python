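"""ANOVA, fold-change CIs, BH adjustment and the per-contrast DE driver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lesionexpr import (
    SimulationParams,
    StudyDesign,
    aggregate_to_genes,
    anova_f,
    bh_adjust,
    compute_quality_weights,
    contrast_estimate,
    run_de,
    simulate_study,
)
from lesionexpr.de import TINY_P
from oracles import brute_anova_f, brute_bh, pooled_t


def two_class_design(n1, n2):
    rows = [{"sample_id": f"a{i}", "patient_id": f"pa{i}", "tissue_class": "HELU"}
            for i in range(n1)]
    rows += [{"sample_id": f"b{i}", "patient_id": f"pb{i}", "tissue_class": "TDLU"}
             for i in range(n2)]
    return StudyDesign(pd.DataFrame(rows))


def series(case_vals, ref_vals):
    idx = [f"a{i}" for i in range(len(case_vals))] + [f"b{i}" for i in range(len(ref_vals))]
    return pd.Series(list(case_vals) + list(ref_vals), index=idx, dtype=float)


class TestAnova:
    def test_textbook_example_f_equals_8(self):
        design = two_class_design(2, 2)
        res = anova_f(series([1, 2], [3, 4]), design)
        assert res.f == pytest.approx(8.0)
        assert res.f == pytest.approx(pooled_t([1, 2], [3, 4]) ** 2)
        assert res.p == pytest.approx(float(stats.f.sf(8.0, 1, 2)))

    def test_identical_data_gives_f_zero_p_one(self):
        res = anova_f(series([2, 2], [2, 2]), two_class_design(2, 2))
        assert res.f == 0.0 and res.p == 1.0 and not res.degenerate

    def test_equal_means_nonzero_variance(self):
        res = anova_f(series([1, 3], [2, 2]), two_class_design(2, 2))
        assert res.f == pytest.approx(brute_anova_f([[1, 3], [2, 2]]))

    def test_zero_within_class_variance_is_degenerate(self):
        rows = [{"sample_id": f"s{i}", "patient_id": f"p{i}", "tissue_class": c}
                for i, c in enumerate(["HN", "HN", "ADH", "ADH", "DCIS", "DCIS"])]
        design = StudyDesign(pd.DataFrame(rows))
        values = pd.Series([0, 0, 1, 1, 2, 2], index=[f"s{i}" for i in range(6)], dtype=float)
        res = anova_f(values, design)
        assert res.degenerate
        assert res.p == TINY_P

    def test_requires_two_samples_per_class(self):
        with pytest.raises(ValueError, match="two samples"):
            anova_f(series([1.0], [2, 3]), two_class_design(1, 2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_two_class_f_equals_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8, size=2)
        a, b = rng.normal(0, 1, n1), rng.normal(0.5, 1.2, n2)
        design = two_class_design(n1, n2)
        res = anova_f(series(a, b), design)
        assert abs(res.f - pooled_t(a, b) ** 2) < 1e-10
        assert res.f == pytest.approx(brute_anova_f([a, b]))

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 1, 5) for i in range(3)]
        rows = [{"sample_id": f"s{i}{j}", "patient_id": f"p{i}{j}", "tissue_class": f"c{i}"}
                for i in range(3) for j in range(5)]
        values = pd.Series(np.concatenate(groups),
                           index=[f"s{i}{j}" for i in range(3) for j in range(5)])
        res = anova_f(values, StudyDesign(pd.DataFrame(rows)))
        f_ref, p_ref = stats.f_oneway(*groups)
        assert res.f == pytest.approx(float(f_ref))
        assert res.p == pytest.approx(float(p_ref))


class TestContrastEstimate:
    def test_unpaired_hand_example(self):
        est = contrast_estimate(series([3, 4], [1, 2]), two_class_design(2, 2), "HELU", "TDLU")
        assert est.fold_change == pytest.approx(2.0)
        half = stats.t.ppf(0.975, 2) * math.sqrt(0.5 * (0.5 + 0.5))
        assert est.ci_low == pytest.approx(2.0 - half)
        assert est.ci_high == pytest.approx(2.0 + half)
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (-1.04, 5.04)

    def test_identical_classes_centre_zero(self):
        est = contrast_estimate(series([1, 2], [1, 2]), two_class_design(2, 2), "HELU", "TDLU")
        assert est.fold_change == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_zero_variance_gives_nd_interval(self):
        est = contrast_estimate(series([2, 2], [1, 1]), two_class_design(2, 2), "HELU", "TDLU")
        assert est.fold_change == 1.0
        assert not est.ci_defined

    def test_paired_uses_within_patient_differences(self, paired_design):
        # constant per-patient difference: fold change exact, zero SE -> ND CI
        vals = pd.Series({f"P{i}_HELU": i + 1.0 for i in range(1, 5)}
                         | {f"P{i}_TDLU": float(i) for i in range(1, 5)})
        est = contrast_estimate(vals, paired_design, "HELU", "TDLU", paired=True)
        assert est.fold_change == pytest.approx(1.0)
        assert not est.ci_defined

    def test_paired_without_complete_pairs_is_error(self):
        design = two_class_design(2, 2)  # distinct patients per class: no pairs
        with pytest.raises(ValueError, match="complete patient pairs"):
            contrast_estimate(series([1, 2], [3, 4]), design, "HELU", "TDLU", paired=True)

    def test_paired_ci_covers_at_nominal_rate(self, paired_design):
        rng = np.random.default_rng(5)
        hits = 0
        n = 400
        for _ in range(n):
            diffs = rng.normal(1.0, 0.7, 4)
            base = rng.normal(8, 1, 4)
            vals = pd.Series(
                {f"P{i}_TDLU": base[i - 1] for i in range(1, 5)}
                | {f"P{i}_HELU": base[i - 1] + diffs[i - 1] for i in range(1, 5)}
            )
            est = contrast_estimate(vals, paired_design, "HELU", "TDLU", paired=True)
            hits += est.ci_low <= 1.0 <= est.ci_high
        assert hits / n == pytest.approx(0.95, abs=0.04)


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal_p(self):
        assert bh_adjust([0.05] * 10) == pytest.approx([0.05] * 10)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.2], [float("nan")]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_matches_step_up_oracle_and_invariants(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(brute_bh(p))
        assert np.all(q >= np.asarray(p) - 1e-15)  # q >= p elementwise
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)  # monotone in p-order
        # re-adjusting q preserves the weak ordering (ties may be introduced)
        q2 = bh_adjust(q)
        for i in range(len(q)):
            for j in range(len(q)):
                if q[i] < q[j]:
                    assert q2[i] <= q2[j] + 1e-15


def run_paired_pipeline(params):
    study = simulate_study(params)
    weights = compute_quality_weights(study.match_table)
    matrix = aggregate_to_genes(study.expression, weights,
                                panel=None, mode="literal")
    return study, run_de(matrix, study.design, paired=True)["HELU_vs_TDLU"]


class TestRunDE:
    def test_single_gene_q_equals_p(self, paired_design):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 1.5, 2.5, 3.0, 4.0, 3.5, 4.5]],
            index=["G"],
            columns=[f"P{i}_{c}" for i in range(1, 5) for c in ("TDLU", "HELU")],
        )
        res = run_de(matrix, paired_design)["HELU_vs_TDLU"].results
        assert res.loc["G", "q_value"] == pytest.approx(res.loc["G", "p_value"])

    def test_null_study_reference_run_has_no_discoveries(self):
        params = SimulationParams(n_genes=360, n_de_genes=0, frac_unmatched_genes=0.0, seed=11)
        _, table = run_paired_pipeline(params)
        assert table.n_significant == 0

    def test_planted_effects_all_recovered(self):
        # 30 genes at log2 effect 2.0 with noise 0.5 over 8 pairs: power ≈ 1
        params = SimulationParams(
            n_genes=360, n_de_genes=30, effect_size=2.0, noise_sd=0.5,
            frac_unmatched_genes=0.0, frac_promiscuous_probes=0.0, seed=3,
        )
        study, table = run_paired_pipeline(params)
        assert study.truth.de_genes <= table.significant_genes()

    def test_gene_with_too_few_samples_gets_nd_row(self, paired_design):
        cols = [f"P{i}_{c}" for i in range(1, 5) for c in ("TDLU", "HELU")]
        matrix = pd.DataFrame(np.random.default_rng(0).normal(8, 1, (2, 8)),
                              index=["G1", "G2"], columns=cols)
        matrix.loc["G2", [c for c in cols if "HELU" in c][:3]] = np.nan
        res = run_de(matrix, paired_design, paired=True)["HELU_vs_TDLU"].results
        assert res.loc["G2", "reason"] == "too_few_samples"
        assert np.isnan(res.loc["G2", "q_value"]) and not res.loc["G2", "significant"]
        assert res.loc["G1", "reason"] == ""

    def test_unpaired_null_p_values_are_uniform(self):
        """With no patient effect, per-gene ANOVA p-values are U(0,1) under the null."""
        params = SimulationParams(
            n_genes=5000, n_de_genes=0, patient_sd=0.0, probe_sets_per_gene=(1, 1),
            frac_unmatched_genes=0.0, frac_promiscuous_probes=0.0, seed=29,
        )
        study = simulate_study(params)
        weights = compute_quality_weights(study.match_table)
        matrix = aggregate_to_genes(study.expression, weights)
        table = run_de(matrix, study.design, paired=False)["HELU_vs_TDLU"]
        p = table.results["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_cutoff_validation(self, paired_design):
        matrix = pd.DataFrame(np.zeros((1, 8)), index=["G"],
                              columns=[f"P{i}_{c}" for i in range(1, 5) for c in ("TDLU", "HELU")])
        with pytest.raises(ValueError, match="cutoff"):
            run_de(matrix, paired_design, cutoff=1.5)

    def test_triplet_layout_default_contrasts(self):
        params = SimulationParams(classes=("HN", "ADH", "DCIS"), n_genes=50,
                                  n_de_genes=5, frac_unmatched_genes=0.0, seed=2)
        study = simulate_study(params)
        weights = compute_quality_weights(study.match_table)
        matrix = aggregate_to_genes(study.expression, weights)
        tables = run_de(matrix, study.design, paired=True)
        assert set(tables) == {"ADH_vs_HN", "DCIS_vs_HN"}
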