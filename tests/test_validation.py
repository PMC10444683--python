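"""Validation battery: formulas, pass rules, and fixture reproduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoquant.exceptions import DomainError, InsufficientDataError
from nucleoquant.validation import (
    accuracy_pct,
    assess_accuracy_precision,
    ion_ratio_check,
    isr_evaluate,
    isr_percent_difference,
    matrix_effect_cv,
    precision_cv,
    recovery_pct,
    selectivity_check,
    stability_assess,
    summarize_ranges,
)


class TestAccuracyPrecision:
    def test_accuracy_hand_values(self):
        assert accuracy_pct([10, 10, 10], 10) == 100.0
        assert accuracy_pct([9, 10, 11], 10) == pytest.approx(100.0)
        assert accuracy_pct([8.5], 10) == 85.0

    def test_accuracy_errors(self):
        with pytest.raises(InsufficientDataError):
            accuracy_pct([], 10)
        with pytest.raises(DomainError):
            accuracy_pct([1.0], 0.0)

    def test_cv_hand_values(self):
        assert precision_cv([5, 5, 5, 5]) == 0.0
        assert precision_cv([9, 10, 11]) == pytest.approx(10.0)

    def test_cv_needs_two(self):
        with pytest.raises(InsufficientDataError):
            precision_cv([5.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k=st.floats(0.01, 1000.0))
    def test_cv_scale_invariant(self, k):
        base = np.array([9.0, 10.0, 11.0, 10.5])
        assert precision_cv(k * base) == pytest.approx(precision_cv(base), rel=1e-9)

    def _runs(self, values_by_run, analyte="Ino", level="HQC", nominal=2.0):
        rows = []
        for run, values in values_by_run.items():
            for v in values:
                rows.append(
                    {"analyte_code": analyte, "level": level, "nominal_uM": nominal,
                     "run": run, "conc_uM": v}
                )
        return pd.DataFrame(rows)

    def test_exact_replicates_pass(self):
        res = assess_accuracy_precision(self._runs({1: [2.0] * 6, 2: [2.0] * 6}))
        by_scope = {r.scope: r for r in res}
        assert by_scope["within_run"].accuracy_pct == 100.0
        assert by_scope["within_run"].cv_pct == 0.0
        assert by_scope["between_run"].n == 12
        assert all(r.pass_accuracy and r.pass_precision for r in res)

    def test_hqc_accuracy_within_15_passes(self):
        res = assess_accuracy_precision(self._runs({1: [0.9245 * 2.0] * 6}))
        within = [r for r in res if r.scope == "within_run"][0]
        assert within.accuracy_pct == pytest.approx(92.45)
        assert within.pass_accuracy

    def test_lloq_accuracy_beyond_20_fails(self):
        df = self._runs({1: [0.79 * 0.05] * 6}, level="LLOQ", nominal=0.05)
        res = assess_accuracy_precision(df)
        within = [r for r in res if r.scope == "within_run"][0]
        assert within.accuracy_pct == pytest.approx(79.0)
        assert not within.pass_accuracy

    def test_missing_cell_absent_not_failed(self):
        df = self._runs({1: [2.0]})  # one replicate: neither scope computable
        assert assess_accuracy_precision(df) == []


class TestMatrixEffect:
    def test_identical_areas_no_effect(self):
        res = matrix_effect_cv([5, 6, 7], [5, 6, 7], [9, 9, 9], [9, 9, 9])
        assert all(m == 1.0 for m in res.mf_analyte)
        assert res.me_cv_pct == 0.0
        assert res.passed

    def test_hand_computed_cv(self):
        # analyte MFs 0.9/1.0/1.1 against IS MFs 0.95/1.0/1.05
        res = matrix_effect_cv(
            [0.9, 1.0, 1.1], [1.0, 1.0, 1.0], [0.95, 1.0, 1.05], [1.0, 1.0, 1.0]
        )
        assert np.allclose(res.normalized_mf, [0.9 / 0.95, 1.0, 1.1 / 1.05])
        norm = np.array([0.9 / 0.95, 1.0, 1.1 / 1.05])
        assert res.me_cv_pct == pytest.approx(
            100 * norm.std(ddof=1) / norm.mean(), rel=1e-12
        )
        assert res.me_cv_pct == pytest.approx(5.02, abs=0.01)

    def test_outlier_replicate_fails(self):
        res = matrix_effect_cv([0.9, 1.0, 2.2], [1, 1, 1], [1, 1, 1], [1, 1, 1])
        assert res.me_cv_pct > 15
        assert not res.passed

    def test_constant_matrix_factor_invariant_to_is(self):
        res = matrix_effect_cv([4, 8, 6], [2, 4, 3], [10, 14, 4], [5, 7, 2])
        assert res.me_cv_pct == pytest.approx(0.0, abs=1e-10)

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            matrix_effect_cv([1, 2], [1, 2, 3], [1, 2, 3], [1, 2, 3])


class TestRecoveryStability:
    def test_identical_groups_full_recovery(self):
        assert recovery_pct([3, 4, 5], [3, 4, 5]) == 100.0

    def test_partial_recovery(self):
        post = np.array([100.0, 101.0, 99.0])
        assert recovery_pct(0.685 * post, post) == pytest.approx(68.5)

    def test_scale_invariance(self):
        a, b = np.array([3.0, 4.0, 5.0]), np.array([4.0, 5.0, 6.0])
        assert recovery_pct(2 * a, 2 * b) == pytest.approx(recovery_pct(a, b))

    @pytest.mark.parametrize(
        "pct,expected_pass",
        [(100.0, True), (86.21, True), (84.9, False), (85.0, True), (115.0, True), (115.1, False)],
    )
    def test_stability_window(self, pct, expected_pass):
        res = stability_assess(pct / 100 * 2.0, 2.0, "bench_top", "6h", "HQC")
        assert res.pct_of_nominal == pytest.approx(pct)
        assert res.passed is expected_pass


class TestIonRatioSelectivity:
    def test_pse_within_window_passes(self, panel_map):
        res = ion_ratio_check(17.1, 100.0, panel_map["Pse"])
        assert res.observed_ratio_pct == pytest.approx(17.1)
        assert res.passed

    def test_boundary_is_closed(self, panel_map):
        spec = panel_map["Pse"]  # window 14.0 - 20.9
        assert ion_ratio_check(14.0, 100.0, spec).passed
        assert ion_ratio_check(20.9, 100.0, spec).passed

    def test_outside_window_fails(self, panel_map):
        assert not ion_ratio_check(25.0, 100.0, panel_map["Pse"]).passed

    def test_zero_quantifier_rejected(self, panel_map):
        with pytest.raises(DomainError):
            ion_ratio_check(10.0, 0.0, panel_map["Pse"])

    def test_selectivity_threshold(self):
        assert selectivity_check(blank_response=0.02, lloq_response=1.0)
        assert not selectivity_check(blank_response=0.5, lloq_response=1.0)


class TestIsr:
    def test_identical_pair_zero(self):
        assert isr_percent_difference(10, 10) == 0.0

    def test_mean_denominator(self):
        assert isr_percent_difference(100, 120) == pytest.approx(100 * 20 / 110)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 100.0), b=st.floats(0.1, 100.0))
    def test_signed_antisymmetry(self, a, b):
        assert isr_percent_difference(a, b, signed=True) == pytest.approx(
            -isr_percent_difference(b, a, signed=True), rel=1e-9, abs=1e-9
        )
        assert isr_percent_difference(a, b) == pytest.approx(
            isr_percent_difference(b, a), rel=1e-12
        )

    def test_all_zero_differences_pass(self):
        res = isr_evaluate(pairs=[(10, 10), (5, 5)])
        assert res.passed and res.max_difference_pct == 0.0

    def test_three_of_four_within_passes(self):
        res = isr_evaluate(differences=[5, 10, 15, 25])
        assert res.within_tol_fraction == 0.75
        assert res.passed

    def test_boundary_difference_counts_as_within(self):
        res = isr_evaluate(differences=[20.0, 20.0, 20.0])
        assert res.within_tol_fraction == 1.0 and res.n_exceeding == 0

    def test_monotone_in_differences(self):
        rng = np.random.default_rng(5)
        diffs = rng.uniform(0, 40, 30)
        before = isr_evaluate(differences=diffs)
        shrunk = isr_evaluate(differences=0.8 * diffs)
        assert shrunk.within_tol_fraction >= before.within_tol_fraction
        if before.passed:
            assert shrunk.passed

    def test_reference_matrix_summary(self, isr_ref):
        res = isr_evaluate(differences=isr_ref.to_numpy())
        assert res.max_difference_pct == pytest.approx(34.6)
        assert res.n_exceeding == 8
        assert res.passed


class TestSummarizeRanges:
    def test_half_up_rounding(self):
        assert summarize_ranges([92.45, 100.0, 108.41]) == (92.5, 108.4)

    def test_single_value(self):
        assert summarize_ranges([7.77]) == (7.8, 7.8)

    def test_exclusion_moves_the_extreme(self):
        vals = [60.0, 82.0, 90.0, 95.0, 99.0]
        assert summarize_ranges(vals)[0] == 60.0
        assert summarize_ranges(vals, exclude_mask=[True, False, False, False, False])[0] == 82.0

    def test_empty_after_exclusion(self):
        with pytest.raises(InsufficientDataError):
            summarize_ranges([1.0], exclude_mask=[True])

    def test_reference_report_ranges(self, qc_ref):
        """Summaries over the packaged QC table match the published ranges."""
        assert summarize_ranges(qc_ref["intra_accuracy_pct"]) == (92.5, 108.4)
        assert summarize_ranges(qc_ref["inter_accuracy_pct"]) == (93.1, 109.4)
        assert summarize_ranges(qc_ref["intra_cv_pct"]) == (0.6, 9.3)
        assert summarize_ranges(qc_ref["inter_cv_pct"]) == (2.5, 10.5)
        mask = (qc_ref["analyte_code"] == "8OH2dG").to_numpy()
        assert summarize_ranges(qc_ref["recovery_pct"], exclude_mask=mask) == (82.7, 97.3)
        assert summarize_ranges(qc_ref.loc[mask, "recovery_pct"]) == (68.5, 79.1)
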