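from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from noisefield.agreement import AgreementCategory
from noisefield.cohort import EyeRecord
from noisefield.errors import InputError
from noisefield.stats import (PreferenceCounts, binom_two_sided,
                              chi2_adjusted_residuals, clopper_pearson,
                              detection_table, mcnemar_exact,
                              preference_counts_from_records,
                              preference_table)


def exact_two_sided_p(k: int, n: int) -> Fraction:
    """Enumeration oracle: doubled smaller tail of Binomial(n, 1/2)."""
    tail = min(k, n - k)
    cum = sum(Fraction(comb(n, i)) for i in range(tail + 1))
    return min(Fraction(1), 2 * cum / Fraction(2) ** n)


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (7, 0, 0.015625),   # moderate-stage discordant pairs
        (5, 0, 0.0625),     # advanced stage
        (2, 0, 0.5),        # severe stage
        (0, 0, 1.0),
    ])
    def test_printed_exact_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_enumeration_oracle_up_to_n_25(self):
        for n in range(0, 26):
            for b in range(n + 1):
                assert mcnemar_exact(b, n - b) == pytest.approx(
                    float(exact_two_sided_p(b, n)), rel=1e-12)

    @given(b=st.integers(0, 40), c=st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_range(self, b, c):
        p = mcnemar_exact(b, c)
        assert p == mcnemar_exact(c, b)
        assert 0 < p <= 1

    def test_monotone_in_imbalance_at_fixed_total(self):
        # p shrinks (weakly) as |b - c| grows at fixed b + c
        ps = [mcnemar_exact(b, 12 - b) for b in range(6, 13)]
        assert all(later <= earlier for earlier, later in zip(ps, ps[1:]))

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            mcnemar_exact(-1, 0)


class TestBinomTwoSided:
    @pytest.mark.parametrize("k,n,expected", [
        (9, 10, 0.021484375),   # severe-stage preference split
        (5, 10, 1.0),
        (10, 10, 0.001953125),
    ])
    def test_examples(self, k, n, expected):
        assert binom_two_sided(k, n) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_binomtest_at_half(self):
        for n in range(1, 26):
            for k in range(n + 1):
                assert binom_two_sided(k, n) == pytest.approx(
                    sps.binomtest(k, n, 0.5).pvalue, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            binom_two_sided(5, 4)


class TestChi2AdjustedResiduals:
    # detection-by-stage tables for the two noise conditions
    CG = [[66, 51, 31, 17], [31, 4, 2, 3]]
    ANALOG = [[49, 44, 26, 15], [48, 11, 7, 5]]

    def test_cg_table_statistic_and_residuals(self):
        chi2, df, p, r = chi2_adjusted_residuals(self.CG)
        assert chi2 == pytest.approx(18.876, abs=5e-4)
        assert df == 3 and p < 0.001
        assert r[0].round(2).tolist() == [-4.26, 2.68, 2.13, 0.54]

    def test_analog_table_statistic_and_residuals(self):
        chi2, df, p, r = chi2_adjusted_residuals(self.ANALOG)
        assert chi2 == pytest.approx(18.098, abs=5e-4)
        assert r[0].round(2).tolist() == [-4.24, 2.67, 1.77, 0.95]

    def test_uniform_table_has_zero_statistic(self):
        chi2, df, p, r = chi2_adjusted_residuals([[10, 10], [10, 10]])
        assert chi2 == 0 and np.allclose(r, 0)

    def test_invariant_under_row_and_column_permutation(self):
        chi2a, _, _, ra = chi2_adjusted_residuals(self.CG)
        table = np.array(self.CG)[::-1, ::-1]
        chi2b, _, _, rb = chi2_adjusted_residuals(table)
        assert chi2b == pytest.approx(chi2a)
        assert np.allclose(rb, ra[::-1, ::-1])

    def test_two_row_residuals_are_antisymmetric(self):
        _, _, _, r = chi2_adjusted_residuals(self.CG)
        assert np.allclose(r[0], -r[1])

    def test_residuals_match_statsmodels(self):
        from statsmodels.stats.contingency_tables import Table
        _, _, _, r = chi2_adjusted_residuals(self.CG)
        sm = Table(np.array(self.CG)).standardized_resids
        assert np.allclose(r, sm)

    def test_zero_margin_rejected(self):
        with pytest.raises(InputError):
            chi2_adjusted_residuals([[0, 0], [1, 2]])


class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lo,hi", [
        (31, 33, 0.798, 0.993),
        (165, 205, 0.744, 0.857),
        (17, 20, 0.621, 0.968),
    ])
    def test_printed_intervals(self, x, n, lo, hi):
        low, high = clopper_pearson(x, n)
        assert low == pytest.approx(lo, abs=5e-4)
        assert high == pytest.approx(hi, abs=5e-4)

    def test_boundary_cases(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    def test_matches_statsmodels_beta_method(self):
        for x, n in [(0, 7), (3, 7), (7, 7), (41, 53), (134, 205)]:
            lo, hi = clopper_pearson(x, n)
            sm_lo, sm_hi = proportion_confint(x, n, method="beta")
            assert (lo, hi) == pytest.approx((sm_lo, sm_hi), abs=1e-10)

    def test_exact_coverage_at_n_20(self):
        # coverage >= 95% for every p, by exhaustive enumeration
        n = 20
        intervals = [clopper_pearson(x, n) for x in range(n + 1)]
        for p in np.arange(0.05, 0.951, 0.05):
            cover = sum(sps.binom.pmf(x, n, p)
                        for x, (lo, hi) in enumerate(intervals)
                        if lo <= p <= hi)
            assert cover >= 0.95 - 1e-12

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            clopper_pearson(5, 0)


def _record(i, stage, cg, analog, pref=None):
    return EyeRecord(eye_id=f"e{i}", group="glaucoma", stage=stage,
                     cg_outcome=cg, analog_outcome=analog, preference=pref)


class TestReportBuilders:
    def test_detection_table_on_a_small_handmade_cohort(self):
        a, p_, n_ = "agreement", "partial_agreement", "no_response"
        records = (
            [_record(i, "M1", a, a, "cg") for i in range(3)]
            + [_record(10 + i, "M1", p_, n_) for i in range(2)]
            + [_record(20 + i, "M2", a, n_) for i in range(4)]
            + [_record(30 + i, "M2", n_, n_) for i in range(1)]
            + [_record(40 + i, "M3", a, a, "same") for i in range(2)]
            + [_record(50 + i, "M4", n_, n_) for i in range(2)]
            + [EyeRecord(f"n{i}", "normal", None, n_, n_) for i in range(3)]
            + [EyeRecord("n9", "normal", None, "no_agreement", n_)]
            + [EyeRecord(f"p{i}", "ppg", None, n_, n_) for i in range(2)]
        )
        report = detection_table(records)
        m1 = report.cg.row("M1")
        assert (m1.n_eyes, m1.detected) == (5, 5)
        m2 = report.cg.row("M2")
        assert (m2.detected, m2.mcnemar_b, m2.mcnemar_c) == (4, 4, 0)
        assert m2.mcnemar_p == pytest.approx(0.125)
        total = report.cg.row("Total")
        assert (total.n_eyes, total.detected) == (14, 11)
        assert report.cg.specificity == pytest.approx(3 / 4)
        assert report.analog.specificity == pytest.approx(1.0)
        assert report.n_ppg == 2 and report.ppg_detected_cg == 0
        pooled = report.cg.row("M3+M4")
        assert (pooled.n_eyes, pooled.detected) == (4, 2)

    def test_empty_cohort_rejected(self):
        with pytest.raises(InputError):
            detection_table([])

    def test_preference_table_totals_and_p(self):
        per_stage = {"M4": PreferenceCounts(9, 5, 1),
                     "M1": PreferenceCounts(1, 0, 1)}
        rows = preference_table(per_stage)
        assert [r.stage for r in rows] == ["M1", "M4", "Total"]
        m4 = rows[1]
        assert m4.binom_p == pytest.approx(0.021484375)
        assert m4.cg_rate == pytest.approx(0.6)
        total = rows[2]
        assert total.counts == PreferenceCounts(10, 5, 2)

    def test_preference_counts_from_records(self):
        records = [_record(1, "M1", "agreement", "agreement", "cg"),
                   _record(2, "M1", "agreement", "partial_agreement", "analog"),
                   _record(3, "M2", "agreement", "no_response")]
        counts = preference_counts_from_records(records)
        assert counts == {"M1": PreferenceCounts(1, 0, 1)}
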