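"""Agreement battery: differences, limits, correlation, ICC, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from swlslink.agreement import (
    PairedScores,
    agreement_report,
    anova_two_way,
    category_concordance,
    difference_stats,
    icc,
    icc_both,
    interpret_icc,
    limits_of_agreement,
    pearson_r,
    threshold_proportions,
)

WORKED_MATRIX = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)


def paired(direct, prorated):
    return PairedScores(np.asarray(direct, float), np.asarray(prorated, float))


class TestPairedScores:
    def test_rejects_mismatched_or_short(self):
        with pytest.raises(ValueError):
            paired([5, 6], [5, 6, 7])
        with pytest.raises(ValueError, match="at least 2"):
            paired([5], [6])

    def test_rejects_out_of_scale_or_missing(self):
        with pytest.raises(ValueError, match="within"):
            paired([4, 6], [5, 6])
        with pytest.raises(ValueError, match="non-finite"):
            paired([5, np.nan], [5, 6])


class TestDifferenceStats:
    def test_identical_vectors(self):
        d = difference_stats(paired([5, 10, 20], [5, 10, 20]))
        assert (d.mean_diff, d.sd_diff, d.mean_abs_diff) == (0, 0, 0)

    def test_plus_minus_one(self):
        d = difference_stats(paired([11, 9], [10, 10]))
        assert d.mean_diff == 0
        assert d.sd_diff == pytest.approx(1.4142135623730951)
        assert d.mean_abs_diff == 1 and d.sd_abs_diff == 0

    def test_sign_convention_direct_minus_prorated(self):
        d = difference_stats(paired([5, 5], [6, 6]))
        assert d.mean_diff == -1

    def test_abs_mean_bounds_mean(self, scored):
        d = difference_stats(paired(scored["direct"], scored["prorated"]))
        assert d.mean_abs_diff >= abs(d.mean_diff)
        assert d.sd_diff >= 0


class TestLimitsOfAgreement:
    def test_unit_case(self):
        d = difference_stats(paired([11, 9], [10, 10]))
        # rescale by hand: mean 0, SD sqrt(2); check the ±1.96×SD construction
        loa = limits_of_agreement(d)
        assert loa.lower == pytest.approx(-1.96 * d.sd_diff)
        assert loa.upper == pytest.approx(+1.96 * d.sd_diff)
        assert loa.upper - loa.lower == pytest.approx(2 * 1.96 * d.sd_diff)

    def test_published_scale_arithmetic(self):
        from swlslink.agreement import DifferenceStats

        d = DifferenceStats(mean_diff=-0.39, sd_diff=1.95,
                            mean_abs_diff=1.46, sd_abs_diff=1.35, n=17897)
        loa = limits_of_agreement(d)
        assert loa.lower == pytest.approx(-4.212)
        assert loa.upper == pytest.approx(3.432)

    def test_degenerate_zero_sd(self):
        d = difference_stats(paired([10, 12], [10, 12]))
        loa = limits_of_agreement(d)
        assert loa.lower == loa.upper == 0

    def test_coverage_of_simulated_normal_differences(self):
        """~95% of iid normal differences fall inside the estimated limits."""
        rng = np.random.default_rng(101)
        diffs = rng.normal(-0.4, 2.0, size=10_000)
        m, s = diffs.mean(), diffs.std(ddof=1)
        lo, hi = m - 1.96 * s, m + 1.96 * s
        coverage = np.mean((diffs > lo) & (diffs < hi))
        assert abs(coverage - 0.95) <= 0.01


class TestPearson:
    def test_perfect_and_inverse(self):
        assert pearson_r(paired([5, 10, 15], [5, 10, 15])).r == pytest.approx(1.0)
        d = np.array([5.0, 10, 15])
        assert pearson_r(paired(d, 40 - d)).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson_r(paired([5, 10, 15], [6, 9, 16]))
        assert res.r == pytest.approx(0.9743547036924461)
        assert res.very_high  # r > 0.9

    def test_constant_vector_is_undefined_not_zero(self):
        res = pearson_r(paired([5, 10, 15], [7, 7, 7]))
        assert not res.defined and np.isnan(res.r)

    @given(
        st.floats(min_value=0.1, max_value=0.8),
        st.floats(min_value=-2.0, max_value=2.0),
    )
    def test_invariance_under_positive_affine_maps(self, a, b):
        direct = np.array([6.0, 11, 17, 23, 30])
        prorated = np.array([7.0, 10, 18, 21, 32])
        base = pearson_r(paired(direct, prorated)).r
        transformed = a * (prorated - 5) + 10 + b  # stays within [5, 35]
        assert pearson_r(paired(direct, transformed)).r == pytest.approx(base, abs=1e-9)


class TestAnova:
    def test_worked_four_by_two(self):
        ms = anova_two_way(WORKED_MATRIX)
        assert ms.msr == pytest.approx(13.333333333333334)
        assert ms.msc == pytest.approx(2.0)
        assert ms.mse == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns(self):
        ms = anova_two_way(np.array([[5, 5], [9, 9], [20, 20.0]]))
        assert ms.msc == pytest.approx(0) and ms.mse == pytest.approx(0, abs=1e-12)
        assert ms.msr > 0

    def test_all_equal(self):
        ms = anova_two_way(np.full((4, 2), 7.0))
        assert ms.msr == ms.msc == ms.mse == 0

    def test_sum_of_squares_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            x = rng.normal(0, 3, size=(n, 2))
            ms = anova_two_way(x)
            ss = ms.msr * (n - 1) + ms.msc + ms.mse * (n - 1)
            assert ss == pytest.approx(np.sum((x - x.mean()) ** 2), rel=1e-9)


def icc_oracle(x):
    """Variance-components oracle: long-format two-way OLS ANOVA (statsmodels)."""
    import statsmodels.api as smapi
    from statsmodels.formula.api import ols

    n, k = x.shape
    long = pd.DataFrame(
        {
            "y": x.ravel(),
            "subj": np.repeat(np.arange(n), k).astype(str),
            "meas": np.tile(np.arange(k), n).astype(str),
        }
    )
    tab = smapi.stats.anova_lm(ols("y ~ C(subj) + C(meas)", data=long).fit(), typ=2)
    msr = tab.loc["C(subj)", "sum_sq"] / tab.loc["C(subj)", "df"]
    msc = tab.loc["C(meas)", "sum_sq"] / tab.loc["C(meas)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    var_r = (msr - mse) / k
    var_c = (msc - mse) / n
    consistency = var_r / (var_r + mse)
    agreement = var_r / (var_r + var_c + mse)
    return consistency, agreement


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.array([[5, 5], [9, 9], [20, 20.0]])
        assert icc(x, "consistency").estimate == pytest.approx(1.0)
        assert icc(x, "agreement").estimate == pytest.approx(1.0)

    def test_systematic_offset_penalized_only_under_agreement(self):
        col1 = np.array([5.0, 10, 15, 20])
        x = np.column_stack([col1, col1 + 5])
        assert icc(x, "consistency").estimate == pytest.approx(1.0)
        assert icc(x, "agreement").estimate < 1.0

    def test_worked_matrix_agreement_value(self):
        res = icc(WORKED_MATRIX, "agreement")
        assert res.estimate == pytest.approx(13.333333333333334 / 14.333333333333334)
        assert res.estimate == pytest.approx(0.9302, abs=5e-5)
        assert res.variant == "ICC(A,1)"

    def test_all_equal_is_undefined(self):
        res = icc(np.full((4, 2), 7.0), "agreement")
        assert np.isnan(res.estimate) and res.interpretation is None

    def test_interpretation_bands(self):
        assert interpret_icc(0.2) == "poor"
        assert interpret_icc(0.5) == "moderate"
        assert interpret_icc(0.75) == "moderate"
        assert interpret_icc(0.9) == "good"
        assert interpret_icc(0.95) == "excellent"

    def test_matches_variance_component_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 20))
            x = rng.normal(20, 4, size=(n, 2)) + rng.normal(0, 2, size=(n, 1))
            oc, oa = icc_oracle(x)
            assert icc(x, "consistency").estimate == pytest.approx(oc, abs=1e-9)
            assert icc(x, "agreement").estimate == pytest.approx(oa, abs=1e-9)

    def test_matches_pingouin_estimates_and_cis(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(3):
            n = int(rng.integers(6, 20))
            x = rng.normal(20, 4, size=(n, 2)) + rng.normal(0, 2, size=(n, 1))
            long = pd.DataFrame(
                {
                    "y": x.ravel(),
                    "subj": np.repeat(np.arange(n), 2),
                    "meas": np.tile([0, 1], n),
                }
            )
            res = pg.intraclass_corr(long, "subj", "meas", "y").set_index("Type")
            both = {"consistency": "ICC(C,1)", "agreement": "ICC(A,1)"}
            for variant, key in both.items():
                mine = icc(x, variant)
                assert mine.estimate == pytest.approx(res.loc[key, "ICC"], abs=1e-9)
                # pingouin prints CIs rounded to 2 decimals
                assert np.allclose(mine.ci95, res.loc[key, "CI95"], atol=0.006)


class TestThresholds:
    def test_examples(self):
        assert threshold_proportions([0, 0, 0]) == {2.0: 1.0, 3.0: 1.0, 4.0: 1.0}
        got = threshold_proportions([0, 1, 2, 3, 4])
        assert got == {2.0: 0.4, 3.0: 0.6, 4.0: 0.8}
        assert threshold_proportions([4, -5, 6]) == {2.0: 0.0, 3.0: 0.0, 4.0: 0.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            threshold_proportions([])

    @given(st.lists(st.floats(-6, 6, allow_nan=False), min_size=1, max_size=40))
    def test_monotone_in_threshold_and_sign_invariant(self, diffs):
        props = threshold_proportions(diffs)
        vals = [props[t] for t in (2.0, 3.0, 4.0)]
        assert vals == sorted(vals)
        flipped = threshold_proportions([-d for d in diffs])
        assert flipped == props


class TestConcordance:
    def test_identical(self):
        res = category_concordance([1, 3, 6], [1, 3, 6])
        assert res.prop_same == 1.0 and res.max_abs_shift == 0
        assert res.crosstab.values.sum() == 3

    def test_counting_example(self):
        direct = [3] * 10
        prorated = [3] * 7 + [2] + [4, 4]
        res = category_concordance(direct, prorated)
        assert (res.prop_same, res.prop_lower, res.prop_higher) == (0.7, 0.1, 0.2)
        assert res.max_abs_shift == 1
        assert res.prop_same + res.prop_lower + res.prop_higher == pytest.approx(1)

    def test_systematic_upshift(self):
        res = category_concordance([1, 2, 3], [2, 3, 4])
        assert res.prop_higher == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            category_concordance([1, 2], [1])


class TestReport:
    def test_full_report_fields_consistent(self, scored):
        rep = agreement_report(scored["direct"], scored["prorated"], label="overall")
        assert rep.n == len(scored)
        assert rep.loa.lower <= rep.diff.mean_diff <= rep.loa.upper
        assert rep.icc_headline is rep.icc_agreement
        c = rep.concordance
        assert c.prop_same + c.prop_lower + c.prop_higher == pytest.approx(1)
        assert c.crosstab.values.sum() == rep.n
        d = rep.to_dict()
        assert d["n"] == rep.n and d["icc"]["headline_variant"] == "ICC(A,1)"
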