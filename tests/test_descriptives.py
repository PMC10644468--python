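"""Descriptive statistics: severity bands, intervals, group tests, model fits.

The published caregiver summary counts serve as worked-example inputs whose
printed statistics the routines must reproduce.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet import (
    ancova_group_effect,
    isi_category,
    logistic_insomnia,
    mann_whitney_u,
    pearson_chi2,
    pooled_t,
    prevalence_with_ci,
    welch_t,
)
from symptomnet.examples import CAREGIVER_MOMENTS, CAREGIVER_TABLES


class TestIsiCategory:
    @pytest.mark.parametrize(
        "total,expected",
        [(0, "none"), (7, "none"), (8, "subthreshold"), (14, "subthreshold"),
         (15, "moderate"), (21, "moderate"), (22, "severe"), (28, "severe")],
    )
    def test_band_edges(self, total, expected):
        assert isi_category(total) == expected

    @pytest.mark.parametrize("bad", [-1, 29, 7.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            isi_category(bad)


class TestPrevalence:
    def test_caregiver_interval(self):
        r = prevalence_with_ci(208, 1101)
        assert r.as_percent() == (18.9, 16.7, 21.3)

    def test_zero_count_boundary(self):
        r = prevalence_with_ci(0, 100)
        assert r.proportion == 0.0
        assert r.ci_low == 0.0
        assert r.ci_high > 0

    def test_rare_event_interval(self):
        r = prevalence_with_ci(7, 1101)
        assert round(r.ci_low, 3) == 0.003
        assert round(r.ci_high, 3) == 0.013

    def test_ordering_invariant(self):
        for k, n in [(1, 10), (5, 10), (9, 10), (50, 200)]:
            r = prevalence_with_ci(k, n)
            assert 0 <= r.ci_low <= r.proportion <= r.ci_high <= 1

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            prevalence_with_ci(0, 0)


class TestChi2:
    def test_gender_table(self):
        r = pearson_chi2(CAREGIVER_TABLES["gender_male"])
        assert round(r.statistic, 3) == 4.494
        assert r.df == 1

    def test_financial_status_table(self):
        r = pearson_chi2(CAREGIVER_TABLES["financial_status"])
        assert round(r.statistic, 3) == 16.872
        assert r.df == 2

    def test_identical_row_proportions_give_zero(self):
        r = pearson_chi2([[10, 20, 30], [20, 40, 60]])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2([[0, 0], [5, 3]])


class TestTTests:
    def test_age_welch_statistic(self):
        a = CAREGIVER_MOMENTS["age"]
        r = welch_t(*a["without"], *a["with"])
        assert round(r.statistic, 3) == -0.360
        assert r.df == pytest.approx(286.1, abs=0.5)

    def test_equal_means_give_zero(self):
        r = welch_t(5.0, 1.0, 50, 5.0, 2.0, 60)
        assert r.statistic == 0.0

    def test_qol_pooled_df(self):
        q = CAREGIVER_MOMENTS["qol"]
        r = pooled_t(*q["without"], *q["with"])
        assert r.df == 1099
        assert r.statistic == pytest.approx(15.3, abs=0.1)

    def test_near_degenerate_second_sample_approaches_one_sample_t(self):
        """sd2 -> 0 with n2 large: Welch t tends to the one-sample t against mean2."""
        mean1, sd1, n1 = 5.3, 1.1, 40
        r = welch_t(mean1, sd1, n1, 5.0, 1e-6, 10_000)
        one_sample = (mean1 - 5.0) / (sd1 / np.sqrt(n1))
        assert r.statistic == pytest.approx(one_sample, rel=1e-6)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            welch_t(1, 0.0, 10, 2, 1.0, 10)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert r.statistic == 0.0

    def test_identical_samples_give_zero_z(self):
        r = mann_whitney_u([1, 1, 1], [1, 1, 1])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_exact_p_matches_enumeration_with_ties(self):
        # frozen oracle: enumerating all C(7,4)=35 group assignments of the
        # pooled ranks of {1,2,2,5} vs {2,3,4} gives U=4 and two-sided p=21/35
        r = mann_whitney_u([1, 2, 2, 5], [2, 3, 4], method="exact")
        assert r.statistic == 4.0
        assert r.p_value == pytest.approx(21 / 35)

    def test_u_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.integers(0, 5, 30), rng.integers(0, 6, 25)
        r = mann_whitney_u(x, y)
        u_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        # recover U from our signed Z: recompute directly
        ranks = stats.rankdata(np.concatenate([x, y]))
        u = ranks[:30].sum() - 30 * 31 / 2
        assert u == u_scipy
        # our normal-approximation p close to scipy's asymptotic p
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                     use_continuity=False).pvalue
        assert r.p_value == pytest.approx(p_scipy, abs=1e-10)


class TestAncova:
    def test_no_covariates_equals_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        g = rng.integers(0, 2, 200)
        r = ancova_group_effect(y, g)
        t = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert r.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert r.p_value == pytest.approx(t.pvalue, rel=1e-10)

    def test_outcome_equal_to_covariate_gives_zero_f(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(size=100)
        g = rng.integers(0, 2, 100)
        r = ancova_group_effect(cov, g, cov)
        assert r.statistic == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 2, 50)
        with pytest.raises(ValueError, match="rank deficient"):
            ancova_group_effect(rng.normal(size=50), g, np.column_stack([g, g]))


class TestLogistic:
    def test_saturated_2x2_recovers_cross_product_ratio(self):
        a, b, c, d = 30, 70, 20, 80  # exposed-case, exposed-noncase, ...
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        fit = logistic_insomnia(y, pd.DataFrame({"x": x}))
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_all_zero_predictor_rejected(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 100)
        with pytest.raises(ValueError, match="rank deficient"):
            logistic_insomnia(y, pd.DataFrame({"z": np.zeros(100)}))

    def test_parameter_recovery_with_site_adjustment(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.standard_normal(n)
        site = rng.integers(0, 3, n)
        eta = -1.0 + 0.17 * x + 0.2 * (site == 1)
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_insomnia(y, pd.DataFrame({"x": x}), site=site)
        coef = fit.table.loc["x", "coef"]
        se = (np.log(fit.table.loc["x", "ci_high"]) - np.log(fit.table.loc["x", "ci_low"])) / (2 * 1.96)
        assert abs(coef - 0.17) < 3 * se

    def test_separation_detected(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), np.zeros(20)] * 5.0
        with pytest.raises(RuntimeError, match="separation|failed"):
            logistic_insomnia(y, pd.DataFrame({"x": x}))

    def test_or_equals_exp_coef_invariant(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 300).astype(float)
        X = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        fit = logistic_insomnia(y, X)
        np.testing.assert_allclose(fit.table["odds_ratio"], np.exp(fit.table["coef"]))
        assert (fit.table["ci_low"] <= fit.table["odds_ratio"]).all()
        assert (fit.table["odds_ratio"] <= fit.table["ci_high"]).all()
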