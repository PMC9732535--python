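"""Drive inference: goodness of fit, proportion tests, cohort comparison."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from rbdrive.drive import (
    compare_transmission,
    dispersion_test,
    estimate_transmission,
    gof_test,
    proportion_test,
)
from rbdrive.io import fmt
from rbdrive.segregation import CountDistribution, SegregationModel, transmission_pmf


def chi2_oracle(observed, n_total):
    """Direct rational-arithmetic chi-square against Binomial(8, 1/2)."""
    stat = Fraction(0)
    for k, o in enumerate(observed):
        e = Fraction(n_total * comb(8, k), 256)
        stat += (o - e) ** 2 / e
    return float(stat)


class TestGofAsymptotic:
    def test_maternal_statistic_matches_rational_oracle(self, female_dist, mendelian_model):
        res = gof_test(female_dist, mendelian_model)
        oracle = chi2_oracle(female_dist.counts, 83)
        assert res.statistic == pytest.approx(oracle, abs=1e-9)
        assert res.statistic == pytest.approx(139.3, abs=0.1)
        assert res.df == 8

    @pytest.mark.parametrize("dist_name", ["female_dist", "male_dist"])
    def test_both_cohorts_reject_the_mendelian_null(self, dist_name, mendelian_model, request):
        dist = request.getfixturevalue(dist_name)
        res = gof_test(dist, mendelian_model)
        assert fmt(res.p_value, 4) == "0.0000"

    def test_perfect_fit_gives_zero_statistic(self, mendelian_model):
        # 256 * Binomial(8, 1/2) pmf is integer-valued by construction
        counts = (256 * transmission_pmf(mendelian_model)).round().astype(int)
        dist = CountDistribution(8, counts)
        res = gof_test(dist, mendelian_model)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_tail_pooling_reduces_df_and_keeps_statistic_finite(self, male_dist, mendelian_model):
        pooled = gof_test(male_dist, mendelian_model, pool_below=5.0)
        unpooled = gof_test(male_dist, mendelian_model)
        assert pooled.df < unpooled.df
        assert np.isfinite(pooled.statistic)
        assert pooled.pooled_bins != "none"
        assert abs(pooled.expected.sum() - male_dist.n) < 1e-9

    def test_zero_expected_with_observed_mass_is_an_error(self):
        dist = CountDistribution(3, [1, 0, 0, 9])
        model = SegregationModel.homogeneous(3, 1.0)
        with pytest.raises(ValueError, match="infinite"):
            gof_test(dist, model)


class TestGofMonteCarlo:
    def test_fixed_seed_is_bit_reproducible(self, male_dist, mendelian_model):
        a = gof_test(male_dist, mendelian_model, method="monte_carlo",
                     n_resamples=5000, seed=42)
        b = gof_test(male_dist, mendelian_model, method="monte_carlo",
                     n_resamples=5000, seed=42)
        assert a.p_value == b.p_value
        assert a.statistic == b.statistic

    def test_add_one_estimator_never_returns_zero(self, male_dist, mendelian_model):
        res = gof_test(male_dist, mendelian_model, method="monte_carlo",
                       n_resamples=2000, seed=0)
        assert res.p_value >= 1 / 2001

    def test_matches_exact_multinomial_enumeration_on_reduced_case(self):
        # 3 trivalents, 10 offspring: all C(13, 3) = 286 outcome tables can
        # be enumerated, giving the exact tail probability of the statistic.
        n_triv, n_tot = 3, 10
        model = SegregationModel.mendelian(n_triv)
        pmf = transmission_pmf(model)
        observed = CountDistribution(n_triv, [4, 1, 2, 3])
        obs_stat = gof_test(observed, model).statistic

        from itertools import product
        exact_tail = 0.0
        for c0 in range(n_tot + 1):
            for c1 in range(n_tot + 1 - c0):
                for c2 in range(n_tot + 1 - c0 - c1):
                    c3 = n_tot - c0 - c1 - c2
                    counts = np.array([c0, c1, c2, c3])
                    stat = ((counts - n_tot * pmf) ** 2 / (n_tot * pmf)).sum()
                    if stat >= obs_stat - 1e-9:
                        exact_tail += stats.multinomial.pmf(counts, n_tot, pmf)

        res = gof_test(observed, model, method="monte_carlo",
                       n_resamples=100_000, seed=7)
        mc_se = np.sqrt(exact_tail * (1 - exact_tail) / res.n_resamples)
        assert abs(res.p_value - exact_tail) <= 3 * mc_se

    def test_requires_minimum_resamples(self, male_dist, mendelian_model):
        with pytest.raises(ValueError):
            gof_test(male_dist, mendelian_model, method="monte_carlo", n_resamples=10)

    def test_agrees_with_asymptotic_when_expected_counts_large(self):
        # N = 500 under a mild shift: all expected counts >= 5 except tails,
        # so the chi-square approximation should match resampling closely.
        rng = np.random.default_rng(11)
        model = SegregationModel.mendelian(8)
        counts = np.bincount(rng.binomial(8, 0.55, size=500), minlength=9)
        dist = CountDistribution(8, counts)
        asym = gof_test(dist, model, pool_below=5.0)
        mc = gof_test(dist, model, method="monte_carlo", pool_below=5.0,
                      n_resamples=50_000, seed=3)
        se = np.sqrt(max(mc.p_value * (1 - mc.p_value), 1e-12) / mc.n_resamples)
        assert abs(asym.p_value - mc.p_value) <= max(3 * se, 0.01)


class TestProportionTest:
    def test_five_of_six_normal_approximation(self):
        res = proportion_test(5, 6, 0.5, "greater", "normal_approx")
        assert res.z == pytest.approx(1.633, abs=0.001)
        assert fmt(res.p_value, 4) == "0.0512"

    def test_five_of_six_exact_binomial(self):
        res = proportion_test(5, 6, 0.5, "greater", "exact_binomial")
        assert res.p_value == pytest.approx(7 / 64, abs=1e-12)

    def test_estimate_at_null_gives_half_p(self):
        res = proportion_test(3, 6, 0.5, "greater", "normal_approx")
        assert res.z == 0.0
        assert res.p_value == pytest.approx(0.5)

    def test_exact_one_sided_tails_match_rational_sums(self):
        # arbitrary-precision oracle: Fraction tail sums at p0 = 1/2
        for trials in range(1, 31):
            for successes in range(trials + 1):
                upper = sum(Fraction(comb(trials, j), 2**trials)
                            for j in range(successes, trials + 1))
                lower = sum(Fraction(comb(trials, j), 2**trials)
                            for j in range(0, successes + 1))
                g = proportion_test(successes, trials, 0.5, "greater", "exact_binomial")
                l = proportion_test(successes, trials, 0.5, "less", "exact_binomial")
                assert g.p_value == pytest.approx(float(upper), abs=1e-12)
                assert l.p_value == pytest.approx(float(lower), abs=1e-12)

    @pytest.mark.parametrize("successes,trials,p0", [(5, 6, 0.5), (40, 100, 0.3), (7, 20, 0.6)])
    def test_two_sided_normal_is_twice_smaller_one_sided(self, successes, trials, p0):
        two = proportion_test(successes, trials, p0, "two_sided", "normal_approx")
        g = proportion_test(successes, trials, p0, "greater", "normal_approx")
        l = proportion_test(successes, trials, p0, "less", "normal_approx")
        assert two.p_value == pytest.approx(2 * min(g.p_value, l.p_value))

    def test_wilson_interval_is_ordered_and_bounded(self):
        res = proportion_test(5, 6, 0.5)
        lo, hi = res.conf_int
        assert 0.0 <= lo <= res.estimate <= hi <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(7, 6)
        with pytest.raises(ValueError):
            proportion_test(1, 6, p0=1.0)


class TestEstimateTransmission:
    def test_maternal_cohort(self, female_dist):
        res = estimate_transmission(female_dist)
        assert res.estimate == pytest.approx(256 / 664)
        assert fmt(100 * res.estimate, 1) == "38.6"
        assert "independen" in res.note

    def test_paternal_cohort(self, male_dist):
        res = estimate_transmission(male_dist)
        assert res.estimate == pytest.approx(228 / 448)
        assert res.estimate == pytest.approx(0.509, abs=0.001)

    def test_complete_transmission(self):
        dist = CountDistribution(8, [0, 0, 0, 0, 0, 0, 0, 0, 7])
        assert estimate_transmission(dist).estimate == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            estimate_transmission(CountDistribution(8, np.zeros(9, dtype=int)))


class TestCompareTransmission:
    def test_maternal_vs_paternal_z_matches_pooled_arithmetic(self, female_dist, male_dist):
        res = compare_transmission(female_dist, male_dist)
        # pooled p-hat = 484/1112; direct arithmetic gives |z| ~ 4.07
        assert abs(res.z) == pytest.approx(4.07, abs=0.01)
        assert res.p_value < 0.01
        assert res.estimate == pytest.approx(484 / 1112)

    def test_identical_cohorts_give_null_result(self, female_dist):
        res = compare_transmission(female_dist, female_dist)
        assert res.z == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_empty_cohort_rejected(self, female_dist):
        empty = CountDistribution(8, np.zeros(9, dtype=int))
        with pytest.raises(ValueError):
            compare_transmission(female_dist, empty)


class TestDispersionTest:
    def test_maternal_cohort_is_overdispersed(self, female_dist, mendelian_model):
        res = dispersion_test(female_dist, mendelian_model, n_resamples=5000, seed=1)
        assert res.statistic > 1.0
        assert res.p_value < 0.05

    def test_binomial_data_give_ratio_near_one(self):
        rng = np.random.default_rng(5)
        counts = np.bincount(rng.binomial(8, 0.5, size=5000), minlength=9)
        dist = CountDistribution(8, counts)
        res = dispersion_test(dist, n_resamples=3000, seed=2)
        assert res.statistic == pytest.approx(1.0, abs=0.07)
        assert res.p_value > 0.05

    def test_degenerate_distribution_rejected(self):
        dist = CountDistribution(8, [0, 0, 0, 12, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="degenerate|variance"):
            dispersion_test(dist)
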