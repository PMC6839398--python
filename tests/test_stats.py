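"""Statistical procedures against exact oracles and calibrations."""

import numpy as np
import pytest
from scipy import stats as sps

from spermshape import (SwimUpModelSpec, betareg_fit,
                        binomial_test_two_tailed, generate_swimup_counts,
                        holm_bonferroni, ks_two_sample,
                        likelihood_ratio_test, one_sample_ztest,
                        se_proportion, two_proportion_ztest,
                        wilcoxon_ranksum)


class TestSeProportion:
    @pytest.mark.parametrize("k,n,expected", [
        (50, 100, 0.0500),
        (0, 20, 0.0),
        (20, 254, 0.01690),
    ])
    def test_examples(self, k, n, expected):
        assert abs(se_proportion(k, n) - expected) < 5e-5

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            se_proportion(0, 0)


class TestTwoProportionZ:
    def test_resorption_counts_male_line(self):
        """Yates-corrected test on the embryo-resorption counts by paternal
        genotype (20/254 vs 17/302) reproduces the published p = 0.38
        (printed half-up from p = 0.375)."""
        _, p = two_proportion_ztest(20, 254, 17, 302, continuity=True)
        assert abs(p - 0.375) < 5e-4

    def test_resorption_counts_maternal_line(self):
        _, p = two_proportion_ztest(12, 254, 25, 302, continuity=True)
        assert round(p, 2) == 0.13

    def test_identical_proportions(self):
        z, p = two_proportion_ztest(10, 100, 10, 100)
        assert z == 0.0 and p == 1.0

    def test_degenerate_pooled_variance(self):
        with pytest.warns(UserWarning):
            z, p = two_proportion_ztest(0, 10, 0, 10)
        assert p == 1.0

    def test_group_swap_flips_sign(self):
        z1, p1 = two_proportion_ztest(30, 100, 10, 100)
        z2, p2 = two_proportion_ztest(10, 100, 30, 100)
        assert z1 == -z2 and p1 == p2

    def test_uncorrected_matches_chisquare(self):
        """Without continuity correction, z^2 equals the 2x2 Pearson
        chi-square statistic (algebraic identity)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(20, 200, 2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            z, _ = two_proportion_ztest(int(k1), int(n1), int(k2), int(n2),
                                        continuity=False)
            table = [[k1, n1 - k1], [k2, n2 - k2]]
            chi2 = sps.chi2_contingency(table, correction=False).statistic
            assert abs(z ** 2 - chi2) < 1e-8


class TestOneSampleZ:
    def test_null_value(self):
        z, p = one_sample_ztest(50, 100, 0.5)
        assert z == 0.0 and p == 1.0

    def test_moderate_excess(self):
        z, p = one_sample_ztest(60, 100, 0.5)
        assert abs(z - 2.0) < 1e-12
        assert abs(p - 0.0455) < 5e-4

    def test_extreme_boundary(self):
        z, p = one_sample_ztest(400, 400, 0.5)
        assert z == 20.0 and p < 1e-80

    def test_type_one_error_calibrated(self):
        """At n=400 counts, the alpha=0.05 rejection rate under the null
        stays in [0.03, 0.07]."""
        rng = np.random.default_rng(1)
        ks = rng.binomial(400, 0.5, size=20000)
        rejects = np.mean([one_sample_ztest(int(k), 400, 0.5)[1] < 0.05
                           for k in ks])
        assert 0.03 <= rejects <= 0.07


def _binom_two_tailed_enumeration(k, n, p0):
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-10)].sum())


class TestBinomialTest:
    def test_observed_equals_expected(self):
        assert binomial_test_two_tailed(5, 10, 0.5) == 1.0

    def test_extreme_tail(self):
        assert abs(binomial_test_two_tailed(0, 10, 0.5) - 2 / 1024) < 1e-12

    @pytest.mark.parametrize("p0", [0.5, 0.3])
    def test_matches_exhaustive_enumeration(self, p0):
        for n in range(1, 13):
            for k in range(n + 1):
                expected = _binom_two_tailed_enumeration(k, n, p0)
                assert abs(binomial_test_two_tailed(k, n, p0) - expected) \
                    < 1e-10, (k, n, p0)

    def test_doubled_tail_variant(self):
        p = binomial_test_two_tailed(3, 10, 0.5, method="doubled")
        expected = 2 * sps.binom.cdf(3, 10, 0.5)
        assert abs(p - expected) < 1e-12


class TestHolm:
    def test_worked_example(self):
        adjusted, reject = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        np.testing.assert_allclose(adjusted, [0.03, 0.06, 0.06])
        assert list(reject) == [True, False, False]

    def test_single_p_unchanged(self):
        adjusted, _ = holm_bonferroni([0.2])
        assert adjusted[0] == 0.2

    def test_all_zero_all_rejected(self):
        _, reject = holm_bonferroni([0.0, 0.0, 0.0])
        assert reject.all()

    def test_adjusted_monotone_in_input_order(self):
        rng = np.random.default_rng(2)
        p = rng.random(10)
        adjusted, _ = holm_bonferroni(p)
        order = np.argsort(p)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)


def _ranksum_exact_enumeration(a, b):
    """Exhaustive permutation oracle for the rank-sum p-value (tiny n)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2
    ws = [sum(ranks[list(idx)])
          for idx in combinations(range(len(pooled)), n1)]
    ws = np.array(ws)
    return np.mean(np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-12)


class TestWilcoxon:
    def test_identical_samples(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p > 0.9

    def test_extreme_small_sample_exact(self):
        w, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert abs(p - 0.1) < 1e-12

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 5)
            _, p = wilcoxon_ranksum(a, b)
            assert abs(p - _ranksum_exact_enumeration(a, b)) < 1e-10

    def test_exact_and_asymptotic_agree_at_moderate_n(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.3, 1, 15)
        p_asym = wilcoxon_ranksum(a, b)[1]
        p_exact = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue)
        assert abs(p_asym - p_exact) < 0.02


class TestKS:
    def test_identical_samples(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        rng = np.random.default_rng(5)
        d, p = ks_two_sample(rng.uniform(0, 1, 50), rng.uniform(2, 3, 50))
        assert d == 1.0 and p < 1e-10

    def test_null_rejection_rate(self):
        """Same-distribution pairs at the study's fraction sizes reject at
        about the nominal 1% rate."""
        rng = np.random.default_rng(6)
        rejects = sum(ks_two_sample(rng.normal(0, 1, 285),
                                    rng.normal(0, 1, 656))[1] < 0.01
                      for _ in range(500))
        assert rejects <= 12


class TestBetaRegression:
    def test_slope_recovered_on_model_data(self):
        spec = SwimUpModelSpec(n_males=10, seed=8, genotypes=("YQDEL",),
                               states=("live",),
                               logit_slope={"YQDEL": 0.15},
                               precision_phi=50.0)
        table = generate_swimup_counts(spec)
        fit = betareg_fit(table, formula="x_prop ~ segment")
        slope = fit.coefficients["segment"]
        assert abs(slope - 0.15) < 0.08
        assert fit.phi > 0
        assert np.all((fit.fitted > 0) & (fit.fitted < 1))

    def test_null_data_slope_small(self):
        hits = 0
        for seed in range(20):
            spec = SwimUpModelSpec(n_males=10, seed=seed,
                                   genotypes=("WT",), states=("live",),
                                   logit_slope={"WT": 0.0})
            fit = betareg_fit(generate_swimup_counts(spec),
                              formula="x_prop ~ segment")
            se = fit.model_result.bse["segment"]
            hits += abs(fit.coefficients["segment"]) < 2 * se
        assert hits >= 17

    def test_boundary_proportions_shrunk(self):
        import pandas as pd
        table = pd.DataFrame({
            "male_id": ["m"] * 6, "genotype": ["WT"] * 6,
            "state": ["live"] * 6, "fraction": [1, 2, 3, 4, 5, 6],
            "x_count": [0, 10, 12, 14, 16, 20],
            "y_count": [20, 10, 8, 6, 4, 0]})
        fit = betareg_fit(table, formula="x_prop ~ segment")
        assert np.isfinite(fit.llf)

    def test_rank_deficient_design_rejected(self):
        spec = SwimUpModelSpec(n_males=4, seed=1, genotypes=("WT",),
                               states=("live",))
        table = generate_swimup_counts(spec)
        with pytest.raises(ValueError, match="rank"):
            betareg_fit(table,
                        formula="x_prop ~ segment + I(2*segment)")


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self):
        spec = SwimUpModelSpec(n_males=6, seed=2, genotypes=("WT",),
                               states=("live",))
        table = generate_swimup_counts(spec)
        fit = betareg_fit(table, formula="x_prop ~ segment")
        fit2 = betareg_fit(table, formula="x_prop ~ segment + I(segment**2)")
        chi2, df, p = likelihood_ratio_test(fit2, fit)
        assert df == 1 and chi2 >= 0

    def test_df_bookkeeping(self):
        spec = SwimUpModelSpec(n_males=6, seed=3)
        table = generate_swimup_counts(spec)
        full = betareg_fit(table)
        reduced = betareg_fit(
            table, formula="x_prop ~ C(genotype) * C(state) + segment")
        null = betareg_fit(table, formula="x_prop ~ 1")
        assert likelihood_ratio_test(full, reduced)[1] == 3
        assert likelihood_ratio_test(full, null)[1] == 7

    def test_non_nested_order_rejected(self):
        spec = SwimUpModelSpec(n_males=6, seed=4)
        table = generate_swimup_counts(spec)
        full = betareg_fit(table)
        reduced = betareg_fit(table, formula="x_prop ~ segment")
        with pytest.raises(ValueError):
            likelihood_ratio_test(reduced, full)
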