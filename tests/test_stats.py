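"""Count and size-distribution statistics: exact oracles and recovery."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microdomain.core import ParameterError
from microdomain.stats import (
    HistogramSpec,
    compare_groups,
    compare_poisson_rates,
    fit_lognormal,
    fit_poisson,
    frequency_histogram,
)


def ctest_oracle_equal_exposure(k1: int, K: int) -> Fraction:
    """Exact-rational minimum-likelihood two-sided binomial p at q = 1/2.

    Enumerates every outcome of Binomial(K, 1/2) and sums the probability
    of those no more likely than the observed k1.
    """
    weights = [comb(K, x) for x in range(K + 1)]
    w_obs = weights[k1]
    return Fraction(sum(w for w in weights if w <= w_obs), 2**K)


class TestPoissonFit:
    def test_all_zero_counts(self):
        fit = fit_poisson([0, 0, 0, 0])
        assert fit.lambda_hat == 0.0

    def test_mle_is_sample_mean(self):
        assert fit_poisson([0, 0, 1, 2, 1]).lambda_hat == pytest.approx(0.8)

    def test_ci_contains_lambda_hat(self):
        fit = fit_poisson(np.random.default_rng(1).poisson(0.7, 200))
        assert fit.ci95[0] <= fit.lambda_hat <= fit.ci95[1]

    def test_sampling_error_bound(self):
        counts = np.random.default_rng(2).poisson(0.72, 201)
        fit = fit_poisson(counts)
        assert abs(fit.lambda_hat - 0.72) < 3 * math.sqrt(0.72 / 201)

    @pytest.mark.parametrize("bad", [[], [-1, 0], [0.5, 1.0]])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ParameterError):
            fit_poisson(bad)

    def test_gof_rarely_rejects_true_poisson(self):
        """Type-I of the chi-square GOF at alpha = 0.01 stays at or below 2%."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            fit = fit_poisson(rng.poisson(0.5, 200))
            if np.isfinite(fit.gof_p) and fit.gof_p < 0.01:
                rejections += 1
        assert rejections / n_rep <= 0.02


class TestCTest:
    def test_no_events_gives_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            res = compare_poisson_rates(0, 10, 0, 10)
        assert res.p_two_sided == 1.0
        assert res.degenerate

    def test_matches_exact_enumeration(self):
        res = compare_poisson_rates(3, 10, 12, 10, method="ctest")
        oracle = ctest_oracle_equal_exposure(3, 15)
        assert res.p_two_sided == pytest.approx(float(oracle), abs=1e-12)

    def test_symmetric_under_group_swap(self):
        a = compare_poisson_rates(5, 100, 19, 150, method="ctest")
        b = compare_poisson_rates(19, 150, 5, 100, method="ctest")
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12)

    def test_p_decreases_with_rate_separation(self):
        """For fixed total count and exposures, larger rate differences
        give smaller p-values."""
        K = 20
        ps = [
            compare_poisson_rates(k1, 50, K - k1, 50, method="ctest").p_two_sided
            for k1 in range(K // 2, -1, -1)
        ]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    @given(
        k1=st.integers(0, 25),
        k2=st.integers(0, 25),
        n1=st.floats(1.0, 500.0),
        n2=st.floats(1.0, 500.0),
    )
    def test_p_is_a_probability_and_swap_invariant(self, k1, k2, n1, n2):
        if k1 + k2 == 0:
            return
        a = compare_poisson_rates(k1, n1, k2, n2, method="ctest")
        b = compare_poisson_rates(k2, n2, k1, n1, method="ctest")
        assert 0.0 < a.p_two_sided <= 1.0
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-9)


class TestETest:
    def test_symmetric_under_group_swap(self):
        a = compare_poisson_rates(29, 194, 145, 201, method="etest")
        b = compare_poisson_rates(145, 201, 29, 194, method="etest")
        assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-9)

    def test_agrees_with_ctest_on_clear_difference(self):
        c = compare_poisson_rates(10, 100, 40, 100, method="ctest")
        e = compare_poisson_rates(10, 100, 40, 100, method="etest")
        assert c.p_two_sided < 0.001 and e.p_two_sided < 0.001
        # the unconditional test is typically at least as powerful
        assert e.p_two_sided <= 2 * c.p_two_sided

    def test_null_case_moderate_p(self):
        res = compare_poisson_rates(50, 100, 50, 100, method="etest")
        assert res.p_two_sided > 0.5


class TestLognormalFit:
    def test_equal_sizes_flagged_degenerate(self):
        fit = fit_lognormal([5.0] * 10)
        assert fit.degenerate
        assert fit.sigma_log == 0.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.lognormal(3.2, 0.6, 500)
        fit = fit_lognormal(x)
        se_mu = 0.6 / math.sqrt(500)
        se_sigma = 0.6 / math.sqrt(2 * 500)
        assert abs(fit.mu_log - 3.2) < 3 * se_mu
        assert abs(fit.sigma_log - 0.6) < 3 * se_sigma

    def test_arithmetic_moments_follow_parameters(self):
        fit = fit_lognormal(np.random.default_rng(5).lognormal(3.0, 0.5, 200))
        assert fit.mean_arith == pytest.approx(math.exp(fit.mu_log + fit.sigma_log**2 / 2))
        assert fit.median_arith == pytest.approx(math.exp(fit.mu_log))

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ParameterError):
            fit_lognormal([1.0, -2.0, 3.0])

    def test_default_cluster_law_mean_is_38(self):
        """The generator's high-cholesterol law is parameterized to an
        arithmetic mean of 38 molecules per cluster (median 25)."""
        from microdomain.simgen import FieldSimParams

        p = FieldSimParams(seed=0)
        law_mean = math.exp(p.cluster_logmu + p.cluster_logsigma**2 / 2)
        assert law_mean == pytest.approx(38.0, rel=1e-9)


class TestHistogram:
    def test_empty_input_all_zero(self):
        spec = frequency_histogram([], HistogramSpec(bin_width=2.0))
        assert spec.counts.sum() == 0

    def test_direct_count_example(self):
        # half-open bins [10,12), [12,14): 11 -> bin 0; 12, 13 -> bin 1;
        # 14 lies outside the given edges and is dropped
        spec = frequency_histogram(
            [11, 12, 13, 14], HistogramSpec(bin_width=2.0, bin_edges=np.array([10.0, 12.0, 14.0]))
        )
        assert list(spec.counts) == [1, 2]

    def test_half_open_bins_from_data(self):
        spec = frequency_histogram([11, 12, 13, 14], HistogramSpec(bin_width=2.0))
        assert spec.bin_edges[0] == 10.0
        assert list(spec.counts) == [1, 2, 1]

    @given(st.lists(st.floats(0.0, 100.0), max_size=100))
    def test_counts_conserve_in_range_samples(self, xs):
        spec = frequency_histogram(xs, HistogramSpec(bin_width=2.0))
        if xs:
            lo, hi = spec.bin_edges[0], spec.bin_edges[-1]
            in_range = sum(lo <= x < hi for x in xs)
            assert spec.counts.sum() == in_range

    def test_mismatched_edge_spacing_rejected(self):
        with pytest.raises(ParameterError):
            HistogramSpec(bin_width=2.0, bin_edges=np.array([0.0, 1.0, 2.0]))


class TestGroupComparisons:
    def test_identical_groups_p_near_one(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p_values["a vs b"] >= 0.99

    def test_strong_separation_small_p(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        res = compare_groups({"a": a, "b": b})
        assert res.p_values["a vs b"] < 1e-4

    def test_dunnett_returns_one_p_per_treatment(self):
        rng = np.random.default_rng(7)
        res = compare_groups(
            {
                "ctrl": rng.normal(0, 1, 10),
                "t1": rng.normal(0.5, 1, 10),
                "t2": rng.normal(2, 1, 10),
            },
            test="anova_dunnett",
            control_label="ctrl",
        )
        assert set(res.p_values) == {"t1 vs ctrl", "t2 vs ctrl"}

    def test_tukey_covers_all_pairs(self):
        rng = np.random.default_rng(8)
        res = compare_groups(
            {k: rng.normal(0, 1, 8) for k in "abc"}, test="anova_tukey"
        )
        assert len(res.p_values) == 3

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})
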