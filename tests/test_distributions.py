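"""Beta-binomial invitation distribution: pmf, moments, feasibility,
sampling, thinning and maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rddsim import (
    BetaBinomialParams,
    DegenerateDistributionError,
    FeasibilityError,
    MomentSpec,
    ParameterError,
    bb_fit_mle,
    bb_from_moments,
    bb_moments,
    bb_pmf,
    bb_sample,
    point_mass,
    thin,
    variance_bounds,
)
from rddsim.fixtures import sigma2_high, sigma2_low

# Oracle values for alpha=0.0559, beta=0.1086, c=4, computed from the
# ratio-of-beta-functions formula C(c,k) B(k+a, c-k+b) / B(a, b) with
# 50-digit arithmetic.  These shapes moment-match the observed overall
# sending behaviour (mean 1.36, variance 3.21).
PMF_ORACLE_BIMODAL = {0: 0.60144464025755439, 4: 0.28262308811281541}


class TestPmf:
    def test_uniform_case(self):
        p = BetaBinomialParams(1.0, 1.0, 4)
        assert np.allclose(p.pmf_vector(), 0.2, atol=1e-14)
        assert bb_pmf(0, p) == pytest.approx(0.2, abs=1e-14)

    @pytest.mark.parametrize("k,expected", sorted(PMF_ORACLE_BIMODAL.items()))
    def test_bimodal_matches_exact_formula(self, k, expected):
        p = BetaBinomialParams(0.0559, 0.1086, 4)
        assert bb_pmf(k, p) == pytest.approx(expected, rel=1e-12)

    def test_out_of_support_and_bad_shapes(self):
        p = BetaBinomialParams(1.0, 1.0, 4)
        with pytest.raises(ParameterError):
            bb_pmf(5, p)
        with pytest.raises(ParameterError):
            BetaBinomialParams(-1.0, 1.0, 4)
        with pytest.raises(ParameterError):
            BetaBinomialParams(1.0, 1.0, 0)

    @given(
        log_a=st.floats(math.log(1e-3), math.log(1e3)),
        log_b=st.floats(math.log(1e-3), math.log(1e3)),
        c=st.integers(1, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalisation_across_shape_range(self, log_a, log_b, c):
        p = BetaBinomialParams(math.exp(log_a), math.exp(log_b), c)
        assert abs(p.pmf_vector().sum() - 1.0) < 1e-12

    def test_bimodality_near_max_variance(self):
        # near the upper variance bound the pmf must peak at 0 and c
        for mu in (1.0, 1.36, 2.0, 3.0):
            s2 = 0.97 * variance_bounds(mu, 4)[1]
            v = bb_from_moments(MomentSpec(mu, s2), 4).pmf_vector()
            assert v[0] > v[1] and v[4] > v[3]


class TestMomentsRoundTrip:
    def test_uniform_moments(self):
        m = bb_moments(BetaBinomialParams(1.0, 1.0, 4))
        assert (m.mu, m.sigma2) == (pytest.approx(2.0), pytest.approx(2.0))

    def test_binomial_floor_limit(self):
        # alpha = beta -> infinity approaches the binomial variance
        m = bb_moments(BetaBinomialParams(1e7, 1e7, 4))
        assert m.sigma2 == pytest.approx(4 * 0.5 * 0.5, rel=1e-5)

    def test_observed_overall_moments_invert(self):
        p = bb_from_moments(MomentSpec(1.36, 3.21), 4)
        assert p.alpha == pytest.approx(0.0559, rel=2e-3)
        assert p.beta == pytest.approx(0.1086, rel=2e-3)
        m = bb_moments(p)
        assert m.mu == pytest.approx(1.36, rel=1e-9)
        assert m.sigma2 == pytest.approx(3.21, rel=1e-9)

    def test_inverse_agrees_with_numeric_root_find(self):
        # independent 2-D root-find on the forward moment equations
        from scipy.optimize import fsolve

        def eqs(logs):
            m = bb_moments(BetaBinomialParams(*np.exp(logs), 4))
            return [m.mu - 1.36, m.sigma2 - 3.21]

        a, b = np.exp(fsolve(eqs, [0.0, 0.0], xtol=1e-13))
        p = bb_from_moments(MomentSpec(1.36, 3.21), 4)
        assert p.alpha == pytest.approx(a, rel=1e-6)
        assert p.beta == pytest.approx(b, rel=1e-6)

    @pytest.mark.parametrize("mu", [round(0.1 * i, 1) for i in range(1, 40)])
    @pytest.mark.parametrize("rule", [sigma2_high, sigma2_low])
    def test_round_trip_on_scenario_grid(self, mu, rule):
        s2 = rule(mu)
        m = bb_moments(bb_from_moments(MomentSpec(mu, s2), 4))
        assert m.mu == pytest.approx(mu, rel=1e-9)
        assert m.sigma2 == pytest.approx(s2, rel=1e-9)

    def test_infeasible_variance_raises_naming_band(self):
        with pytest.raises(FeasibilityError, match=r"\(1(\.0)?.*4"):
            bb_from_moments(MomentSpec(2.0, 0.5), 4)

    def test_clamp_projects_inside_band(self):
        p = bb_from_moments(MomentSpec(2.0, 0.5), 4, clamp=True)
        assert bb_moments(p).sigma2 == pytest.approx(1.0 + 1e-6, rel=1e-6)

    def test_degenerate_means_signal_point_mass(self):
        with pytest.raises(DegenerateDistributionError):
            bb_from_moments(MomentSpec(0.0, 0.0), 4)
        with pytest.raises(DegenerateDistributionError):
            bb_from_moments(MomentSpec(4.0, 0.1), 4)


class TestVarianceBounds:
    def test_symmetric_case(self):
        assert variance_bounds(2.0, 4) == (pytest.approx(1.0), pytest.approx(4.0))

    def test_degenerate_mean(self):
        assert variance_bounds(0.0, 4) == (0.0, 0.0)

    def test_observed_moments_are_representable(self):
        lo, hi = variance_bounds(1.36, 4)
        assert lo < 3.21 < hi
        assert hi == pytest.approx(3.5904)

    def test_envelope_via_shape_sweep(self):
        # every representable variance lies strictly inside the bounds
        rng_shapes = np.exp(np.linspace(np.log(1e-3), np.log(1e3), 40))
        for a in rng_shapes:
            for b in rng_shapes:
                m = bb_moments(BetaBinomialParams(a, b, 4))
                lo, hi = variance_bounds(m.mu, 4)
                assert lo < m.sigma2 < hi

    def test_mean_out_of_range(self):
        with pytest.raises(ParameterError):
            variance_bounds(4.5, 4)


class TestSampling:
    def test_empty_sample(self, rng):
        assert bb_sample(BetaBinomialParams(1, 1, 4), 0, rng).size == 0

    def test_reproducible(self):
        p = BetaBinomialParams(0.5, 0.7, 4)
        a = bb_sample(p, 1000, np.random.default_rng(3))
        b = bb_sample(p, 1000, np.random.default_rng(3))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "alpha,beta,mu,sigma2",
        [(1.0, 1.0, 2.0, 2.0), (0.0559, 0.1086, 1.36, 3.21)],
    )
    def test_sample_moments(self, rng, alpha, beta, mu, sigma2):
        x = bb_sample(BetaBinomialParams(alpha, beta, 4), 100_000, rng)
        se = math.sqrt(sigma2 / x.size)
        assert abs(x.mean() - mu) < 3 * se
        assert x.var() == pytest.approx(sigma2, rel=0.05)

    @pytest.mark.parametrize(
        "i,alpha,beta",
        [(0, 0.0559, 0.1086), (1, 1, 1), (2, 2, 5), (3, 0.3, 0.3), (4, 8, 2)],
    )
    def test_sampler_pmf_chi2(self, i, alpha, beta):
        p = BetaBinomialParams(alpha, beta, 4)
        x = bb_sample(p, 100_000, np.random.default_rng(100 + i))
        obs = np.bincount(x, minlength=5)
        assert stats.chisquare(obs, x.size * p.pmf_vector()).pvalue > 0.001


class TestPointMassAndThinning:
    def test_point_mass_moments_and_pmf(self):
        pm = point_mass(4, 4)
        assert pm.moments() == MomentSpec(4.0, 0.0)
        assert pm.pmf_vector().tolist() == [0, 0, 0, 0, 1]
        with pytest.raises(ParameterError):
            point_mass(5, 4)

    def test_point_mass_zero_kills_tree(self, rng):
        assert np.all(point_mass(0, 4).sample(10, rng) == 0)

    def test_thin_edge_cases(self, rng):
        assert thin(0, 0.5, rng) == 0
        assert thin(4, 1.0, rng) == 4
        with pytest.raises(ParameterError):
            thin(4, 1.5, rng)

    def test_thinned_point_mass_mean(self, rng):
        x = thin(np.full(100_000, 4), 0.19, rng)
        se = math.sqrt(4 * 0.19 * 0.81 / x.size)
        assert abs(x.mean() - 0.76) < 3 * se


class TestMLE:
    def test_parameter_recovery(self):
        true = BetaBinomialParams(0.5, 1.0, 4)
        x = bb_sample(true, 100_000, np.random.default_rng(42))
        fit = bb_fit_mle(x, 4)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(0.5, rel=0.05)
        assert fit.params.beta == pytest.approx(1.0, rel=0.05)
        # implied moments recovered to < 2%
        tm = bb_moments(true)
        assert fit.moments.mu == pytest.approx(tm.mu, rel=0.02)
        assert fit.moments.sigma2 == pytest.approx(tm.sigma2, rel=0.02)

    def test_uniform_counts_fit_uniform_shapes(self):
        x = np.random.default_rng(7).integers(0, 5, 200_000)
        fit = bb_fit_mle(x, 4)
        assert fit.params.alpha == pytest.approx(1.0, rel=0.05)
        assert fit.params.beta == pytest.approx(1.0, rel=0.05)

    def test_constant_counts_are_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            bb_fit_mle(np.full(50, 2), 4)

    def test_loglik_no_worse_than_moment_start(self):
        x = bb_sample(BetaBinomialParams(0.3, 0.6, 4), 5000, np.random.default_rng(5))
        fit = bb_fit_mle(x, 4)
        start = bb_from_moments(MomentSpec(x.mean(), x.var()), 4)
        ll_start = np.log(start.pmf_vector())[x].sum()
        assert fit.log_likelihood >= ll_start - 1e-9
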