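"""Unit and property tests for the distribution's analytic functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from wtexpd import (
    EULER_GAMMA,
    OrderStatSpec,
    ParameterError,
    SupportError,
    WTexpdParams,
    cdf,
    cumulative_hazard,
    entropy,
    hazard,
    kurtosis,
    mean,
    order_statistic_pdf,
    pdf,
    quantile,
    raw_moment,
    rvs,
    sf,
    skewness,
    variance,
)


def wp(tau=0.0, lam=1.0, beta=1.0, theta=1.0):
    return WTexpdParams.from_scale(tau=tau, lam=lam, beta=beta, theta=theta)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tau=0.0, alpha=1.0, theta=1.0, beta=0.0),
            dict(tau=0.0, alpha=1.0, theta=1.0, beta=-2.0),
            dict(tau=0.0, alpha=1.0, theta=-1.0, beta=1.0),  # lam < 0
            dict(tau=0.0, alpha=1.0, theta=0.0, beta=1.0),
            dict(tau=np.inf, alpha=1.0, theta=1.0, beta=1.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            WTexpdParams(**kwargs)

    def test_negative_pair_allowed(self):
        # both scale components negative, positive ratio: valid (seen in fits)
        p = WTexpdParams(tau=0.0, alpha=-0.279, theta=-0.124, beta=0.583)
        assert p.lam == pytest.approx(0.279 / 0.124)


class TestPointValues:
    def test_unit_exponential_reduction(self):
        assert pdf(1.0, wp()) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_pdf_vanishes_at_threshold_for_steep_shape(self):
        assert pdf(3.0, wp(tau=3.0, lam=2.0, beta=2.5)) == 0.0

    def test_pdf_boundary_beta_one_and_below(self):
        assert pdf(3.0, wp(tau=3.0, lam=2.0, beta=1.0)) == pytest.approx(0.5)
        with pytest.warns(RuntimeWarning):
            assert pdf(3.0, wp(tau=3.0, lam=2.0, beta=0.7)) == np.inf

    def test_cdf_endpoints(self):
        p = wp(tau=2.0, lam=3.0, beta=1.3)
        assert cdf(2.0, p) == 0.0
        assert cdf(2.0 + 3.0, p) == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)

    def test_sf_complements_cdf(self, rng):
        p = wp(tau=1.0, lam=2.0, beta=0.8)
        x = 1.0 + rng.exponential(2.0, size=200)
        assert np.max(np.abs(sf(x, p) + cdf(x, p) - 1.0)) < 1e-12

    def test_constant_hazard_iff_beta_one(self):
        p = wp(lam=2.0, beta=1.0)
        for t in (0.3, 1.7, 9.0):
            assert hazard(t, p) == pytest.approx(0.5, rel=1e-14)

    def test_hazard_direct_value(self):
        # beta=2, lam=1: h(t) = 2t, cross-checked by -d ln S/dt
        p = wp(beta=2.0)
        assert hazard(3.0, p) == pytest.approx(6.0, rel=1e-12)
        h = 1e-6
        fd = -(np.log(sf(3.0 + h, p)) - np.log(sf(3.0 - h, p))) / (2 * h)
        assert hazard(3.0, p) == pytest.approx(fd, rel=1e-8)

    def test_support_errors(self):
        p = wp(tau=5.0)
        with pytest.raises(SupportError):
            hazard(5.0, p)
        with pytest.raises(SupportError):
            cumulative_hazard(4.9, p)
        assert cumulative_hazard(5.0, p) == 0.0


class TestIdentities:
    @pytest.mark.parametrize("tau,lam,beta", [(0.0, 1.0, 2.5), (1.0, 2.0, 0.8), (-3.0, 0.5, 1.0)])
    def test_hazard_is_pdf_over_sf(self, tau, lam, beta, rng):
        p = wp(tau, lam, beta)
        t = tau + rng.exponential(lam, size=100) + 1e-9
        assert np.max(np.abs(hazard(t, p) - pdf(t, p) / sf(t, p))) < 1e-10

    @pytest.mark.parametrize("tau,lam,beta", [(0.0, 1.5, 0.9), (2.0, 3.0, 1.7)])
    def test_cumulative_hazard_is_minus_log_sf(self, tau, lam, beta, rng):
        p = wp(tau, lam, beta)
        t = tau + rng.exponential(lam, size=100)
        assert np.max(np.abs(cumulative_hazard(t, p) + np.log(sf(t, p)))) < 1e-10

    def test_cumulative_hazard_integrates_hazard(self):
        p = wp(0.0, 1.5, 0.9)
        val, _ = integrate.quad(lambda t: hazard(t, p), 0.0, 2.0, points=[1e-12])
        assert val == pytest.approx(cumulative_hazard(2.0, p), abs=1e-6)

    def test_cdf_matches_pdf_quadrature(self):
        p = wp(1.0, 2.0, 0.8)
        grid = 1.0 + np.linspace(0.05, 8.0, 50)
        for x in grid:
            val, _ = integrate.quad(lambda t: pdf(t, p), 1.0, x)
            assert abs(val - cdf(x, p)) < 1e-8

    def test_normalization_over_random_parameters(self, rng):
        for _ in range(50):
            p = wp(
                tau=rng.uniform(-5, 5),
                lam=rng.uniform(0.2, 5.0),
                beta=rng.uniform(0.3, 4.0),
            )
            val, _ = integrate.quad(
                lambda t: pdf(t, p), p.tau, np.inf, limit=200
            )
            assert abs(val - 1.0) < 1e-8

    def test_scale_pair_invariance(self, rng):
        base = WTexpdParams(tau=0.5, alpha=2.0, theta=0.8, beta=1.3)
        x = 0.5 + rng.exponential(1.0, size=50)
        for c in (2.0, -3.5, 0.01):
            scaled = WTexpdParams(tau=0.5, alpha=2.0 * c, theta=0.8 * c, beta=1.3)
            assert np.allclose(pdf(x, base), pdf(x, scaled), rtol=1e-14)
            assert np.allclose(cdf(x, base), cdf(x, scaled), rtol=1e-14)
            assert quantile(0.37, base) == pytest.approx(quantile(0.37, scaled), rel=1e-14)

    def test_reduces_to_exponential_and_weibull(self, rng):
        # theta=1, beta=1, alpha=1/rate: exponential(rate); theta=1: 3-par Weibull
        x = rng.exponential(1.0, size=50)
        rate = 2.7
        p_exp = WTexpdParams(tau=0.0, alpha=1.0 / rate, theta=1.0, beta=1.0)
        assert np.allclose(pdf(x, p_exp), stats.expon.pdf(x, scale=1 / rate), rtol=1e-12)
        p_w = WTexpdParams(tau=0.4, alpha=2.2, theta=1.0, beta=1.6)
        assert np.allclose(
            pdf(x + 0.4 + 1e-9, p_w),
            stats.weibull_min.pdf(x + 0.4 + 1e-9, 1.6, loc=0.4, scale=2.2),
            rtol=1e-10,
        )


class TestQuantile:
    def test_endpoints_and_median(self):
        p = wp(tau=2.0, lam=3.0, beta=2.0)
        assert quantile(0.0, p) == pytest.approx(2.0)
        assert quantile(1 - math.exp(-1.0), wp(lam=1.0, beta=3.3)) == pytest.approx(1.0)
        # oracle: numeric root of the cdf
        root = optimize.brentq(lambda x: cdf(x, p) - 0.5, 2.0 + 1e-12, 100.0, xtol=1e-13)
        assert quantile(0.5, p) == pytest.approx(root, abs=1e-9)
        assert quantile(0.5, p) == pytest.approx(2.0 + 3.0 * math.log(2.0) ** 0.5, rel=1e-12)

    def test_round_trip_grid(self):
        p = wp(tau=-1.0, lam=2.5, beta=0.6)
        grid = np.arange(0.01, 1.0, 0.01)
        assert np.max(np.abs(cdf(quantile(grid, p), p) - grid)) < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            quantile(1.0, wp())
        with pytest.raises(ValueError):
            quantile(-0.1, wp())

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        tau=st.floats(-10, 10),
        lam=st.floats(0.05, 20),
        beta=st.floats(0.2, 6),
        prob=st.floats(0.0, 0.999),
    )
    def test_round_trip_property(self, tau, lam, beta, prob):
        p = wp(tau, lam, beta)
        q = quantile(prob, p)
        assert q >= tau
        assert cdf(q, p) == pytest.approx(prob, abs=1e-9)


class TestRandomVariates:
    def test_deterministic_under_seed(self):
        p = wp(1.0, 2.0, 1.5)
        a = rvs(p, 5, seed=123)
        b = rvs(p, 5, seed=123)
        assert np.array_equal(a, b)

    def test_support_and_size(self):
        x = rvs(wp(tau=7.0), 1000, seed=1)
        assert x.shape == (1000,)
        assert np.all(x > 7.0)

    def test_law_of_large_numbers(self):
        x = rvs(wp(), 10**5, seed=5)
        assert abs(np.mean(x) - 1.0) < 3.0 / np.sqrt(10**5)

    def test_bad_size(self):
        with pytest.raises(ValueError):
            rvs(wp(), 0, seed=1)


class TestMoments:
    def test_exponential_moments(self):
        assert raw_moment(1, wp()) == pytest.approx(1.0)
        assert raw_moment(2, wp()) == pytest.approx(2.0)
        assert mean(wp(tau=2.0, lam=3.0)) == pytest.approx(5.0)
        assert variance(wp(tau=2.0, lam=3.0)) == pytest.approx(9.0)

    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_raw_moments_match_quadrature(self, r):
        p = wp(tau=1.0, lam=2.0, beta=1.3)
        val, _ = integrate.quad(lambda x: x**r * pdf(x, p), 1.0, np.inf, limit=200)
        assert raw_moment(r, p) == pytest.approx(val, abs=1e-6)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            raw_moment(5, wp())

    def test_mean_half_normal_case(self):
        assert mean(wp(beta=2.0)) == pytest.approx(math.sqrt(math.pi) / 2.0, rel=1e-12)

    def test_variance_location_invariant(self):
        assert variance(wp(tau=0.0, lam=1.0, beta=0.7)) == pytest.approx(
            variance(wp(tau=100.0, lam=1.0, beta=0.7)), rel=1e-14
        )

    def test_skewness_kurtosis_exponential(self):
        assert skewness(wp()) == pytest.approx(2.0, rel=1e-9)
        assert kurtosis(wp()) == pytest.approx(9.0, rel=1e-9)

    def test_shape_only_dependence(self):
        assert skewness(wp(0.0, 1.0, 1.5)) == pytest.approx(
            skewness(wp(50.0, 9.0, 1.5)), rel=1e-12
        )
        assert kurtosis(wp(0.0, 1.0, 1.5)) == pytest.approx(
            kurtosis(wp(50.0, 9.0, 1.5)), rel=1e-12
        )

    def test_skewness_matches_simulation(self):
        p = wp(beta=2.0)
        x = rvs(p, 10**6, seed=11)
        z = (x - x.mean()) / x.std()
        mc = float(np.mean(z**3))
        se = float(np.std(z**3)) / np.sqrt(x.size)
        assert abs(skewness(p) - mc) < 3 * se


class TestEntropy:
    def test_exponential_values(self):
        assert entropy(wp(lam=1.0)) == pytest.approx(1.0, rel=1e-12)
        assert entropy(wp(lam=math.e)) == pytest.approx(2.0, rel=1e-12)

    def test_location_invariance(self):
        assert entropy(wp(tau=0.0, lam=2.0, beta=1.5)) == pytest.approx(
            entropy(wp(tau=42.0, lam=2.0, beta=1.5)), rel=1e-14
        )

    def test_matches_weibull_closed_form(self):
        lam, beta = 2.0, 1.5
        expected = EULER_GAMMA * (1 - 1 / beta) + math.log(lam / beta) + 1
        assert entropy(wp(lam=lam, beta=beta)) == pytest.approx(expected, rel=1e-14)

    def test_monte_carlo_negative_mean_log_density(self):
        p = wp(lam=2.0, beta=1.5)
        x = rvs(p, 10**6, seed=21)
        lg = np.log(pdf(x, p))
        mc = -float(np.mean(lg))
        se = float(np.std(lg)) / np.sqrt(x.size)
        assert abs(entropy(p) - mc) < 3 * se


class TestOrderStatistics:
    def test_single_draw_is_pdf(self, rng):
        p = wp(1.0, 2.0, 1.4)
        x = 1.0 + rng.exponential(2.0, size=30)
        assert np.allclose(
            order_statistic_pdf(x, p, OrderStatSpec(1, 1)), pdf(x, p), rtol=1e-14
        )

    def test_maximum_of_three_normalizes(self):
        p = wp()
        val, _ = integrate.quad(
            lambda x: order_statistic_pdf(x, p, OrderStatSpec(3, 3)), 0, np.inf
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_minimum_of_five_exponentials(self):
        # min of 5 unit exponentials is Exponential(rate 5)
        got = order_statistic_pdf(0.2, wp(), OrderStatSpec(1, 5))
        assert got == pytest.approx(5.0 * math.exp(-1.0), rel=1e-12)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            OrderStatSpec(0, 3)
        with pytest.raises(ValueError):
            OrderStatSpec(4, 3)
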