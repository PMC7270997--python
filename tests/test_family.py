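"""The NE-X generator: distribution functions, quantile, sampler."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from nexdist import NewExtended, Weibull, new_weibull

LN2 = np.log(2.0)


class TestCdf:
    def test_zero_at_support_lower_end(self):
        for theta in (0.25, 1.0, 7.0):
            m = new_weibull(theta, 1.3, 0.8)
            assert m.cdf(0.0) == 0.0
            assert m.cdf(-3.0) == 0.0

    def test_theta_one_reduces_to_F_squared(self, exp_theta1):
        # the family collapses to the exponentiated (max-of-two) case
        x = np.linspace(0.01, 12, 200)
        F = exp_theta1.baseline.cdf(x)
        np.testing.assert_allclose(exp_theta1.cdf(x), F**2, rtol=0, atol=1e-15)

    def test_theta_two_hand_value(self, theta2_model):
        # F = 0.5 at x = ln 2; G = 1 - (0.75/1.25)^2 = 0.64
        assert theta2_model.cdf(LN2) == pytest.approx(0.64, abs=1e-14)

    def test_monotone_and_limits(self):
        m = new_weibull(5.0, 0.7, 2.0)
        x = np.linspace(0, 50, 500)
        g = m.cdf(x)
        assert np.all(np.diff(g) >= 0)
        assert g[-1] == pytest.approx(1.0, abs=1e-12)

    def test_invalid_theta_rejected(self, unit_weibull):
        for theta in (0.0, -1.0):
            with pytest.raises(ValueError):
                NewExtended(theta, unit_weibull)


class TestPdf:
    def test_zero_outside_support(self, theta2_model):
        assert theta2_model.pdf(0.0) == 0.0
        assert theta2_model.pdf(-1.0) == 0.0

    @pytest.mark.parametrize(
        "theta, expected", [(1.0, 1.0), (2.0, 1.536)]
    )
    def test_hand_values_at_f1_F_half(self, theta, expected):
        # Weibull(a=1, gamma=2) has f = 1 and F = 0.5 at x = (ln 2)/2
        m = NewExtended(theta, Weibull(1.0, 2.0))
        x = LN2 / 2.0
        assert m.baseline.cdf(x) == pytest.approx(0.5, abs=1e-15)
        assert m.pdf(x) == pytest.approx(expected, rel=1e-12)

    def test_theta_one_reduces_to_2fF(self, exp_theta1):
        x = np.linspace(0.05, 10, 100)
        f = np.exp(exp_theta1.baseline.logpdf(x))
        F = exp_theta1.baseline.cdf(x)
        np.testing.assert_allclose(exp_theta1.pdf(x), 2 * f * F, rtol=1e-14)

    @pytest.mark.parametrize("theta", [0.25, 0.5, 1.0, 2.0, 5.0, 20.0])
    def test_normalizes_to_one(self, theta):
        m = new_weibull(theta, 0.9, 1.0)
        total, _ = integrate.quad(m.pdf, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_matches_numeric_cdf_derivative(self, theta2_model):
        x = np.linspace(0.1, 5, 80)
        h = 1e-6
        num = (theta2_model.cdf(x + h) - theta2_model.cdf(x - h)) / (2 * h)
        np.testing.assert_allclose(theta2_model.pdf(x), num, atol=1e-5)


class TestSurvivalHazard:
    def test_sf_one_at_origin(self, theta2_model):
        assert theta2_model.sf(0.0) == 1.0

    def test_sf_complement_hand_value(self, theta2_model):
        assert theta2_model.sf(LN2) == pytest.approx(0.36, abs=1e-14)

    def test_hazard_hand_value(self, exp_theta1):
        # g = 2fF = 0.5 and S = 0.75 at x = ln 2
        assert exp_theta1.hazard(LN2) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_hazard_domain_error_where_sf_zero(self):
        # a bounded-support parent makes the survival exactly zero past the
        # upper endpoint, where the hazard is undefined
        from nexdist.baselines import Baseline

        class Uniform01(Baseline):
            name = "uniform01"
            params = {}

            def cdf(self, x):
                return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)

            def logpdf(self, x):
                x = np.asarray(x, dtype=float)
                return np.where((x > 0) & (x < 1), 0.0, -np.inf)

        m = NewExtended(3.0, Uniform01())
        assert m.hazard(0.5) > 0
        with pytest.raises(ValueError):
            m.hazard(2.0)

    def test_hazard_finite_and_positive_in_deep_tail(self):
        m = new_weibull(3.0, 2.0, 1.0)
        h = m.hazard(50.0)  # float survival underflows but logs stay finite
        assert np.isfinite(h) and h > 0

    def test_sf_strictly_decreasing_in_theta(self):
        # stochastic ordering of the family in the extension parameter
        thetas = [0.25, 0.5, 1.0, 1.5, 3.0, 10.0]
        for x in (0.3, 1.0, 2.5):
            sfs = [new_weibull(t, 1.2, 0.9).sf(x) for t in thetas]
            assert np.all(np.diff(sfs) < 0)


class TestQuantile:
    def test_u_zero_maps_to_support_low(self, theta2_model):
        assert theta2_model.ppf(0.0) == 0.0

    def test_hand_value_theta2(self, theta2_model):
        # u=0.64: w=0.6, F^2 = 0.4/1.6 = 0.25 -> x with F = 0.5
        assert theta2_model.ppf(0.64) == pytest.approx(LN2, rel=1e-12)

    def test_theta_one_branch(self, exp_theta1):
        # G = F^2, so the 0.25-quantile is the parent median
        assert exp_theta1.ppf(0.25) == pytest.approx(LN2, rel=1e-12)

    def test_rejects_u_outside_unit_interval(self, theta2_model):
        for u in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                theta2_model.ppf(u)

    def test_matches_printed_sampler_formula(self):
        # closed form: x = [-log(1 - ((w-1)/((1-theta)w-1))^(1/2)) / gamma]^(1/a)
        theta, a, gamma = 2.7, 1.4, 0.6
        m = new_weibull(theta, a, gamma)
        u = np.array([0.05, 0.3, 0.64, 0.9, 0.99])
        w = (1 - u) ** (1 / theta)
        ref = (-np.log(1 - np.sqrt((w - 1) / ((1 - theta) * w - 1))) / gamma) ** (1 / a)
        np.testing.assert_allclose(m.ppf(u), ref, rtol=1e-10)

    @given(
        theta=st.floats(0.05, 30.0),
        a=st.floats(0.3, 4.0),
        gamma=st.floats(0.05, 5.0),
        u=st.floats(1e-6, 1 - 1e-6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_cdf_inverts_quantile(self, theta, a, gamma, u):
        m = new_weibull(theta, a, gamma)
        assert m.cdf(m.ppf(u)) == pytest.approx(u, abs=1e-8)

    def test_numeric_fallback_agrees_with_closed_form(self):
        # a parent exposing only cdf/logpdf exercises the generic
        # root-finding quantile; compare against the closed-form Weibull path
        from nexdist.baselines import Baseline

        ref = Weibull(1.2, 0.8)

        class NumericParent(Baseline):
            name = "numeric"
            params = {}

            def cdf(self, x):
                return ref.cdf(x)

            def logpdf(self, x):
                return ref.logpdf(x)

        m_num = NewExtended(1.7, NumericParent())
        m_closed = new_weibull(1.7, 1.2, 0.8)
        for u in (0.1, 0.5, 0.9):
            assert m_num.ppf(u) == pytest.approx(m_closed.ppf(u), rel=1e-9)


class TestSampler:
    def test_empty_sample(self, theta2_model):
        assert theta2_model.rvs(0, seed=1).size == 0

    def test_negative_size_rejected(self, theta2_model):
        with pytest.raises(ValueError):
            theta2_model.rvs(-1, seed=1)

    def test_deterministic_given_seed(self, theta2_model):
        a = theta2_model.rvs(100, seed=42)
        b = theta2_model.rvs(100, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_empirical_distribution_matches_cdf(self, theta2_model):
        x = theta2_model.rvs(10_000, seed=7)
        assert stats.kstest(x, theta2_model.cdf).pvalue > 0.01

    def test_all_positive(self):
        m = new_weibull(0.3, 0.7, 2.0)
        assert np.all(m.rvs(5000, seed=3) > 0)
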