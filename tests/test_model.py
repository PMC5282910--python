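"""Generative-model unit and property tests.

Closed-form oracles: the Weibull-PH cumulative hazard and ten-year risk have
explicit formulas; Monte-Carlo summaries are checked against direct
numerical integration over the frailty distribution.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from cmrctsim import (
    ModelParams,
    cumulative_hazard,
    draw_frailties,
    latent_time_log_correlation,
    population_risk_summary,
    sample_event_time,
    ten_year_risk,
)


class TestModelParams:
    def test_defaults(self, params):
        assert (params.lambda_c, params.gamma_c) == (36.0, 1.2)
        assert (params.lambda_m, params.gamma_m) == (55.0, 1.2)
        assert (params.sigma, params.beta, params.t_max) == (0.7, -0.32, 3.0)

    @pytest.mark.parametrize(
        "bad", [{"lambda_c": 0}, {"gamma_c": -1}, {"sigma": -0.1}, {"t_max": 0}]
    )
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestFrailties:
    def test_zero_variance_and_determinism(self):
        assert np.all(draw_frailties(5, 0.0, np.random.default_rng(1)) == 0.0)
        a = draw_frailties(3, 0.7, np.random.default_rng(42))
        b = draw_frailties(3, 0.7, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_large_sample_moments(self, rng):
        eps = draw_frailties(10**6, 0.7, rng)
        assert abs(eps.mean()) < 0.01
        assert abs(eps.std() - 0.7) < 0.01

    def test_invalid_arguments(self, rng):
        with pytest.raises(ValueError):
            draw_frailties(0, 0.7, rng)
        with pytest.raises(ValueError):
            draw_frailties(5, -1.0, rng)


class TestCumulativeHazard:
    def test_closed_form_values(self):
        assert cumulative_hazard(36.0, 36.0, 1.2) == pytest.approx(1.0)
        assert cumulative_hazard(10.0, 36.0, 1.2) == pytest.approx(0.2150, abs=5e-5)
        assert cumulative_hazard(0.0, 36.0, 1.2) == 0.0

    @given(
        t=st.floats(0.01, 50), eta=st.floats(-3, 3), shape=st.floats(0.5, 3)
    )
    def test_proportional_hazards_exact(self, t, eta, shape):
        base = cumulative_hazard(t, 36.0, shape, eta)
        doubled = cumulative_hazard(t, 36.0, shape, eta + np.log(2.0))
        assert doubled == pytest.approx(2.0 * base, rel=1e-12)

    def test_monotone_in_t(self):
        t = np.linspace(0, 30, 100)
        h = cumulative_hazard(t, 36.0, 1.2, 0.3)
        assert np.all(np.diff(h) > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cumulative_hazard(-1.0, 36.0, 1.2)


class TestEventTimes:
    def test_cdf_matches_closed_form(self, rng):
        t = sample_event_time(36.0, 1.2, 0.0, rng, size=10**5)
        assert np.all(t > 0)
        frac = (t <= 10.0).mean()
        assert frac == pytest.approx(1.0 - np.exp(-0.2150), abs=0.01)

    def test_exponential_special_case(self, rng):
        t = sample_event_time(36.0, 1.0, 0.0, rng, size=10**5)
        assert t.mean() == pytest.approx(36.0, rel=0.02)

    def test_strictly_decreasing_in_eta_for_fixed_u(self):
        etas = np.linspace(-2, 4, 13)
        draws = [
            sample_event_time(36.0, 1.2, e, np.random.default_rng(7), size=50)
            for e in etas
        ]
        for lo, hi in zip(draws, draws[1:]):
            assert np.all(hi < lo)


class TestTenYearRisk:
    def test_closed_form_values(self, params):
        assert ten_year_risk(0.0, params, 0) == pytest.approx(0.1935, abs=5e-5)
        assert ten_year_risk(0.0, params, 1) == pytest.approx(0.1445, abs=5e-5)

    def test_monotone_in_epsilon_and_protective(self, params):
        eps = np.linspace(-2, 2, 41)
        r0 = ten_year_risk(eps, params, 0)
        r1 = ten_year_risk(eps, params, 1)
        assert np.all(np.diff(r0) > 0)
        assert np.all(r1 < r0)
        assert np.all((r0 > 0) & (r0 < 1))


class TestPopulationSummary:
    def test_degenerate_frailty(self, rng):
        mean, sd = population_risk_summary(1000, ModelParams(sigma=0.0), rng)
        assert mean == pytest.approx(0.1935, abs=5e-5)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_numerical_integration(self, params, rng):
        """MC mean/SD of ten-year risk vs direct Gauss quadrature over the
        frailty density (independent oracle)."""
        h10 = (10.0 / params.lambda_c) ** params.gamma_c

        def moment(k):
            f = lambda s: (1 - np.exp(-h10 * np.exp(s))) ** k * stats.norm.pdf(
                s, scale=params.sigma
            )
            return integrate.quad(f, -6, 6)[0]

        m1 = moment(1)
        sd_true = np.sqrt(moment(2) - m1**2)
        mean, sd = population_risk_summary(10**5, params, rng)
        assert mean == pytest.approx(m1, abs=0.005)
        assert sd == pytest.approx(sd_true, abs=0.005)

    def test_too_small_n_rejected(self, params, rng):
        with pytest.raises(ValueError):
            population_risk_summary(1, params, rng)


class TestLatentCorrelation:
    def test_analytic_values(self):
        assert latent_time_log_correlation(0.0, 1.2) == 0.0
        assert latent_time_log_correlation(0.7, 1.2) == pytest.approx(
            0.2295, abs=5e-5
        )
        assert latent_time_log_correlation(100.0, 1.2) == pytest.approx(1.0, abs=1e-3)

    def test_simulation_matches_analytic_on_log_scale(self, params, rng):
        eps = draw_frailties(10**5, params.sigma, rng)
        tc = sample_event_time(params.lambda_c, params.gamma_c, eps, rng)
        tm = sample_event_time(params.lambda_m, params.gamma_m, eps, rng)
        r_log = np.corrcoef(np.log(tc), np.log(tm))[0, 1]
        assert r_log == pytest.approx(
            latent_time_log_correlation(params.sigma, params.gamma_c), abs=0.01
        )


def test_marginal_survival_matches_integrated_curve(params, rng):
    """Empirical survival of uncensored control times vs the frailty-mixed
    marginal E_eps[exp(-(t/lambda_c)^gamma_c e^eps)], numerically integrated."""
    eps = draw_frailties(10**5, params.sigma, rng)
    tc = sample_event_time(params.lambda_c, params.gamma_c, eps, rng)
    for t in (1.0, 2.0, 3.0):
        h = (t / params.lambda_c) ** params.gamma_c
        marginal = integrate.quad(
            lambda s: np.exp(-h * np.exp(s)) * stats.norm.pdf(s, scale=params.sigma),
            -6,
            6,
        )[0]
        assert (tc > t).mean() == pytest.approx(marginal, abs=0.01)
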