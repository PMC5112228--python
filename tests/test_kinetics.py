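"""Closed-form kinetics: logistic growth, cumulative biomass, product/substrate laws."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy.integrate import quad

from rhamnopt import (
    BatchKineticParams,
    YieldSet,
    integral_biomass,
    logistic_biomass,
    product_concentration,
    specific_rates,
    substrate_concentration,
)

from conftest import GRID

# high-precision (40-digit) evaluation of the logistic closed form at
# mu=0.13, x0=0.1, xm=3.04, t=24
X_AT_24 = 1.3227624012899144
# likewise for the cumulative-biomass closed form at t=20
B_AT_20 = 8.034570170855122


def valid_params(draw):
    mu = draw(st.floats(0.02, 1.0))
    x0 = draw(st.floats(0.01, 1.0))
    xm = x0 * draw(st.floats(1.5, 50.0))
    return BatchKineticParams(mu_max=mu, x0=x0, xm=xm)


params_st = st.builds(
    lambda mu, x0, ratio: BatchKineticParams(mu_max=mu, x0=x0, xm=x0 * ratio),
    st.floats(0.02, 1.0),
    st.floats(0.01, 1.0),
    st.floats(1.5, 50.0),
)


class TestLogisticBiomass:
    def test_starts_at_x0_and_saturates_at_xm(self, growth_params):
        assert logistic_biomass(growth_params, 0.0) == pytest.approx(0.1, abs=0)
        assert logistic_biomass(growth_params, 1e6) == pytest.approx(3.04, rel=1e-12)

    def test_matches_high_precision_oracle(self, growth_params):
        assert logistic_biomass(growth_params, 24.0) == pytest.approx(
            X_AT_24, rel=1e-14
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=params_st, t=st.floats(0.01, 48.0))
    def test_solves_the_logistic_ode(self, params, t):
        """Central-difference derivative equals mu*(1 - x/xm)*x."""
        assume(params.mu_max * t < 8.0)  # finite differences lose precision
        # once the curve saturates
        h = 1e-4
        x = logistic_biomass(params, t)
        dx = (
            logistic_biomass(params, t + h) - logistic_biomass(params, t - h)
        ) / (2 * h)
        expected = params.mu_max * (1 - x / params.xm) * x
        assert dx == pytest.approx(expected, rel=1e-5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=params_st, t=st.floats(0.0, 200.0))
    def test_bounded_between_x0_and_xm(self, params, t):
        x = logistic_biomass(params, t)
        assert params.x0 * (1 - 1e-15) <= x <= params.xm
        if params.mu_max * t < 30.0:  # below float saturation of the tail
            assert x < params.xm

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            BatchKineticParams(mu_max=-0.1, x0=0.1, xm=3.0)
        with pytest.raises(ValueError):
            BatchKineticParams(mu_max=0.1, x0=3.0, xm=1.0)
        with pytest.raises(ValueError):
            logistic_biomass(
                BatchKineticParams(mu_max=0.1, x0=0.1, xm=3.0), -1.0
            )


class TestIntegralBiomass:
    def test_zero_at_origin(self, growth_params):
        assert integral_biomass(growth_params, 0.0) == 0.0

    def test_matches_high_precision_oracle(self, growth_params):
        assert integral_biomass(growth_params, 20.0) == pytest.approx(
            B_AT_20, rel=1e-13
        )

    def test_derivative_is_the_biomass(self, growth_params):
        h = 1e-6
        d = (
            integral_biomass(growth_params, 10.0 + h)
            - integral_biomass(growth_params, 10.0 - h)
        ) / (2 * h)
        assert d == pytest.approx(logistic_biomass(growth_params, 10.0), rel=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(params=params_st, t=st.floats(0.1, 48.0))
    def test_equals_adaptive_quadrature(self, params, t):
        ref, _ = quad(
            lambda tau: logistic_biomass(params, tau), 0.0, t,
            epsabs=1e-12, epsrel=1e-12,
        )
        assert integral_biomass(params, t) == pytest.approx(ref, rel=1e-8)

    def test_no_overflow_at_long_times(self, growth_params):
        assert np.isfinite(integral_biomass(growth_params, 1e4))


class TestLuedekingPiretLaws:
    def test_product_reduces_to_p0_without_coefficients(self):
        p = BatchKineticParams(mu_max=0.2, x0=0.1, xm=2.0, p0=0.7)
        assert np.all(product_concentration(p, GRID) == 0.7)

    def test_product_matches_term_by_term_evaluation(self):
        p = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, alpha=0.3091, beta=-0.000009, p0=0.05
        )
        t = GRID
        expected = (
            0.05
            + 0.3091 * (logistic_biomass(p, t) - 0.1)
            - 0.000009 * integral_biomass(p, t)
        )
        np.testing.assert_allclose(product_concentration(p, t), expected, rtol=1e-14)

    def test_product_vanishing_terms_at_t0(self, full_params):
        assert product_concentration(full_params, 0.0) == full_params.p0

    def test_substrate_trivial_cases(self):
        p = BatchKineticParams(mu_max=0.2, x0=0.1, xm=2.0, s0=5.0)
        assert np.all(substrate_concentration(p, GRID) == 5.0)
        assert substrate_concentration(p, 0.0) == 5.0

    def test_substrate_monotone_decline_with_positive_coefficients(self):
        p = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, gamma=0.85, eta=0.45, s0=30.0
        )
        s = substrate_concentration(p, GRID)
        assert np.all(np.diff(s) <= 0)

    def test_substrate_floor_and_depletion_flag(self):
        p = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, gamma=0.85, eta=0.45, s0=5.0
        )
        s, depleted = substrate_concentration(p, GRID, return_depleted=True)
        assert np.all(s >= 0)
        assert depleted[-1] and not depleted[0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a1=st.floats(-1, 1), b1=st.floats(-0.01, 0.01),
        a2=st.floats(-1, 1), b2=st.floats(-0.01, 0.01),
        lam=st.floats(0, 1),
    )
    def test_linearity_in_the_coefficients(self, a1, b1, a2, b2, lam):
        """p(t) is linear in (alpha, beta) at fixed growth parameters."""
        def make(a, b):
            return BatchKineticParams(
                mu_max=0.13, x0=0.1, xm=3.04, alpha=a, beta=b
            )

        t = GRID[1:]
        mix = product_concentration(
            make(lam * a1 + (1 - lam) * a2, lam * b1 + (1 - lam) * b2), t
        )
        combo = lam * product_concentration(make(a1, b1), t) + (
            1 - lam
        ) * product_concentration(make(a2, b2), t)
        np.testing.assert_allclose(mix, combo, rtol=1e-9, atol=1e-12)

    def test_substrate_linear_in_coefficients_before_flooring(self):
        def make(g, e):
            return BatchKineticParams(
                mu_max=0.13, x0=0.1, xm=3.04, gamma=g, eta=e, s0=10.0
            )

        t = GRID
        mix = substrate_concentration(make(0.5, 0.1), t, floor=False)
        combo = 0.5 * substrate_concentration(make(1.0, 0.2), t, floor=False) + (
            0.5 * substrate_concentration(make(0.0, 0.0), t, floor=False)
        )
        np.testing.assert_allclose(mix, combo, rtol=1e-12)


class TestSpecificRates:
    def test_rest_state_and_maintenance_only(self):
        ys = YieldSet(Yxs_glucose=0.5, Yxs_nitrogen=0.4, Yxs_phosphorous=0.3,
                      Yps=0.47, M=0.0)
        assert specific_rates(0.0, ys) == (0.0, 0.0, 0.0, 0.0)
        ys_m = YieldSet(Yxs_glucose=0.5, Yxs_nitrogen=0.4, Yxs_phosphorous=0.3,
                        Yps=0.47, M=0.02)
        q = specific_rates(0.0, ys_m)
        assert q.q_s_glucose == pytest.approx(0.02)
        assert q.q_s_nitrogen == q.q_s_phosphorous == q.q_p == 0.0

    def test_hand_arithmetic(self):
        ys = YieldSet(Yxs_glucose=0.5, M=0.01)
        assert specific_rates(0.1, ys).q_s_glucose == pytest.approx(0.21)

    def test_zero_yield_raises(self):
        with pytest.raises(ZeroDivisionError):
            specific_rates(0.1, YieldSet(Yxs_glucose=0.0))
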