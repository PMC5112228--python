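"""Fed-batch simulator: feed profiles, analytic limits, mass balances."""

import numpy as np
import pytest

from rhamnopt import (
    BatchKineticParams,
    FedBatchState,
    FeedProfile,
    GrowthLaw,
    feed_rate_at,
    logistic_biomass,
    mass_balance_audit,
    product_concentration,
    simulate_fedbatch,
    substrate_concentration,
)


def constant_profile(rate, substrate="glucose", sF=10.0, **kw):
    return FeedProfile(
        kind="piecewise_constant",
        rates={substrate: np.full(12, rate)},
        feed_concentrations={substrate: sF},
        **kw,
    )


class TestFeedRateAt:
    def test_constant_profile_is_flat(self):
        prof = constant_profile(0.45)
        for t in [0.0, 3.9, 24.0, 47.9, 48.0]:
            assert feed_rate_at(prof, "glucose", t) == 0.45

    def test_half_open_interval_convention(self):
        rates = np.arange(12, dtype=float)
        prof = FeedProfile(kind="piecewise_constant",
                           rates={"glucose": rates},
                           feed_concentrations={"glucose": 10.0})
        assert feed_rate_at(prof, "glucose", 4.0) == 1.0   # right interval
        assert feed_rate_at(prof, "glucose", 48.0) == 11.0  # last closed

    def test_exponential_with_zero_lambda_is_constant(self):
        prof = FeedProfile(kind="exponential_then_constant",
                           rates={"glucose": (0.02, 0.0, 24.0)},
                           feed_concentrations={"glucose": 10.0})
        assert feed_rate_at(prof, "glucose", 5.0) == 0.02
        assert feed_rate_at(prof, "glucose", 40.0) == 0.02

    def test_exponential_holds_after_switch(self):
        prof = FeedProfile(kind="exponential_then_constant",
                           rates={"glucose": (0.01, 0.05, 24.0)},
                           feed_concentrations={"glucose": 10.0})
        at_switch = 0.01 * np.exp(0.05 * 24.0)
        assert feed_rate_at(prof, "glucose", 30.0) == pytest.approx(at_switch)

    def test_outside_horizon_raises(self):
        prof = constant_profile(0.45)
        with pytest.raises(ValueError):
            feed_rate_at(prof, "glucose", 50.0)

    def test_unfed_substrate_rate_is_zero(self):
        assert feed_rate_at(constant_profile(0.45), "nitrogen", 10.0) == 0.0


class TestFeedProfileValidation:
    def test_wrong_interval_count_rejected(self):
        with pytest.raises(ValueError, match="intervals"):
            FeedProfile(kind="piecewise_constant",
                        rates={"glucose": np.zeros(10)},
                        feed_concentrations={"glucose": 10.0})

    def test_bounds_violation_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            constant_profile(0.1, bounds=(0.01, 0.06))

    def test_switch_time_outside_horizon_rejected(self):
        with pytest.raises(ValueError, match="t_switch"):
            FeedProfile(kind="exponential_then_constant",
                        rates={"glucose": (0.01, 0.0, 60.0)},
                        feed_concentrations={"glucose": 10.0})


class TestBatchLimit:
    def test_zero_feed_reduces_to_closed_forms(self, batch_init, logistic_growth):
        """Grid-point agreement with the logistic and integrated
        Luedeking-Piret forms at <= 1e-6 relative."""
        params = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, alpha=0.3091, beta=-0.000009,
            gamma=0.6111, eta=0.0002, s0=10.0,
        )
        tc = simulate_fedbatch(
            batch_init, logistic_growth, params, constant_profile(0.0)
        )
        t = tc.times
        np.testing.assert_allclose(
            tc.biomass, logistic_biomass(params, t), rtol=1e-6
        )
        np.testing.assert_allclose(
            tc.product[1:], product_concentration(params, t)[1:], rtol=1e-6
        )
        np.testing.assert_allclose(
            tc.substrates["glucose"], substrate_concentration(params, t),
            rtol=1e-6,
        )

    def test_zero_feed_conserves_volume(self, batch_init, logistic_growth, full_params):
        tc = simulate_fedbatch(
            batch_init, logistic_growth, full_params, constant_profile(0.0)
        )
        np.testing.assert_array_equal(tc.volume, np.full(13, 1.0))


def _dormant_growth():
    """A growth law that yields mu = 0 everywhere (threshold above s0)."""
    return GrowthLaw(mu_max=0.5, kind="substrate_limited",
                     Ks=1.0, Ki=1.0, Si=1e6)


class TestDilutionLimits:
    def test_constant_feed_dilution_closed_form(self):
        """mu = 0, q = 0: S(t) = sF + (S0 - sF) V0/(V0 + F t)."""
        init = FedBatchState(V=1.0, X=0.1, S={"glucose": 2.0})
        params = BatchKineticParams(mu_max=0.5, x0=0.1, xm=3.04)
        prof = constant_profile(0.45, sF=10.0)
        tc = simulate_fedbatch(
            init, _dormant_growth(), params, prof,
            substrate_coeffs={"glucose": (0.0, 0.0)},
            product_coeffs=(0.0, 0.0),
        )
        t = tc.times
        expected = 10.0 + (2.0 - 10.0) * 1.0 / (1.0 + 0.45 * t)
        np.testing.assert_allclose(tc.substrates["glucose"], expected, rtol=1e-6)

    def test_pure_water_feed_dilutes_everything(self):
        init = FedBatchState(V=1.0, X=1.0, S={"glucose": 5.0}, P=0.5)
        params = BatchKineticParams(mu_max=0.5, x0=0.1, xm=3.04)
        prof = constant_profile(0.2, sF=0.0)
        tc = simulate_fedbatch(
            init, _dormant_growth(), params, prof,
            substrate_coeffs={"glucose": (0.0, 0.0)},
            product_coeffs=(0.0, 0.0),
        )
        for series in (tc.biomass, tc.product, tc.substrates["glucose"]):
            assert np.all(np.diff(series) < 0)
        np.testing.assert_allclose(tc.volume, 1.0 + 0.2 * tc.times, rtol=1e-9)


class TestMassBalance:
    def test_closure_below_1e6_for_feeding_run(self, logistic_growth):
        init = FedBatchState(V=1.0, X=0.1,
                             S={"glucose": 10.0, "nitrogen": 1.7})
        params = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, alpha=0.3091, beta=-0.000009
        )
        prof = FeedProfile(
            kind="piecewise_constant",
            rates={"glucose": np.full(12, 0.03),
                   "nitrogen": np.full(12, 0.01)},
            feed_concentrations={"glucose": 10.0, "nitrogen": 1.7},
        )
        tc = simulate_fedbatch(
            init, logistic_growth, params, prof,
            substrate_coeffs={"glucose": (0.6111, 0.0002),
                              "nitrogen": (0.0112, -0.000003)},
        )
        closure = mass_balance_audit(tc, prof)
        assert max(closure.values()) < 1e-6

    def test_batch_limit_has_zero_fed_mass(self, batch_init, logistic_growth, full_params):
        prof = constant_profile(0.0)
        tc = simulate_fedbatch(batch_init, logistic_growth, full_params, prof)
        assert tc.metadata["fed_volume"]["glucose"] == 0.0

    def test_closure_degrades_with_looser_tolerance(self, logistic_growth):
        init = FedBatchState(V=1.0, X=0.1, S={"glucose": 10.0})
        params = BatchKineticParams(
            mu_max=0.13, x0=0.1, xm=3.04, gamma=0.6111, eta=0.0002, s0=10.0
        )
        prof = constant_profile(0.03)
        errs = []
        for rtol in (1e-10, 1e-7, 1e-4):
            tc = simulate_fedbatch(
                init, logistic_growth, params, prof, rtol=rtol,
                atol=rtol * 1e-3,
            )
            errs.append(mass_balance_audit(tc, prof)["glucose"])
        assert errs[0] <= errs[1] <= errs[2]


class TestWithdrawal:
    def test_negative_rates_clamped_by_default(self, logistic_growth, full_params):
        init = FedBatchState(V=1.0, X=0.1, S={"glucose": 10.0})
        prof = constant_profile(-0.01)
        tc = simulate_fedbatch(init, logistic_growth, full_params, prof)
        np.testing.assert_array_equal(tc.volume, np.full(13, 1.0))

    def test_withdrawal_mode_shrinks_volume(self, logistic_growth, full_params):
        init = FedBatchState(V=1.0, X=0.1, S={"glucose": 10.0})
        prof = constant_profile(-0.01)
        tc = simulate_fedbatch(
            init, logistic_growth, full_params, prof, allow_withdrawal=True
        )
        np.testing.assert_allclose(tc.volume, 1.0 - 0.01 * tc.times, rtol=1e-9)


def test_grid_refinement_stability(batch_init, logistic_growth, full_params):
    """Endpoints are solver-tolerance converged: tightening rtol by 10x
    moves the 48-h state by < 1e-6 relative."""
    prof = constant_profile(0.03)
    a = simulate_fedbatch(batch_init, logistic_growth, full_params, prof,
                          rtol=1e-9, atol=1e-12)
    b = simulate_fedbatch(batch_init, logistic_growth, full_params, prof,
                          rtol=1e-10, atol=1e-13)
    assert abs(a.product[-1] - b.product[-1]) / b.product[-1] < 1e-6
    assert abs(a.biomass[-1] - b.biomass[-1]) / b.biomass[-1] < 1e-6
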