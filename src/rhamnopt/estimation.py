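"""Kinetic-constant estimation from batch time courses.

Two-stage procedure: (1) nonlinear least squares of the logistic closed form
to the biomass series gives (mu_max, x0, xm); (2) given that growth fit, the
Luedeking-Piret coefficients are obtained by ordinary least squares of the
product (or substrate-depletion) response on the two regressors
A(t) = x(t) - x0 and B(t) = int_0^t x dt, both evaluated from the growth fit.
No intercept is fitted: p0/s0 are taken from the first observation, which
makes the regression exactly p - p0 = alpha*A + beta*B.

Yield coefficients are whole-run ratios Delta(biomass)/Delta(substrate),
reported signed as observed (negative when substrate is consumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .kinetics import (
    SUBSTRATES,
    BatchKineticParams,
    TimeCourse,
    biomass_increment,
    integral_biomass,
    logistic_biomass,
)

__all__ = [
    "LogisticFit",
    "RegressionFit",
    "FitResult",
    "fit_logistic",
    "fit_product_params",
    "fit_substrate_params",
    "compute_yield_coefficients",
    "fit_batch_kinetics",
]

#: Condition number above which an OLS design matrix is flagged.
COND_WARN_THRESHOLD = 1e8


@dataclass(frozen=True)
class LogisticFit:
    mu_max: float
    x0: float
    xm: float
    residual_sumsq: float
    n_obs: int

    def params(self, **kwargs) -> BatchKineticParams:
        return BatchKineticParams(
            mu_max=self.mu_max, x0=self.x0, xm=self.xm, **kwargs
        )


@dataclass(frozen=True)
class RegressionFit:
    """OLS result for one Luedeking-Piret pair (growth/non-growth coeff)."""

    growth_coeff: float
    nongrowth_coeff: float
    residual_sumsq: float
    n_obs: int
    condition_warning: bool


@dataclass
class FitResult:
    """Aggregated batch fit: growth, product, per-substrate coefficients."""

    growth: LogisticFit
    product: RegressionFit | None
    substrates: dict[str, RegressionFit] = field(default_factory=dict)
    yields: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "growth": {
                "mu_max": self.growth.mu_max,
                "x0": self.growth.x0,
                "xm": self.growth.xm,
                "residual_sumsq": self.growth.residual_sumsq,
                "n_obs": self.growth.n_obs,
            }
        }
        if self.product is not None:
            out["product"] = {
                "alpha": self.product.growth_coeff,
                "beta": self.product.nongrowth_coeff,
                "residual_sumsq": self.product.residual_sumsq,
                "condition_warning": self.product.condition_warning,
            }
        out["substrates"] = {
            name: {
                "gamma": fit.growth_coeff,
                "eta": fit.nongrowth_coeff,
                "residual_sumsq": fit.residual_sumsq,
                "condition_warning": fit.condition_warning,
            }
            for name, fit in self.substrates.items()
        }
        if self.yields:
            out["yields"] = dict(self.yields)
        return out


class EstimationError(RuntimeError):
    """Raised when a series carries no usable signal or a fit fails."""


def _mu_init_from_early_slope(t: np.ndarray, x: np.ndarray) -> float:
    """Log-linear slope of the early (sub-half-saturation) phase."""
    cutoff = x.min() + 0.5 * (x.max() - x.min())
    mask = x <= cutoff
    if mask.sum() < 2:
        mask = np.zeros_like(mask)
        mask[: max(2, x.size // 3)] = True
    slope = stats.linregress(t[mask], np.log(x[mask])).slope
    return float(np.clip(slope, 1e-3, 5.0))


def fit_logistic(
    tc: TimeCourse, *, fix_x0: bool = False
) -> LogisticFit:
    """Fit the logistic closed form to the biomass series.

    Multi-start nonlinear least squares: xm is initialized at the maximum
    observed biomass, mu_max at the early-phase log-linear slope plus a
    small ladder of fallback starts, x0 at the first observation (held
    fixed when ``fix_x0``).

    Raises
    ------
    EstimationError
        For fewer than 4 points, non-positive biomass, a flat (non-growing)
        series, or optimizer failure at every start.
    """
    t = tc.times
    x = tc.biomass
    if x.size < 4:
        raise EstimationError(f"need >= 4 biomass observations, got {x.size}")
    if np.any(x <= 0):
        raise EstimationError("biomass must be strictly positive")
    if x.max() < 1.02 * x.min():
        raise EstimationError(
            "no growth signal: biomass varies by < 2% over the run"
        )

    x0_init = float(x[0])
    xm_init = float(x.max()) * 1.05
    mu_starts = {_mu_init_from_early_slope(t, x), 0.05, 0.2, 0.5}

    def residuals(theta: np.ndarray) -> np.ndarray:
        if fix_x0:
            mu, xm = theta
            x0 = x0_init
        else:
            mu, x0, xm = theta
        p = BatchKineticParams(mu_max=mu, x0=x0, xm=xm)
        return logistic_biomass(p, t) - x

    lo = [1e-6, x.max() * (1 + 1e-9)] if fix_x0 else [1e-6, 1e-12, x.max() * (1 + 1e-9)]
    hi = [10.0, 100.0 * x.max()] if fix_x0 else [10.0, x.max(), 100.0 * x.max()]

    best = None
    for mu0 in sorted(mu_starts):
        theta0 = [mu0, xm_init] if fix_x0 else [mu0, x0_init, xm_init]
        theta0 = np.clip(theta0, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
        except (ValueError, RuntimeError):
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise EstimationError("logistic fit failed to converge from any start")

    if fix_x0:
        mu, xm = best.x
        x0 = x0_init
    else:
        mu, x0, xm = best.x
    return LogisticFit(
        mu_max=float(mu), x0=float(x0), xm=float(xm),
        residual_sumsq=float(2 * best.cost), n_obs=int(x.size),
    )


def _lp_regression(
    t: np.ndarray, response: np.ndarray, growth: BatchKineticParams
) -> RegressionFit:
    """OLS of a zero-intercept response on [A(t), B(t)] from the growth fit."""
    A = biomass_increment(growth, t)
    B = integral_biomass(growth, t)
    X = np.column_stack([A, B])
    if response.size < 2:
        raise EstimationError("need >= 2 usable observations for regression")
    coeffs, _, _, sing = np.linalg.lstsq(X, response, rcond=None)
    resid = response - X @ coeffs
    cond = float(sing[0] / sing[-1]) if sing[-1] > 0 else np.inf
    return RegressionFit(
        growth_coeff=float(coeffs[0]),
        nongrowth_coeff=float(coeffs[1]),
        residual_sumsq=float(resid @ resid),
        n_obs=int(response.size),
        condition_warning=bool(cond > COND_WARN_THRESHOLD),
    )


def fit_product_params(
    tc: TimeCourse, growth: BatchKineticParams
) -> RegressionFit:
    """Estimate the product-formation pair (alpha, beta) by OLS.

    Response is p(t) - p0 with p0 the first observation; a flat product
    series legitimately returns alpha = beta = 0.
    """
    response = tc.product - tc.product[0]
    return _lp_regression(tc.times, response, growth)


def fit_substrate_params(
    tc: TimeCourse, growth: BatchKineticParams, substrate_name: str
) -> RegressionFit:
    """Estimate the depletion pair (gamma, eta) for one substrate by OLS.

    Response is s0 - s(t). Samples reported as exactly 0 after a positive
    start are treated as censored by the nonnegativity floor (the culture
    exhausted that substrate) and excluded from the regression.
    """
    if substrate_name not in tc.substrates:
        raise KeyError(f"time course has no substrate {substrate_name!r}")
    s = tc.substrates[substrate_name]
    keep = (s > 0) | (np.arange(s.size) == 0)
    response = s[0] - s[keep]
    return _lp_regression(tc.times[keep], response, growth)


def compute_yield_coefficients(tc: TimeCourse) -> dict[str, float]:
    """Whole-run yield ratios, signed as observed.

    Per substrate: Y_{x/s} = Delta(biomass)/Delta(substrate) — negative when
    biomass rises while the substrate falls, matching the sign convention of
    the published tables. Product yield Y_{p/s} uses the glucose change.
    Zero biomass change yields 0; zero substrate change raises.
    """
    if not tc.substrates:
        raise EstimationError("no substrate series present")
    dx = float(tc.biomass[-1] - tc.biomass[0])
    dp = float(tc.product[-1] - tc.product[0])
    out: dict[str, float] = {}
    for name, s in tc.substrates.items():
        ds = float(s[-1] - s[0])
        if ds == 0:
            if dx == 0:
                out[f"Yxs_{name}"] = 0.0
                continue
            raise EstimationError(
                f"substrate {name!r} unchanged over the run: yield undefined"
            )
        out[f"Yxs_{name}"] = dx / ds
    if "glucose" in tc.substrates:
        ds = float(tc.substrates["glucose"][-1] - tc.substrates["glucose"][0])
        if ds != 0:
            out["Yps"] = dp / ds
    return out


def fit_batch_kinetics(
    tc: TimeCourse, *, fix_x0: bool = False
) -> FitResult:
    """Full batch pipeline: logistic fit, then product/substrate OLS, yields."""
    growth_fit = fit_logistic(tc, fix_x0=fix_x0)
    growth = growth_fit.params()
    product = fit_product_params(tc, growth) if tc.product.size else None
    substrates = {
        name: fit_substrate_params(tc, growth, name)
        for name in SUBSTRATES
        if name in tc.substrates
    }
    yields = compute_yield_coefficients(tc) if tc.substrates else {}
    return FitResult(
        growth=growth_fit, product=product, substrates=substrates, yields=yields
    )
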