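"""Closed-form batch kinetics for rhamnolipid fermentation.

Biomass follows Verhulst logistic growth,

    dx/dt = mu_max * (1 - x/x_m) * x,
    x(t)  = x_m x_0 e^{mu t} / (x_m - x_0 + x_0 e^{mu t}),

and product/substrate follow the integrated Luedeking-Piret law: the product
formation rate is a linear combination of the growth rate (growth-associated
coefficient ``alpha``) and the biomass itself (non-growth-associated
coefficient ``beta``), so that

    p(t) = p_0 + alpha * A(t) + beta * B(t),
    s(t) = s_0 - gamma * A(t) - eta * B(t),

with A(t) = x(t) - x_0 and B(t) = int_0^t x(tau) d tau, which for the logistic
has the closed form (x_m/mu_max) * ln(1 - (x_0/x_m)(1 - e^{mu t})).

Specific consumption/production rates used by the fed-batch simulator are the
standard Pirt forms q_s = mu/Y_{x/s} (+ maintenance M for the carbon source)
and q_p = mu/Y_{p/s}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "SUBSTRATES",
    "BatchKineticParams",
    "YieldSet",
    "TimeCourse",
    "ReferenceEndpoints",
    "SpecificRates",
    "logistic_biomass",
    "biomass_increment",
    "integral_biomass",
    "product_concentration",
    "substrate_concentration",
    "specific_rates",
]

#: Canonical substrate names, in column order.
SUBSTRATES = ("glucose", "nitrogen", "phosphorous")


@dataclass(frozen=True)
class BatchKineticParams:
    """Logistic growth + Luedeking-Piret constants for one batch culture.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate, 1/h. Must be positive.
    x0, xm : float
        Initial and maximum (carrying-capacity) biomass, g/l; 0 < x0 < xm.
    alpha, beta : float
        Growth-associated (g/g) and non-growth-associated (g/(g h)) product
        formation coefficients.
    gamma, eta : float
        Growth-associated (g/g) and non-growth-associated (g/(g h)) substrate
        consumption coefficients (consumption-positive convention).
    p0, s0 : float
        Initial product and substrate concentrations, g/l (nonnegative).
    """

    mu_max: float
    x0: float
    xm: float
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    eta: float = 0.0
    p0: float = 0.0
    s0: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu_max > 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if not 0 < self.x0 < self.xm:
            raise ValueError(
                f"need 0 < x0 < xm, got x0={self.x0}, xm={self.xm}"
            )
        if self.p0 < 0 or self.s0 < 0:
            raise ValueError("initial concentrations must be nonnegative")


@dataclass(frozen=True)
class YieldSet:
    """Biomass/product yields and maintenance for the Pirt rate laws.

    ``Yxs_*`` are biomass-per-substrate yields (g/g), ``Yps`` the product
    yield (g/g), ``M`` the maintenance coefficient (g substrate per g biomass
    per h) charged against the carbon source (glucose). A yield left ``None``
    means the corresponding rate is not defined for this run.
    """

    Yxs_glucose: float | None = None
    Yxs_nitrogen: float | None = None
    Yxs_phosphorous: float | None = None
    Yps: float | None = None
    M: float = 0.0

    def Yxs(self, substrate: str) -> float | None:
        return getattr(self, f"Yxs_{substrate}")


class SpecificRates(NamedTuple):
    """Specific rates (1/h): substrate uptake per substrate and production."""

    q_s_glucose: float
    q_s_nitrogen: float
    q_s_phosphorous: float
    q_p: float


@dataclass
class TimeCourse:
    """A sampled fermentation trajectory.

    All series share the length of ``times`` (hours, strictly increasing,
    starting at 0). Concentrations are g/l; ``volume`` (l) is present only
    for fed-batch runs. ``metadata`` carries generator/simulator provenance
    (ground-truth parameters, seeds, mass-balance integrals).
    """

    times: np.ndarray
    biomass: np.ndarray
    product: np.ndarray
    substrates: dict[str, np.ndarray] = field(default_factory=dict)
    volume: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.biomass = np.asarray(self.biomass, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        self.substrates = {
            k: np.asarray(v, dtype=float) for k, v in self.substrates.items()
        }
        if self.volume is not None:
            self.volume = np.asarray(self.volume, dtype=float)
        n = self.times.size
        if n < 1:
            raise ValueError("empty time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, series in self.series().items():
            if series.size != n:
                raise ValueError(
                    f"series {name!r} has length {series.size}, expected {n}"
                )
        for name in self.substrates:
            if name not in SUBSTRATES:
                raise ValueError(f"unknown substrate {name!r}")

    def series(self) -> dict[str, np.ndarray]:
        out = {"biomass": self.biomass, "product": self.product}
        out.update(self.substrates)
        if self.volume is not None:
            out["volume"] = self.volume
        return out

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ReferenceEndpoints:
    """Tabulated fed-batch constants and 48-h endpoints for one condition.

    One column of the published fed-batch constants table: feeding
    ``strategy`` ('constant' or 'exponential') crossed with the fed
    ``substrate``. Values are shipped verbatim as printed, including signs.
    """

    strategy: str
    substrate: str
    Umax: float
    l: float
    h: float
    F: float
    Ki: float
    Si: float
    Sgf: float
    Snf: float
    Spf: float
    alpha: float
    beta: float
    gamma: float
    eta: float
    Ks: float
    Muf: float
    Y: float
    Xf: float
    Pf: float
    Sf: float

    def __post_init__(self) -> None:
        if self.strategy not in ("constant", "exponential"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.substrate not in SUBSTRATES:
            raise ValueError(f"unknown substrate {self.substrate!r}")


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def biomass_increment(params: BatchKineticParams, t) -> np.ndarray | float:
    """Growth-associated term A(t) = x(t) - x_0, g/l.

    Evaluated as (x_m - x_0)(1 - e^{-mu t}) / (1 + r e^{-mu t}) with
    r = (x_m - x_0)/x_0, which is exactly 0 at t = 0 and overflow-free for
    any horizon.
    """
    t = _check_time(t)
    r = (params.xm - params.x0) / params.x0
    em = np.exp(-params.mu_max * t)
    out = (params.xm - params.x0) * (-np.expm1(-params.mu_max * t)) / (1.0 + r * em)
    return out if np.ndim(out) else float(out)


def logistic_biomass(params: BatchKineticParams, t) -> np.ndarray | float:
    """Logistic biomass x(t), g/l, evaluated in overflow-safe form.

    Uses x(t) = x_m / (1 + (x_m/x_0 - 1) e^{-mu t}), algebraically identical
    to the e^{+mu t} form but stable for large mu*t.
    """
    t = _check_time(t)
    ratio = (params.xm - params.x0) / params.x0
    out = params.xm / (1.0 + ratio * np.exp(-params.mu_max * t))
    return out if out.ndim else float(out)


def integral_biomass(params: BatchKineticParams, t) -> np.ndarray | float:
    """Cumulative biomass B(t) = int_0^t x(tau) d tau, g h / l.

    Closed form (x_m/mu) ln(1 + (x_0/x_m)(e^{mu t} - 1)), evaluated through
    log1p/expm1 (exact 0 at t = 0) with a log-sum-exp fallback for mu*t
    large enough to overflow e^{mu t}.
    """
    t = _check_time(t)
    mu, x0, xm = params.mu_max, params.x0, params.xm
    z = np.atleast_1d(np.asarray(mu * t, dtype=float))
    small = z < 500.0
    log_arg = np.empty_like(z)
    log_arg[small] = np.log1p((x0 / xm) * np.expm1(z[small]))
    if not small.all():
        zl = z[~small]
        log_arg[~small] = (
            np.logaddexp(np.log(xm - x0), np.log(x0) + zl) - np.log(xm)
        )
    out = (xm / mu) * log_arg
    return out if np.ndim(t) else float(out[0])


def product_concentration(params: BatchKineticParams, t) -> np.ndarray | float:
    """Integrated Luedeking-Piret product p(t) = p0 + alpha*A(t) + beta*B(t)."""
    A = biomass_increment(params, t)
    B = integral_biomass(params, t)
    return params.p0 + params.alpha * A + params.beta * B


def substrate_concentration(
    params: BatchKineticParams, t, *, floor: bool = True, return_depleted: bool = False
):
    """Substrate s(t) = s0 - gamma*A(t) - eta*B(t), floored at zero.

    With ``return_depleted=True`` also returns a boolean mask of samples at
    which the un-floored value was negative (i.e. the model predicts
    exhaustion and the reported 0 is a censored value).
    """
    A = biomass_increment(params, t)
    B = integral_biomass(params, t)
    raw = params.s0 - params.gamma * A - params.eta * B
    depleted = np.asarray(raw) < 0
    out = np.maximum(raw, 0.0) if floor else raw
    out = out if np.ndim(out) else float(out)
    if return_depleted:
        return out, (depleted if depleted.ndim else bool(depleted))
    return out


def specific_rates(mu: float, yields: YieldSet) -> SpecificRates:
    """Pirt specific rates at instantaneous specific growth rate ``mu`` (1/h).

    q_s,glucose = mu/Y_{x/s} + M (maintenance on the carbon source only);
    q_s,nitrogen = mu/Y_{x/s}; q_s,phosphorous = mu/Y_{x/s};
    q_p = mu/Y_{p/s}. A ``None`` yield gives a zero rate; a zero yield used
    as a divisor raises.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")

    def _ratio(y: float | None, label: str) -> float:
        if y is None:
            return 0.0
        if y == 0:
            raise ZeroDivisionError(f"yield {label} is zero")
        return mu / y

    return SpecificRates(
        q_s_glucose=_ratio(yields.Yxs_glucose, "Yxs_glucose") + yields.M,
        q_s_nitrogen=_ratio(yields.Yxs_nitrogen, "Yxs_nitrogen"),
        q_s_phosphorous=_ratio(yields.Yxs_phosphorous, "Yxs_phosphorous"),
        q_p=_ratio(yields.Yps, "Yps"),
    )
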