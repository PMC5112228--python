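"""Synthetic fermentation time courses for testing estimation/optimization.

Emulates the study design: one biomass series, one rhamnolipid series and
three substrate series sampled every 4 h over a 48-h run (13 points), with
measurement noise. Default ground truth comes from the packaged constants:
growth mu_max = 0.13 1/h, xm = 3.04 g/l, product (alpha, beta) =
(0.3091, -9e-6), per-substrate depletion pairs from the published batch
constants, and initial substrate levels from the culture-medium recipe
(glucose 10.0, nitrogen 1.7, phosphorous 3.0 g/l). Default noise is
multiplicative Gaussian with sigma = 0.05, a typical assay-level scatter.

Ground-truth parameters are recorded in the output's metadata so recovery
tests are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tables
from .fedbatch import FedBatchState, FeedProfile, GrowthLaw, simulate_fedbatch
from .kinetics import (
    SUBSTRATES,
    BatchKineticParams,
    TimeCourse,
    YieldSet,
    logistic_biomass,
    product_concentration,
    substrate_concentration,
)

__all__ = [
    "NoiseModel",
    "default_growth_params",
    "default_substrate_params",
    "generate_batch_timecourse",
    "generate_fedbatch_timecourse",
]

DEFAULT_SCHEDULE = np.arange(0.0, 48.0 + 1e-9, 4.0)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description.

    kind 'multiplicative_gaussian': y * (1 + sigma*Z); 'additive_gaussian':
    y + sigma*Z. sigma = 0 reproduces the model exactly.
    """

    kind: str = "multiplicative_gaussian"
    sigma: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive_gaussian", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(y.shape)
        if self.kind == "multiplicative_gaussian":
            noisy = y * (1.0 + self.sigma * z)
        else:
            noisy = y + self.sigma * z
        return np.maximum(noisy, 0.0)


def default_growth_params(*, x0: float = 0.1) -> BatchKineticParams:
    """Published growth + rhamnolipid constants as a parameter set."""
    prod = tables.batch_constants("rhamnolipid")
    mu = tables.model_parameters("constant", "glucose")["mu_max"]
    xm = tables.reference_endpoints("constant", "glucose").Xf
    return BatchKineticParams(
        mu_max=mu, x0=x0, xm=xm, alpha=prod["alpha"], beta=prod["beta"]
    )


def default_substrate_params() -> dict[str, tuple[float, float, float]]:
    """Per-substrate (gamma, eta, s0): published batch pairs + medium levels."""
    out = {}
    for name in SUBSTRATES:
        row = tables.batch_constants(name)
        out[name] = (row["alpha"], row["beta"], tables.medium_concentration(name))
    return out


def generate_batch_timecourse(
    params: BatchKineticParams | None = None,
    schedule: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    *,
    substrate_params: dict[str, tuple[float, float, float]] | None = None,
) -> TimeCourse:
    """Batch run: closed-form kinetics on the grid, plus measurement noise.

    ``substrate_params`` maps substrate name to (gamma, eta, s0); product
    coefficients and growth come from ``params``. Negative noisy values are
    truncated at zero, like any real assay floor.
    """
    params = params if params is not None else default_growth_params()
    t = np.asarray(schedule, float) if schedule is not None else DEFAULT_SCHEDULE
    noise = noise if noise is not None else NoiseModel()
    if substrate_params is None:
        substrate_params = default_substrate_params()

    rng = np.random.default_rng(noise.seed)
    biomass = logistic_biomass(params, t)
    product = product_concentration(params, t)
    substrates = {}
    for name, (gamma, eta, s0) in substrate_params.items():
        p_sub = BatchKineticParams(
            mu_max=params.mu_max, x0=params.x0, xm=params.xm,
            gamma=gamma, eta=eta, s0=s0,
        )
        substrates[name] = substrate_concentration(p_sub, t)
    if noise.sigma > 0:
        biomass = noise.apply(biomass, rng)
        product = noise.apply(product, rng)
        substrates = {k: noise.apply(v, rng) for k, v in substrates.items()}
    return TimeCourse(
        times=t, biomass=biomass, product=np.maximum(product, 0.0),
        substrates=substrates,
        metadata={
            "generator": "batch_closed_form",
            "truth": {
                "mu_max": params.mu_max, "x0": params.x0, "xm": params.xm,
                "alpha": params.alpha, "beta": params.beta, "p0": params.p0,
                "substrates": {
                    k: {"gamma": g, "eta": e, "s0": s}
                    for k, (g, e, s) in substrate_params.items()
                },
            },
            "noise": {"kind": noise.kind, "sigma": noise.sigma,
                      "seed": noise.seed},
        },
    )


def generate_fedbatch_timecourse(
    init: FedBatchState,
    growth: GrowthLaw,
    params: BatchKineticParams,
    profile: FeedProfile,
    noise: NoiseModel | None = None,
    *,
    yields: YieldSet | None = None,
    substrate_coeffs: dict[str, tuple[float, float]] | None = None,
    **sim_kwargs,
) -> TimeCourse:
    """Fed-batch run: ODE simulation as the signal, plus measurement noise.

    Noise applies to the measured concentrations (biomass, product,
    substrates) but not to the volume, which is known from the pump totals.
    """
    noise = noise if noise is not None else NoiseModel()
    tc = simulate_fedbatch(
        init, growth, params, profile,
        yields=yields, substrate_coeffs=substrate_coeffs, **sim_kwargs,
    )
    rng = np.random.default_rng(noise.seed)
    if noise.sigma > 0:
        tc = TimeCourse(
            times=tc.times,
            biomass=noise.apply(tc.biomass, rng),
            product=noise.apply(tc.product, rng),
            substrates={k: noise.apply(v, rng) for k, v in tc.substrates.items()},
            volume=tc.volume,
            metadata=tc.metadata,
        )
    tc.metadata["noise"] = {
        "kind": noise.kind, "sigma": noise.sigma, "seed": noise.seed
    }
    tc.metadata["truth"] = {
        "mu_max": params.mu_max, "alpha": params.alpha, "beta": params.beta,
        "growth_law": growth.kind,
    }
    return tc
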