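"""Packaged parameter fixtures: published batch/fed-batch kinetic constants.

Values are stored verbatim as printed — including negative yield
coefficients and the occasional internal inconsistency between tables (e.g.
two different growth rates for the same condition). Nothing is "corrected"
here; helpers expose magnitudes with sign flags where the model needs
consumption-positive coefficients.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .kinetics import ReferenceEndpoints

__all__ = [
    "load_tables",
    "batch_constants",
    "reference_endpoints",
    "model_parameters",
    "medium_concentration",
    "signed_magnitude",
]


@lru_cache(maxsize=1)
def load_tables() -> dict:
    """The full fixture as a nested dict (cached)."""
    with resources.files("rhamnopt.data").joinpath("tables.json").open() as fh:
        return json.load(fh)


def batch_constants(series: str) -> dict:
    """Batch Luedeking-Piret constants for one series.

    ``series`` is 'glucose', 'nitrogen', 'phosphorous' (substrate-depletion
    coefficients, returned under keys alpha/beta as printed) or 'rhamnolipid'
    (the product-formation pair).
    """
    table = load_tables()["batch_constants"]
    try:
        return dict(table[series])
    except KeyError:
        raise KeyError(
            f"unknown series {series!r}; expected one of {sorted(table)}"
        ) from None


def reference_endpoints(strategy: str, substrate: str) -> ReferenceEndpoints:
    """Fed-batch constants / 48-h endpoints for one (strategy, substrate)."""
    table = load_tables()["fedbatch_constants"]
    try:
        row = table[strategy][substrate]
    except KeyError:
        raise KeyError(
            f"no fixture column for strategy={strategy!r}, substrate={substrate!r}"
        ) from None
    return ReferenceEndpoints(strategy=strategy, substrate=substrate, **row)


def model_parameters(strategy: str, substrate: str) -> dict:
    """Kinetic model parameters (growth, product, substrate, yields) as printed."""
    table = load_tables()["model_parameters"]
    try:
        return dict(table[strategy][substrate])
    except KeyError:
        raise KeyError(
            f"no model-parameter block for strategy={strategy!r}, "
            f"substrate={substrate!r}"
        ) from None


def medium_concentration(substrate: str) -> float:
    """Default initial concentration (g/l) from the culture medium recipe."""
    return float(load_tables()["medium_g_l"][substrate])


def signed_magnitude(value: float) -> tuple[float, int]:
    """Split a printed coefficient into (|value|, sign in {-1, 0, +1}).

    The published yield coefficients are printed negative (substrate is
    consumed); the model works with consumption-positive magnitudes.
    """
    sign = (value > 0) - (value < 0)
    return abs(value), sign
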