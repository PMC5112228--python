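import numpy as np
import pytest

from rhamnopt import (
    BatchKineticParams,
    FedBatchState,
    GrowthLaw,
)

GRID = np.arange(0.0, 48.0 + 1e-9, 4.0)


@pytest.fixture
def growth_params() -> BatchKineticParams:
    """Published growth constants with the rhamnolipid product pair."""
    return BatchKineticParams(
        mu_max=0.13, x0=0.1, xm=3.04, alpha=0.3091, beta=-0.000009
    )


@pytest.fixture
def full_params() -> BatchKineticParams:
    """Growth + product + glucose depletion constants in one set."""
    return BatchKineticParams(
        mu_max=0.13, x0=0.1, xm=3.04, alpha=0.3091, beta=-0.000009,
        gamma=0.6111, eta=0.0002, s0=10.0,
    )


@pytest.fixture
def batch_init() -> FedBatchState:
    return FedBatchState(V=1.0, X=0.1, S={"glucose": 10.0})


@pytest.fixture
def logistic_growth() -> GrowthLaw:
    return GrowthLaw(mu_max=0.13, xm=3.04)
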