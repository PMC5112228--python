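"""Small exactly-solvable optimization problems for validating the searchers.

The main instance is a discretized toy feed problem: one glucose stream,
three 16-h control intervals, five admissible feed levels per interval —
125 candidate profiles in total, few enough to enumerate exhaustively so
the global optimum is known with certainty. Growth is substrate-limited
with substrate inhibition (mu = mu_max S/(Ks + S + S^2/Ki)), which makes
the optimum an interior feeding policy: too little feed starves the
culture, too much inhibits growth and dilutes the product.

Searchers operate on the continuous box; the objective snaps a candidate to
the nearest admissible level per coordinate before simulation, and distinct
level combinations are memoized so repeated evaluations cost a lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .fedbatch import FedBatchState, FeedProfile, GrowthLaw, simulate_fedbatch
from .kinetics import BatchKineticParams

__all__ = ["ToyFeedProblem", "toy_feed_problem", "two_basin_objective"]


@dataclass
class ToyFeedProblem:
    """A 3-interval, 5-level discretized feed-optimization instance."""

    levels: np.ndarray
    bounds: tuple[float, float]
    n_var: int
    objective: Callable[[np.ndarray], float]
    _table: dict[tuple[int, ...], float] = field(default_factory=dict)

    def snap(self, x: np.ndarray) -> tuple[int, ...]:
        return tuple(int(np.argmin(np.abs(self.levels - xi))) for xi in x)

    def enumerate_all(self) -> dict[tuple[int, ...], float]:
        """Objective value of every candidate (the brute-force oracle)."""
        for idx in itertools.product(range(self.levels.size), repeat=self.n_var):
            self.objective(self.levels[list(idx)])
        return dict(self._table)

    def global_optimum(self) -> tuple[tuple[int, ...], float]:
        table = self.enumerate_all()
        best = max(table, key=table.get)
        return best, table[best]


def toy_feed_problem(
    *, n_levels: int = 5, n_var: int = 3, sim_rtol: float = 1e-8
) -> ToyFeedProblem:
    """Build the standard 125-candidate instance.

    48-h horizon split into ``n_var`` equal control intervals; glucose fed
    at one of ``n_levels`` levels in [0, 0.06] l/h from a 10 g/l stream into
    a starved (0.3 g/l glucose) 1-l culture under inhibited Monod growth.
    The objective is the 48-h product concentration.
    """
    init = FedBatchState(V=1.0, X=0.1, S={"glucose": 0.3})
    growth = GrowthLaw(
        mu_max=0.5, kind="substrate_limited", Ks=0.387, Ki=0.5, Si=0.0
    )
    params = BatchKineticParams(
        mu_max=0.5, x0=0.1, xm=3.04, alpha=0.3091, beta=0.002
    )
    substrate_coeffs = {"glucose": (0.6111, 0.0002)}
    bounds = (0.0, 0.06)
    levels = np.linspace(*bounds, n_levels)
    reps = int(round(48.0 / 4.0 / n_var))
    problem = ToyFeedProblem(
        levels=levels, bounds=bounds, n_var=n_var, objective=None
    )

    def objective(x: np.ndarray) -> float:
        idx = problem.snap(np.asarray(x, dtype=float))
        if idx not in problem._table:
            profile = FeedProfile(
                kind="piecewise_constant",
                rates={"glucose": np.repeat(levels[list(idx)], reps)},
                feed_concentrations={"glucose": 10.0},
            )
            tc = simulate_fedbatch(
                init, growth, params, profile,
                substrate_coeffs=substrate_coeffs,
                rtol=sim_rtol, atol=1e-10,
            )
            problem._table[idx] = float(tc.product[-1])
        return problem._table[idx]

    problem.objective = objective
    return problem


def two_basin_objective(x: np.ndarray) -> float:
    """1-D bimodal test function on [-1, 1]: global basin at +0.5 (value 1),
    inferior basin at -0.5 (value 0.6)."""
    x = float(np.asarray(x).ravel()[0])
    return 1.0 * np.exp(-((x - 0.5) ** 2) / 0.02) + 0.6 * np.exp(
        -((x + 0.5) ** 2) / 0.02
    )
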