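"""Tabu search over continuous feed-rate profiles.

A recency-based tabu list (FIFO, fixed length L) forbids revisiting recently
seen solutions, an aspiration criterion overrides tabu status on strict
improvement over the incumbent best, and the neighbourhood radius shrinks
over iterations following a sigmoid schedule

    S(k) = 1 / (1 + exp(n (k/m - k_center))),

equal to 0.5 at the k_center fraction of the run: coarse global moves early,
fine local moves late. Because the search space is continuous, "the same
solution" means within ``tabu_radius`` in the max-norm. An optional
frequency-based second list penalizes often-visited regions; it is off by
default since only the recency list has well-defined semantics here.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .fedbatch import (
    FedBatchState,
    FeedProfile,
    GrowthLaw,
    simulate_fedbatch,
)
from .kinetics import SUBSTRATES, BatchKineticParams, YieldSet

__all__ = [
    "TabuConfig",
    "Candidate",
    "OptimizationResult",
    "sigmoid_step",
    "generate_neighbors",
    "is_tabu",
    "update_tabu",
    "aspiration_override",
    "tabu_optimize",
    "optimize_feed_profiles",
    "FeedOptimizationReport",
]


@dataclass(frozen=True)
class TabuConfig:
    """Settings for :func:`tabu_optimize`.

    m: iterations; L: tabu-list length; n_neigh: neighbours per iteration;
    n_var: decision-vector length; n_sigmoid: sigmoid complexity coefficient
    (larger = sharper coarse-to-fine transition); k_center: fraction of the
    run at which the step scale is 0.5; tabu_radius: max-norm distance below
    which two solutions count as the same (default 1e-3 of the box width);
    restart: jump back to the best-so-far after ``stall_iterations`` without
    improvement. ``step_scale``, when set, fixes the neighbourhood radius at
    step_scale*(hi-lo) for the whole run instead of the sigmoid schedule
    (a fixed-step local walk).
    """

    n_var: int
    bounds: tuple[float, float]
    m: int = 100
    L: int = 10
    n_neigh: int = 20
    n_sigmoid: float = 10.0
    k_center: float = 0.5
    tabu_radius: float | None = None
    step_scale: float | None = None
    restart: bool = True
    stall_iterations: int | None = None
    use_frequency_list: bool = False
    frequency_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if self.m < 0 or self.L < 0 or self.n_var < 1:
            raise ValueError("m, L must be >= 0 and n_var >= 1")
        if self.m > 0 and self.n_neigh < 2:
            raise ValueError("need at least 2 neighbours per iteration")
        if not 0 < self.k_center < 1:
            raise ValueError("k_center must lie in (0, 1)")
        if not lo <= hi:
            raise ValueError(f"invalid bounds ({lo}, {hi})")

    @property
    def effective_tabu_radius(self) -> float:
        if self.tabu_radius is not None:
            return self.tabu_radius
        lo, hi = self.bounds
        return 1e-3 * (hi - lo)

    @property
    def effective_stall(self) -> int:
        if self.stall_iterations is not None:
            return self.stall_iterations
        return max(1, int(0.2 * self.m))


@dataclass(frozen=True)
class Candidate:
    x: np.ndarray
    objective: float = math.nan
    feasible: bool = True


@dataclass
class OptimizationResult:
    best: Candidate
    history: list[float]
    n_evaluations: int
    n_failures: int
    seed: int
    config: object
    trajectory: list[np.ndarray] | None = None


def sigmoid_step(k: int, cfg: TabuConfig) -> float:
    """Neighbourhood scale S(k) in (0, 1); 0.5 exactly at k = k_center*m."""
    if cfg.m == 0:
        return 0.5
    return 1.0 / (1.0 + math.exp(cfg.n_sigmoid * (k / cfg.m - cfg.k_center)))


def generate_neighbors(
    current: Candidate, k: int, cfg: TabuConfig, rng: np.random.Generator
) -> list[Candidate]:
    """n_neigh uniform box perturbations of radius S(k)*(hi-lo), clipped."""
    lo, hi = cfg.bounds
    scale = cfg.step_scale if cfg.step_scale is not None else sigmoid_step(k, cfg)
    radius = scale * (hi - lo)
    steps = rng.uniform(-radius, radius, size=(cfg.n_neigh, cfg.n_var))
    return [
        Candidate(x=np.clip(current.x + step, lo, hi)) for step in steps
    ]


def is_tabu(
    x: np.ndarray, tabu_list: Sequence[np.ndarray], tabu_radius: float
) -> bool:
    """Within tabu_radius (max-norm, strict) of any stored solution."""
    return any(
        np.max(np.abs(x - stored)) < tabu_radius for stored in tabu_list
    )


def update_tabu(tabu_list: deque, x: np.ndarray) -> deque:
    """Append; deque's maxlen evicts the oldest entry beyond capacity L."""
    tabu_list.append(np.array(x, copy=True))
    return tabu_list


def aspiration_override(candidate: Candidate, best_so_far: Candidate) -> bool:
    """Tabu status may be superseded only on strict improvement on the best."""
    return candidate.objective > best_so_far.objective


def _evaluate(objective, cand: Candidate) -> Candidate:
    try:
        val = float(objective(cand.x))
    except Exception:
        return replace(cand, objective=-math.inf, feasible=False)
    if math.isnan(val):
        return replace(cand, objective=-math.inf, feasible=False)
    return replace(cand, objective=val, feasible=True)


def tabu_optimize(
    objective: Callable[[np.ndarray], float],
    cfg: TabuConfig,
    x0: np.ndarray | None = None,
) -> OptimizationResult:
    """Maximize ``objective`` over the box [lo, hi]^n_var.

    Loop: evaluate a random (or supplied) initial solution; each iteration
    draws n_neigh neighbours, drops tabu ones unless aspiration applies,
    moves to the best admissible neighbour, marks non-improving moves tabu,
    and restarts from the best-so-far after a stall. Fully reproducible
    from ``cfg.seed``; ``history`` records the best-so-far per iteration.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    if x0 is None:
        x0 = rng.uniform(lo, hi, size=cfg.n_var)
    else:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        if x0.size != cfg.n_var:
            raise ValueError("x0 length does not match n_var")

    current = _evaluate(objective, Candidate(x=x0))
    n_eval, n_fail = 1, (0 if current.feasible else 1)
    best = current
    history = [best.objective]
    trajectory = [np.array(current.x, copy=True)]
    tabu: deque = deque(maxlen=cfg.L)
    freq: list[np.ndarray] = []
    radius = cfg.effective_tabu_radius
    stall = 0

    for k in range(1, cfg.m + 1):
        neighbors = [
            _evaluate(objective, c)
            for c in generate_neighbors(current, k, cfg, rng)
        ]
        n_eval += len(neighbors)
        n_fail += sum(not c.feasible for c in neighbors)
        feasible = [c for c in neighbors if c.feasible]
        if not feasible:
            history.append(best.objective)
            continue
        admissible = [
            c for c in feasible
            if not is_tabu(c.x, tabu, radius) or aspiration_override(c, best)
        ]
        pool = admissible if admissible else feasible

        def _score(c: Candidate) -> float:
            if not cfg.use_frequency_list or not freq:
                return c.objective
            visits = sum(np.max(np.abs(c.x - f)) < radius for f in freq)
            return c.objective - cfg.frequency_penalty * visits

        nxt = max(pool, key=_score)
        if nxt.objective <= current.objective:
            # non-improving move: forbid revisiting it for L iterations
            update_tabu(tabu, nxt.x)
        current = nxt
        if cfg.use_frequency_list:
            freq.append(np.array(nxt.x, copy=True))
        if nxt.objective > best.objective:
            best = nxt
            stall = 0
        else:
            stall += 1
            if cfg.restart and stall >= cfg.effective_stall:
                current = best
                stall = 0
        history.append(best.objective)
        trajectory.append(np.array(current.x, copy=True))

    return OptimizationResult(
        best=best, history=history, n_evaluations=n_eval,
        n_failures=n_fail, seed=cfg.seed, config=cfg,
        trajectory=trajectory,
    )


@dataclass
class FeedOptimizationReport:
    """Per-substrate optimal profiles plus best-so-far ladder traces."""

    profiles: dict[str, FeedProfile]
    best_objectives: dict[str, float]
    ladder_best: dict[str, list[float]]
    histories: dict[str, list[float]]
    n_evaluations: int
    seed: int
    bounds: tuple[float, float]
    iteration_ladder: tuple[int, ...]


def optimize_feed_profiles(
    init: FedBatchState,
    growth: GrowthLaw,
    params: BatchKineticParams,
    *,
    feed_concentrations: dict[str, float],
    substrate_coeffs: dict[str, tuple[float, float]] | None = None,
    yields: YieldSet | None = None,
    product_coeffs: tuple[float, float] | None = None,
    substrates: Sequence[str] = SUBSTRATES,
    bounds: tuple[float, float] = (0.01, 0.06),
    dt_u: float = 4.0,
    t_final: float = 48.0,
    iteration_ladder: Sequence[int] = (5, 25, 50, 100),
    n_neigh: int = 20,
    L: int = 10,
    seed: int = 0,
    objective: str = "final_product",
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-9,
    joint: bool = False,
) -> FeedOptimizationReport:
    """Optimize piecewise-constant feed-rate profiles by tabu search.

    By default each substrate's 12-interval profile is optimized in its own
    run (the others unfed), climbing the iteration ladder with warm starts
    so the best objective is nondecreasing along the ladder; ``joint=True``
    instead optimizes all substrates' rates in a single 3x12-variable run.
    The objective is the 48-h product concentration (g/l), or volumetric
    productivity P*V/t_final with ``objective='productivity'``.
    """
    n_int = int(round(t_final / dt_u))
    groups = [tuple(substrates)] if joint else [(s,) for s in substrates]

    def make_objective(group: tuple[str, ...]):
        def f(x: np.ndarray) -> float:
            rates = {
                name: x[i * n_int:(i + 1) * n_int]
                for i, name in enumerate(group)
            }
            profile = FeedProfile(
                kind="piecewise_constant", rates=rates,
                feed_concentrations=feed_concentrations,
                dt_u=dt_u, t_final=t_final, bounds=bounds,
            )
            tc = simulate_fedbatch(
                init, growth, params, profile,
                yields=yields, substrate_coeffs=substrate_coeffs,
                product_coeffs=product_coeffs,
                rtol=sim_rtol, atol=sim_atol,
            )
            P = float(tc.product[-1])
            if objective == "productivity":
                return P * float(tc.volume[-1]) / t_final
            return P
        return f

    profiles: dict[str, FeedProfile] = {}
    best_obj: dict[str, float] = {}
    ladder_best: dict[str, list[float]] = {}
    histories: dict[str, list[float]] = {}
    total_evals = 0

    for gi, group in enumerate(groups):
        label = "+".join(group)
        f = make_objective(group)
        x_start = None
        stage_best: list[float] = []
        full_history: list[float] = []
        best_result = None
        for stage, m in enumerate(iteration_ladder):
            cfg = TabuConfig(
                n_var=n_int * len(group), bounds=bounds, m=m,
                L=L, n_neigh=n_neigh,
                seed=seed + 1000 * gi + stage,
            )
            res = tabu_optimize(f, cfg, x0=x_start)
            total_evals += res.n_evaluations
            x_start = res.best.x  # warm start: ladder best is nondecreasing
            stage_best.append(res.best.objective)
            full_history.extend(res.history)
            if best_result is None or res.best.objective > best_result.best.objective:
                best_result = res
        rates = {
            name: best_result.best.x[i * n_int:(i + 1) * n_int]
            for i, name in enumerate(group)
        }
        profiles[label] = FeedProfile(
            kind="piecewise_constant", rates=rates,
            feed_concentrations=feed_concentrations,
            dt_u=dt_u, t_final=t_final, bounds=bounds,
        )
        best_obj[label] = best_result.best.objective
        ladder_best[label] = stage_best
        histories[label] = full_history

    return FeedOptimizationReport(
        profiles=profiles, best_objectives=best_obj,
        ladder_best=ladder_best, histories=histories,
        n_evaluations=total_evals, seed=seed, bounds=bounds,
        iteration_ladder=tuple(iteration_ladder),
    )
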