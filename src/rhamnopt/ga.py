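"""Binary-coded genetic algorithm (comparison optimizer).

Each decision variable is coded on ``bits_per_gene`` bits mapped affinely
onto its bounds, so 4-bit coding resolves the range into 16 levels (one
level spans 1/16 of the search range; 5 bits give 1/32). Selection is
fitness-proportional roulette wheel, recombination is single-point
crossover at rate Pc, and mutation flips each bit independently at rate Pm.
Elitism (carrying the single best individual) is on by default so the
best-fitness history is nondecreasing and the plateau termination is
well behaved; it can be disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tabu import Candidate, OptimizationResult

__all__ = [
    "GAConfig",
    "encode",
    "decode",
    "encode_vector",
    "decode_vector",
    "roulette_select",
    "single_point_crossover",
    "mutate",
    "ga_optimize",
]


@dataclass(frozen=True)
class GAConfig:
    n_var: int
    bounds: tuple[float, float]
    pop_size: int = 30
    pc: float = 0.7
    pm: float = 0.08
    bits_per_gene: int = 4
    max_generations: int = 100
    plateau_generations: int | None = 30
    target_fitness: float | None = None
    elitism: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pc <= 1 and 0 <= self.pm <= 1):
            raise ValueError("Pc and Pm must lie in [0, 1]")
        if self.bits_per_gene < 1:
            raise ValueError("bits_per_gene must be >= 1")
        if self.pop_size < 2:
            raise ValueError("population size must be >= 2")
        lo, hi = self.bounds
        if not lo <= hi:
            raise ValueError(f"invalid bounds ({lo}, {hi})")


def encode(value: float, bounds: tuple[float, float], bits: int) -> np.ndarray:
    """Binary code (big-endian 0/1 array) of the nearest coding level."""
    lo, hi = bounds
    if not lo <= value <= hi:
        raise ValueError(f"value {value} outside bounds [{lo}, {hi}]")
    levels = 2**bits - 1
    frac = 0.0 if hi == lo else (value - lo) / (hi - lo)
    level = int(round(frac * levels))
    return np.array(
        [(level >> (bits - 1 - i)) & 1 for i in range(bits)], dtype=np.uint8
    )


def decode(bitstring: np.ndarray, bounds: tuple[float, float], bits: int) -> float:
    """Affine map of a big-endian code back onto [lo, hi]; endpoints exact."""
    bitstring = np.asarray(bitstring, dtype=np.uint8)
    if bitstring.size != bits:
        raise ValueError(f"expected {bits} bits, got {bitstring.size}")
    level = int(bitstring @ (1 << np.arange(bits - 1, -1, -1)))
    lo, hi = bounds
    return lo + level * (hi - lo) / (2**bits - 1)


def encode_vector(values: np.ndarray, bounds, bits: int) -> np.ndarray:
    return np.concatenate([encode(v, bounds, bits) for v in values])


def decode_vector(chromosome: np.ndarray, bounds, bits: int, n_var: int) -> np.ndarray:
    return np.array(
        [
            decode(chromosome[i * bits:(i + 1) * bits], bounds, bits)
            for i in range(n_var)
        ]
    )


def roulette_select(fitnesses: np.ndarray, rng: np.random.Generator) -> int:
    """Fitness-proportional selection; shifts nonpositive fitness landscapes.

    When any fitness is negative or all are zero, the wheel is built on
    f - min(f) + eps (the standard shift fallback; callers may flag it).
    """
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0) or f.sum() == 0:
        f = f - f.min() + 1e-12
    return int(rng.choice(f.size, p=f / f.sum()))


def single_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap suffixes after a cut point uniform on [1, len-1]."""
    if parent_a.size != parent_b.size:
        raise ValueError("parents must have equal length")
    cut = int(rng.integers(1, parent_a.size))
    child_a = np.concatenate([parent_a[:cut], parent_b[cut:]])
    child_b = np.concatenate([parent_b[:cut], parent_a[cut:]])
    return child_a, child_b


def mutate(bitstring: np.ndarray, pm: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability pm."""
    flips = rng.random(bitstring.size) < pm
    return np.bitwise_xor(bitstring, flips.astype(np.uint8))


def ga_optimize(objective, cfg: GAConfig) -> OptimizationResult:
    """Maximize ``objective`` on the box by the generational GA loop.

    selection -> crossover (rate Pc) -> mutation (rate Pm) -> evaluation,
    repeated until ``max_generations``, a fitness plateau of
    ``plateau_generations``, or ``target_fitness``. Reproducible from seed.
    """
    rng = np.random.default_rng(cfg.seed)
    bits, n_var = cfg.bits_per_gene, cfg.n_var
    chrom_len = bits * n_var

    def evaluate(pop: np.ndarray) -> np.ndarray:
        vals = np.empty(pop.shape[0])
        for i, chrom in enumerate(pop):
            try:
                vals[i] = float(
                    objective(decode_vector(chrom, cfg.bounds, bits, n_var))
                )
            except Exception:
                vals[i] = -math.inf
            if math.isnan(vals[i]):
                vals[i] = -math.inf
        return vals

    pop = rng.integers(0, 2, size=(cfg.pop_size, chrom_len), dtype=np.uint8)
    obj = evaluate(pop)
    n_eval = cfg.pop_size
    best_i = int(np.argmax(obj))
    best = Candidate(
        x=decode_vector(pop[best_i], cfg.bounds, bits, n_var),
        objective=float(obj[best_i]),
    )
    history = [best.objective]
    plateau = 0

    for _gen in range(cfg.max_generations):
        finite = np.isfinite(obj)
        fitness = np.where(finite, obj, (obj[finite].min() if finite.any() else 0.0))
        children = []
        if cfg.elitism:
            children.append(pop[int(np.argmax(obj))].copy())
        while len(children) < cfg.pop_size:
            ia = roulette_select(fitness, rng)
            ib = roulette_select(fitness, rng)
            a, b = pop[ia].copy(), pop[ib].copy()
            if rng.random() < cfg.pc:
                a, b = single_point_crossover(a, b, rng)
            children.append(mutate(a, cfg.pm, rng))
            if len(children) < cfg.pop_size:
                children.append(mutate(b, cfg.pm, rng))
        pop = np.array(children, dtype=np.uint8)
        obj = evaluate(pop)
        n_eval += cfg.pop_size
        gen_best = int(np.argmax(obj))
        if obj[gen_best] > best.objective:
            best = Candidate(
                x=decode_vector(pop[gen_best], cfg.bounds, bits, n_var),
                objective=float(obj[gen_best]),
            )
            plateau = 0
        else:
            plateau += 1
        history.append(best.objective)
        if cfg.target_fitness is not None and best.objective >= cfg.target_fitness:
            break
        if (
            cfg.plateau_generations is not None
            and plateau >= cfg.plateau_generations
        ):
            break

    return OptimizationResult(
        best=best, history=history, n_evaluations=n_eval,
        n_failures=int(np.sum(~np.isfinite(obj))), seed=cfg.seed, config=cfg,
    )
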