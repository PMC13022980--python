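"""Improved Whale Optimization (IWO) for bounded hyperparameter search.

Standard whale optimization explores a box-bounded search space with three
moves — encircling the current best, a log-spiral "bubble-net" approach, and
a random-whale exploration step.  The improved variant adds:

* tent-map chaotic initialization of the population;
* a nonlinear convergence factor ``a(t) = 2 - 2 (e^{(t/tmax)^m} - 1)/(e - 1)``
  replacing the linear 2 -> 0 decay;
* an oscillating inertia weight ``|cos(l t pi / tmax)|`` on the target term;
* a heavy-tailed Cauchy mutation of the best position, recombined
  coordinate-wise with each whale (binomial crossover);
* an optimal-based feedback move applied to the worst fraction of the
  population each iteration.

Setting ``mutation=False``, ``inertia="constant"`` and
``feedback_fraction=0`` reduces the update exactly to vanilla WOA, which is
exercised as a step-for-step oracle in the test suite.

Positions are real vectors; categorical and log-scaled dimensions are
handled by :class:`SearchSpace` through a continuous relaxation decoded at
evaluation time.  Fitness is minimized.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dimension", "SearchSpace", "Whale", "IWOConfig", "OptimizeResult",
    "tent_map_step", "chaotic_initialize", "convergence_factor",
    "inertia_weight", "cauchy_mutate", "update_position", "feedback_update",
    "optimize",
]


@dataclass(frozen=True)
class Dimension:
    """One axis of the search space.

    ``kind`` is ``continuous``, ``log`` (continuous on a log10 scale, bounds
    given in original units) or ``categorical`` (``menu`` holds the choices;
    internally relaxed to ``[0, len(menu))`` and decoded by floor).
    """

    name: str
    lower: float = 0.0
    upper: float = 1.0
    kind: str = "continuous"
    menu: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "log", "categorical"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.menu:
                raise ValueError(f"categorical dimension {self.name!r} needs "
                                 "a non-empty menu")
        else:
            # equality is allowed (degenerate dimension, pinned with warning)
            if self.lower > self.upper:
                raise ValueError(
                    f"dimension {self.name!r}: lower must be <= upper")
            if self.kind == "log" and self.lower <= 0:
                raise ValueError(f"log dimension {self.name!r} needs "
                                 "positive bounds")

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.kind == "categorical":
            return 0.0, float(len(self.menu))
        if self.kind == "log":
            return math.log10(self.lower), math.log10(self.upper)
        return float(self.lower), float(self.upper)

    def decode(self, value: float):
        if self.kind == "categorical":
            idx = min(int(value), len(self.menu) - 1)
            return self.menu[idx]
        if self.kind == "log":
            return 10.0 ** value
        return value


class SearchSpace:
    """Box-bounded space with per-dimension kinds and decoding."""

    def __init__(self, dimensions: list[Dimension]):
        if not dimensions:
            raise ValueError("search space needs at least one dimension")
        self.dimensions = list(dimensions)
        bounds = np.array([d.internal_bounds for d in dimensions])
        self.lb = bounds[:, 0]
        self.ub = bounds[:, 1]

    def __len__(self) -> int:
        return len(self.dimensions)

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lb, self.ub)

    def decode(self, position: np.ndarray) -> dict:
        return {d.name: d.decode(v)
                for d, v in zip(self.dimensions, position)}


@dataclass
class Whale:
    """One candidate: a position inside the box and its (lower-better) fitness."""

    position: np.ndarray
    fitness: float = math.inf


@dataclass(frozen=True)
class IWOConfig:
    """Optimizer settings.

    ``m`` shapes the convergence factor's curve; ``l_cycle`` the inertia
    oscillation; ``b`` the spiral pitch; ``cauchy_scale`` the mutation step
    as a fraction of each dimension's range; ``crossover_rate`` the
    per-coordinate probability of taking the mutated coordinate;
    ``feedback_fraction`` the share of worst whales passed through the
    optimal-based feedback move.  ``inertia`` selects the cosine schedule
    (default), the 0.9 -> 0.4 ``"linear"`` decay, or ``"constant"`` (1).
    """

    population: int = 20
    tmax: int = 50
    m: float = 0.5
    l_cycle: float = 1.0
    b: float = 1.0
    cauchy_scale: float = 0.1
    crossover_rate: float = 0.1
    feedback_threshold: float = 0.5
    feedback_fraction: float = 0.2
    mutation: bool = True
    force_mutation_index: bool = True
    inertia: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if not 0.1 <= self.cauchy_scale <= 1.0:
            raise ValueError("cauchy_scale must be in [0.1, 1.0]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if not 0.0 <= self.feedback_fraction <= 1.0:
            raise ValueError("feedback_fraction must be in [0, 1]")
        if self.inertia not in ("cosine", "linear", "constant"):
            raise ValueError("inertia must be cosine, linear or constant")


def tent_map_step(ch: float) -> float:
    """One step of the tent map with split point 0.7."""
    if not 0.0 <= ch <= 1.0:
        raise ValueError(f"tent map input must be in [0, 1], got {ch}")
    out = ch / 0.7 if ch < 0.7 else (1.0 - ch) / 0.3
    return min(1.0, max(0.0, out))  # guard float round-off at the break


_TENT_FIXED_POINTS = (0.0, 1.0 / 1.3)


def chaotic_initialize(space: SearchSpace, population: int,
                       rng: np.random.Generator) -> list[Whale]:
    """Tent-map chaotic population inside the box.

    One independent tent-map trajectory per dimension, started at a random
    non-fixed point (perturbed away from a fixed point if one is hit), mapped
    affinely onto ``[lb, ub]``.
    """
    if population < 2:
        raise ValueError("population must be >= 2")
    d = len(space)
    degenerate = space.ub - space.lb <= 0
    if degenerate.any():
        warnings.warn("search space has zero-width dimensions; whales are "
                      "pinned to the lower bound there")
    ch = rng.random(d)
    positions = np.empty((population, d))
    for p in range(population):
        for j in range(d):
            for fp in _TENT_FIXED_POINTS:
                if abs(ch[j] - fp) < 1e-12:
                    ch[j] = min(1.0, max(0.0, ch[j] + rng.uniform(0.01, 0.1)))
            positions[p, j] = ch[j]
            ch[j] = tent_map_step(ch[j])
    positions = space.lb + (space.ub - space.lb) * positions
    return [Whale(position=space.clip(pos)) for pos in positions]


def convergence_factor(t: int, tmax: int, m: float) -> float:
    """Nonlinear decay ``a(t)``: 2 at t=0, 0 at t=tmax, strictly decreasing."""
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    if not 0 <= t <= tmax:
        raise ValueError(f"iteration t={t} outside [0, {tmax}]")
    return 2.0 - 2.0 * (math.exp((t / tmax) ** m) - 1.0) / (math.e - 1.0)


def inertia_weight(t: int, tmax: int, l_cycle: float) -> float:
    """Oscillating weight ``|cos(l t pi / tmax)|`` in [0, 1]."""
    if tmax <= 0:
        raise ValueError("tmax must be positive")
    return abs(math.cos(l_cycle * t * math.pi / tmax))


def _linear_inertia(t: int, tmax: int) -> float:
    return 0.9 - (0.9 - 0.4) * t / tmax


def _inertia(t: int, tmax: int, cfg: IWOConfig) -> float:
    if cfg.inertia == "constant":
        return 1.0
    if cfg.inertia == "linear":
        return _linear_inertia(t, tmax)
    return inertia_weight(t, tmax, cfg.l_cycle)


def cauchy_mutate(best: np.ndarray, current: np.ndarray, space: SearchSpace,
                  cfg: IWOConfig, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed mutant of ``best``, recombined coordinate-wise.

    Each coordinate takes ``best + scale * range * Cauchy`` with probability
    ``crossover_rate``; one forced index per call (when enabled) guarantees
    at least one mutated coordinate.  The rest keep the current whale's
    value.  Result is clipped to the box.
    """
    d = len(best)
    jrand = int(rng.integers(d))
    take = rng.random(d) < cfg.crossover_rate
    if cfg.force_mutation_index:
        take[jrand] = True
    step = cfg.cauchy_scale * (space.ub - space.lb) * rng.standard_cauchy(d)
    mutant = np.where(take, best + step, current)
    return space.clip(mutant)


def update_position(whale: np.ndarray, best: np.ndarray,
                    rand_whale: np.ndarray, mutant: np.ndarray | None,
                    t: int, space: SearchSpace, cfg: IWOConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """One whale move: encircle, explore, or spiral, with inertia and mutant.

    ``mutant`` replaces the move's target vector (the Cauchy-mutated best);
    passing ``None`` uses the plain branch target, which together with
    constant inertia reproduces vanilla WOA exactly.  The random draws
    (p, r1, r2, spiral s) are consumed in a fixed order regardless of the
    branch taken, so runs are reproducible and streams can be shared with a
    reference implementation.
    """
    a = convergence_factor(t, cfg.tmax, cfg.m)
    wt = _inertia(t, cfg.tmax, cfg)
    p = rng.random()
    r1 = rng.random(len(whale))
    r2 = rng.random(len(whale))
    s = rng.uniform(-1.0, 1.0)
    avec = 2.0 * a * r1 - a
    cvec = 2.0 * r2

    if p < 0.5:
        explore = np.abs(avec).mean() >= 1.0
        target = rand_whale if explore else best
        base = mutant if mutant is not None else target
        search = np.abs(cvec * target - whale)
        new = wt * base - avec * search
    else:
        base = mutant if mutant is not None else best
        dist = np.abs(base - whale)
        new = wt * base + dist * math.exp(cfg.b * s) * math.cos(2.0 * math.pi * s)
    return space.clip(new)


def feedback_update(rand_whale: np.ndarray, mutant: np.ndarray,
                    space: SearchSpace, cfg: IWOConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Optimal-based feedback: blend of a random whale and the mutant.

    With probability ``1 - feedback_threshold`` (pl <= threshold) the random
    whale is returned unchanged.
    """
    lam = rng.random()
    pl = rng.random()
    c = rng.uniform(-1.0, 1.0)
    if pl <= cfg.feedback_threshold:
        return rand_whale.copy()
    new = lam * rand_whale + (1.0 - lam) * mutant + c * (rand_whale - mutant)
    return space.clip(new)


@dataclass
class OptimizeResult:
    """Outcome of one IWO run."""

    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    n_evaluations: int
    best_decoded: dict = field(default_factory=dict)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": range(len(self.history)),
                             "best_fitness": self.history})


def _evaluate(objective, position: np.ndarray) -> float:
    value = float(objective(position))
    if math.isnan(value):
        warnings.warn("objective returned NaN; treating as +inf")
        return math.inf
    return value


def optimize(objective, space: SearchSpace, cfg: IWOConfig,
             callback=None) -> OptimizeResult:
    """Minimize ``objective`` over the box with IWO.

    Exactly ``population * (tmax + 1)`` objective evaluations (initial sweep
    plus one per whale per iteration).  The returned history (best-so-far
    after init and after each iteration) is monotone non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = chaotic_initialize(space, cfg.population, rng)
    n_evals = 0
    for whale in pop:
        whale.fitness = _evaluate(objective, whale.position)
        n_evals += 1
    best = min(pop, key=lambda w: w.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    history = [best_fit]

    for t in range(1, cfg.tmax + 1):
        mutants = []
        for whale in pop:
            if cfg.mutation:
                mutants.append(cauchy_mutate(best_pos, whale.position,
                                             space, cfg, rng))
            else:
                mutants.append(None)
        new_positions = []
        for whale, mutant in zip(pop, mutants):
            rand_whale = pop[int(rng.integers(cfg.population))].position
            new_positions.append(update_position(
                whale.position, best_pos, rand_whale, mutant, t, space,
                cfg, rng))
        if cfg.feedback_fraction > 0.0:
            n_fb = int(round(cfg.feedback_fraction * cfg.population))
            worst = np.argsort([w.fitness for w in pop])[::-1][:n_fb]
            for i in worst:
                mutant = mutants[i] if mutants[i] is not None else best_pos
                new_positions[i] = feedback_update(
                    new_positions[i], mutant, space, cfg, rng)
        for whale, pos in zip(pop, new_positions):
            whale.position = pos
            whale.fitness = _evaluate(objective, pos)
            n_evals += 1
            if whale.fitness < best_fit:
                best_fit = whale.fitness
                best_pos = whale.position.copy()
        history.append(best_fit)
        if callback is not None:
            callback(t, best_pos, best_fit)

    return OptimizeResult(best_position=best_pos, best_fitness=best_fit,
                          history=history, n_evaluations=n_evals,
                          best_decoded=space.decode(best_pos))
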