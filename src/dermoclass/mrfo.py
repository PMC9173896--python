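"""Manta Ray Foraging Optimization (MRFO).

A population metaheuristic inspired by three feeding behaviours of
manta rays, used here to train the cascade-forward classifier by
minimizing its misclassification rate, but usable on any box-bounded
fitness function.

Per iteration t of T, each of the N agents x_i (D-dimensional, kept
inside the box [L, U] by clipping) takes one of two moves:

* chain foraging — agents queue behind the best-known position:
  ``x_1 <- x_1 + r (x_best - x_1) + alpha (x_best - x_1)`` and for i>=2
  ``x_i <- x_i + r (x_{i-1} - x_i) + alpha (x_best - x_i)`` with
  ``alpha = 2 r sqrt(|ln r1|)``;

* cyclone foraging — agents spiral around a reference point, which is
  the best position (exploitation) or a fresh uniform random point in
  the box (exploration, favoured early in the run):
  ``x_i <- ref + r (prev - x_i) + beta (ref - x_i)`` with
  ``beta = 2 exp(r1 (T - t + 1)/T) sin(2 pi r1)`` and prev = ref for
  i=1, the previous agent otherwise.

After every agent has moved and been evaluated, each performs a
somersault around the best position:
``x_i <- x_i + S (r2 x_best - r3 x_i)`` with somersault factor S = 2.

The best-ever position is tracked separately from the population
(elitism), so the reported best fitness is non-increasing.  All
randomness comes from one seeded generator, making runs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "MrfoConfig",
    "MrfoState",
    "chain_step",
    "cyclone_step",
    "somersault_step",
    "optimize",
    "error_rate_fitness",
]


@dataclass(frozen=True)
class MrfoConfig:
    population: int = 30
    max_iter: int = 100
    bounds: tuple[np.ndarray, np.ndarray] | tuple[float, float] = (-5.0, 5.0)
    dim: int | None = None  # required when bounds are scalars
    somersault_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.somersault_factor <= 0:
            raise ValueError("somersault_factor must be > 0")
        lo, hi = self.box()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be < upper bounds")

    def box(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.bounds
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
        if lo.size == 1 and hi.size == 1:
            d = self.dim if self.dim is not None else 1
            lo = np.full(d, lo[0])
            hi = np.full(d, hi[0])
        return lo, hi


@dataclass
class MrfoState:
    positions: np.ndarray  # N x D
    fitnesses: np.ndarray  # N
    best_position: np.ndarray  # D
    best_fitness: float
    iteration: int = 0
    lower: np.ndarray = None
    upper: np.ndarray = None


def _clip(x: np.ndarray, state: MrfoState) -> np.ndarray:
    if state.lower is None:
        return x
    return np.clip(x, state.lower, state.upper)


def chain_step(state: MrfoState, i: int, r: float, r1: float) -> np.ndarray:
    """Chain-foraging move for agent i (1-based); returns clipped position."""
    n = state.positions.shape[0]
    if not 1 <= i <= n:
        raise IndexError(f"agent index {i} out of range 1..{n}")
    alpha = 2.0 * r * np.sqrt(abs(np.log(r1)))
    x = state.positions[i - 1]
    best = state.best_position
    prev = best if i == 1 else state.positions[i - 2]
    new = x + r * (prev - x) + alpha * (best - x)
    return _clip(new, state)


def cyclone_step(
    state: MrfoState,
    i: int,
    r: float,
    r1: float,
    t: int,
    T: int,
    use_random_reference: bool = False,
) -> np.ndarray:
    """Cyclone-foraging move for agent i; reference is x_best or, for
    exploration, a fresh uniform point in the box."""
    n = state.positions.shape[0]
    if not 1 <= i <= n:
        raise IndexError(f"agent index {i} out of range 1..{n}")
    if t > T:
        raise ValueError("iteration t exceeds the maximum T")
    beta = 2.0 * np.exp(r1 * (T - t + 1) / T) * np.sin(2.0 * np.pi * r1)
    x = state.positions[i - 1]
    if use_random_reference:
        ref = state.lower + r * (state.upper - state.lower)
    else:
        ref = state.best_position
    prev = ref if i == 1 else state.positions[i - 2]
    new = ref + r * (prev - x) + beta * (ref - x)
    return _clip(new, state)


def somersault_step(state: MrfoState, i: int, r2: float, r3: float) -> np.ndarray:
    """Somersault around the best position: x + S (r2 x_best - r3 x)."""
    n = state.positions.shape[0]
    if not 1 <= i <= n:
        raise IndexError(f"agent index {i} out of range 1..{n}")
    s = getattr(state, "somersault_factor", 2.0)
    x = state.positions[i - 1]
    new = x + s * (r2 * state.best_position - r3 * x)
    return _clip(new, state)


def _evaluate(fitness: Callable, x: np.ndarray) -> float:
    val = float(fitness(x))
    if not np.isfinite(val):
        raise ValueError(f"non-finite fitness {val} at position {x}")
    return val


def optimize(
    fitness: Callable[[np.ndarray], float],
    config: MrfoConfig,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize a fitness function over the configured box.

    Returns (best_position, best_fitness, trace) where trace holds the
    best-ever fitness after each iteration.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.box()
    d = lo.size
    n = config.population
    T = config.max_iter

    positions = lo + rng.random((n, d)) * (hi - lo)
    fitnesses = np.array([_evaluate(fitness, p) for p in positions])
    best_idx = int(np.argmin(fitnesses))
    state = MrfoState(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[best_idx].copy(),
        best_fitness=float(fitnesses[best_idx]),
        lower=lo,
        upper=hi,
    )
    state.somersault_factor = config.somersault_factor

    trace: list[float] = []
    for t in range(1, T + 1):
        state.iteration = t
        for i in range(1, n + 1):
            r = rng.random()
            r1 = rng.random()
            if rng.random() < 0.5:
                explore = (t / T) < rng.random()
                new = cyclone_step(state, i, r, r1, t, T, use_random_reference=explore)
            else:
                new = chain_step(state, i, r, r1)
            state.positions[i - 1] = new
            state.fitnesses[i - 1] = _evaluate(fitness, new)
            if state.fitnesses[i - 1] < state.best_fitness:
                state.best_fitness = float(state.fitnesses[i - 1])
                state.best_position = new.copy()
        for i in range(1, n + 1):
            r2 = rng.random()
            r3 = rng.random()
            new = somersault_step(state, i, r2, r3)
            state.positions[i - 1] = new
            state.fitnesses[i - 1] = _evaluate(fitness, new)
            if state.fitnesses[i - 1] < state.best_fitness:
                state.best_fitness = float(state.fitnesses[i - 1])
                state.best_position = new.copy()
        trace.append(state.best_fitness)
    return state.best_position, state.best_fitness, trace


def error_rate_fitness(
    param_vector: np.ndarray, features: np.ndarray, labels, layout
) -> float:
    """Percent misclassified by the cascade net given a flat weight vector.

    This is the quantity MRFO minimizes when training the classifier:
    ``100 * misclassified / total``.
    """
    from .cascade import predict, unflatten

    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labeled feature set is empty")
    params = unflatten(param_vector, layout)
    pred = predict(params, features)
    return float(np.mean(pred != labels) * 100.0)
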