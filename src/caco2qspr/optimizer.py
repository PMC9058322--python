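"""Quantum-behaved particle swarm optimization (QPSO family).

One global optimizer serves three jobs in the pipeline: continuous
box-constrained search (outlier-filter thresholds, model hyperparameters)
and binary subset search (descriptor selection).

The core is canonical QPSO: each particle is drawn around a stochastic
attractor between its personal best and the global best, with a jump scaled
by the distance to the mean of all personal bests and a contraction-
expansion coefficient annealed from 1.0 to 0.5 over the run.  A hybrid
Levy-flight perturbation kicks the ``L`` worst particles each iteration to
escape local basins; ``lambda_param`` scales the Levy step.  Binary mode
maps the continuous state through a logistic transfer to per-bit selection
probabilities, then repairs oversized subsets by dropping the lowest-
priority members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


class EvaluationError(RuntimeError):
    """The fitness function returned a non-finite value."""


@dataclass
class OptimizerConfig:
    population_size: int = 30
    max_iterations: int = 2000
    lambda_param: float = 1.0
    L_param: int = 10
    bounds: Sequence[tuple[float, float]] = ()
    seed: int = 0
    mode: str = "continuous"  # or "binary"
    levy_enabled: bool = True
    patience: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi}): low must be < high")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0


def _levy_step(rng: np.random.Generator, size: int, alpha: float = 1.5) -> np.ndarray:
    # Mantegna's algorithm for symmetric alpha-stable steps
    from scipy.special import gamma

    sigma_u = (
        gamma(1 + alpha) * np.sin(np.pi * alpha / 2)
        / (gamma((1 + alpha) / 2) * alpha * 2 ** ((alpha - 1) / 2))
    ) ** (1 / alpha)
    u = rng.normal(0, sigma_u, size)
    v = rng.normal(0, 1, size)
    return u / np.abs(v) ** (1 / alpha)


def _check_fitness(value: float, position: np.ndarray) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise EvaluationError(f"non-finite fitness {value} at position {position.tolist()}")
    return value


def minimize(fitness: Callable[[np.ndarray], float], config: OptimizerConfig) -> OptimizationResult:
    """Minimize ``fitness`` over the box given by ``config.bounds``.

    Deterministic for identical (config, seed, fitness); positions are
    clamped to the bounds before every evaluation.
    """
    bounds = np.asarray(config.bounds, dtype=float)
    if bounds.size == 0:
        raise ValueError("continuous mode requires bounds")
    lo, hi = bounds[:, 0], bounds[:, 1]
    d = len(bounds)
    m = config.population_size
    rng = np.random.default_rng(config.seed)

    x = rng.uniform(lo, hi, size=(m, d))
    fit = np.array([_check_fitness(fitness(x[i]), x[i]) for i in range(m)])
    evaluations = m
    pbest, pfit = x.copy(), fit.copy()
    g = int(np.argmin(pfit))
    gbest, gfit = pbest[g].copy(), float(pfit[g])
    history = [gfit]
    stall = 0

    for it in range(config.max_iterations):
        beta = 1.0 - 0.5 * it / max(config.max_iterations - 1, 1)  # 1.0 -> 0.5
        mbest = pbest.mean(axis=0)
        phi = rng.uniform(size=(m, d))
        u = rng.uniform(size=(m, d))
        sign = np.where(rng.uniform(size=(m, d)) < 0.5, 1.0, -1.0)
        attractor = phi * pbest + (1 - phi) * gbest
        x = attractor + sign * beta * np.abs(mbest - x) * np.log(1.0 / u)

        if config.levy_enabled and config.L_param > 0:
            worst = np.argsort(pfit)[-min(config.L_param, m):]
            step = config.lambda_param * 0.01 * (hi - lo)
            for i in worst:
                x[i] = x[i] + step * _levy_step(rng, d)

        np.clip(x, lo, hi, out=x)
        fit = np.array([_check_fitness(fitness(x[i]), x[i]) for i in range(m)])
        evaluations += m

        improved = fit < pfit
        pbest[improved] = x[improved]
        pfit[improved] = fit[improved]
        g = int(np.argmin(pfit))
        if pfit[g] < gfit:
            gbest, gfit = pbest[g].copy(), float(pfit[g])
            stall = 0
        else:
            stall += 1
        history.append(gfit)
        if config.patience is not None and stall >= config.patience:
            break

    return OptimizationResult(
        best_position=gbest, best_fitness=gfit, history=history, evaluations=evaluations
    )


def _repair(bits: np.ndarray, max_selected: int, priority: np.ndarray) -> np.ndarray:
    """Drop lowest-priority selected bits until |set| <= max_selected."""
    selected = np.flatnonzero(bits)
    if selected.size <= max_selected:
        if selected.size == 0:
            # empty sets are infeasible for subset search: force best-priority item
            bits = bits.copy()
            bits[int(np.argmin(priority))] = 1
        return bits
    bits = bits.copy()
    order = selected[np.argsort(priority[selected], kind="stable")]  # best first
    bits[order[max_selected:]] = 0
    return bits


def binary_subset_search(
    fitness: Callable[[np.ndarray], float],
    n_items: int,
    max_selected: int,
    config: OptimizerConfig,
    priority: Sequence[float] | None = None,
) -> OptimizationResult:
    """Search over index subsets of size <= ``max_selected``.

    ``fitness`` receives a sorted integer index array.  Every evaluated
    candidate is feasible: oversized draws are repaired by removing the
    members with the worst ``priority`` (lower value = higher priority,
    default = index order).  Returns the best feasible set as an index array.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if not 1 <= max_selected <= n_items:
        raise ValueError("max_selected must be in [1, n_items]")
    prio = np.arange(n_items, dtype=float) if priority is None else np.asarray(priority, float)
    rng = np.random.default_rng(config.seed)
    m = config.population_size

    def sample_bits(state_row: np.ndarray) -> np.ndarray:
        prob = 1.0 / (1.0 + np.exp(-state_row))  # logistic transfer
        return (rng.uniform(size=n_items) < prob).astype(np.int8)

    def evaluate(bits: np.ndarray) -> float:
        idx = np.flatnonzero(bits)
        return _check_fitness(fitness(idx), idx.astype(float))

    state = rng.normal(0, 1, size=(m, n_items))
    bits = np.array([_repair(sample_bits(state[i]), max_selected, prio) for i in range(m)])
    fit = np.array([evaluate(bits[i]) for i in range(m)])
    evaluations = m
    pbest_state, pbest_bits, pfit = state.copy(), bits.copy(), fit.copy()
    g = int(np.argmin(pfit))
    gbest_state, gbest_bits, gfit = pbest_state[g].copy(), pbest_bits[g].copy(), float(pfit[g])
    history = [gfit]
    stall = 0

    for it in range(config.max_iterations):
        beta = 1.0 - 0.5 * it / max(config.max_iterations - 1, 1)
        mbest = pbest_state.mean(axis=0)
        phi = rng.uniform(size=(m, n_items))
        u = rng.uniform(size=(m, n_items))
        sign = np.where(rng.uniform(size=(m, n_items)) < 0.5, 1.0, -1.0)
        attractor = phi * pbest_state + (1 - phi) * gbest_state
        state = attractor + sign * beta * np.abs(mbest - state) * np.log(1.0 / u)
        if config.levy_enabled and config.L_param > 0:
            worst = np.argsort(pfit)[-min(config.L_param, m):]
            for i in worst:
                state[i] = state[i] + config.lambda_param * _levy_step(rng, n_items)
        np.clip(state, -6.0, 6.0, out=state)

        bits = np.array([_repair(sample_bits(state[i]), max_selected, prio) for i in range(m)])
        fit = np.array([evaluate(bits[i]) for i in range(m)])
        evaluations += m
        improved = fit < pfit
        pbest_state[improved] = state[improved]
        pbest_bits[improved] = bits[improved]
        pfit[improved] = fit[improved]
        g = int(np.argmin(pfit))
        if pfit[g] < gfit:
            gbest_state, gbest_bits, gfit = (
                pbest_state[g].copy(),
                pbest_bits[g].copy(),
                float(pfit[g]),
            )
            stall = 0
        else:
            stall += 1
        history.append(gfit)
        if config.patience is not None and stall >= config.patience:
            break

    return OptimizationResult(
        best_position=np.flatnonzero(gbest_bits),
        best_fitness=gfit,
        history=history,
        evaluations=evaluations,
    )
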