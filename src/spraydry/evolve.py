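"""Evolutionary hyperparameter optimization.

A steady-state tournament scheme: an initial population of hyperparameter
sets is sampled uniformly within bounds (log-uniformly for positive reals on
log bounds); each iteration draws a random tournament subset, takes its
fittest member, mutates one randomly chosen hyperparameter (log-uniform
factor in [0.5, 2] for positive reals, +-1 step for integers, clipped to
bounds), evaluates the mutant and lets it replace the population's current
worst member. The best-ever candidate is tracked separately, so the reported
fitness trajectory is monotone non-increasing.

Reference-scale budgets are population 200, tournament 40, 800 iterations;
desk-scale defaults elsewhere in the package shrink these.

Fitness evaluations for hyperparameter search are leave-one-API-out CV RMSE
(see :func:`evolve_hyperparameters`), cached by spec hash — CV is the
runtime bottleneck and mutants frequently revisit earlier candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modeling import DEFAULT_BOUNDS, ModelSpec, cv_score, encode_folds

__all__ = ["EvolutionResult", "evolve", "evolve_hyperparameters"]


@dataclass
class EvolutionResult:
    best_params: dict
    best_fitness: float
    history: list[float]  # best-ever fitness after each iteration
    evaluations: int


def _sample(bounds: dict[str, tuple], rng: np.random.Generator) -> dict:
    params = {}
    for name, (kind, lo, hi) in bounds.items():
        if kind == "int":
            params[name] = int(rng.integers(lo, hi + 1))
        elif kind == "log":
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def _mutate(params: dict, bounds: dict[str, tuple], rng: np.random.Generator) -> dict:
    out = dict(params)
    name = list(bounds)[rng.integers(len(bounds))]
    kind, lo, hi = bounds[name]
    if kind == "int":
        step = 1 if rng.random() < 0.5 else -1
        out[name] = int(np.clip(out[name] + step, lo, hi))
    else:
        factor = np.exp(rng.uniform(np.log(0.5), np.log(2.0)))
        if kind == "log" or lo > 0:
            value = out[name] * factor
        else:  # bounds admitting non-positive values: additive kick instead
            value = out[name] + (factor - 1.0) * (hi - lo) / 2.0
        out[name] = float(np.clip(value, lo, hi))
    return out


def evolve(
    objective,
    bounds: dict[str, tuple],
    population: int = 200,
    tournament: int = 40,
    iterations: int = 800,
    seed: int = 0,
) -> EvolutionResult:
    """Minimize ``objective(params) -> float`` within ``bounds``.

    Fully reproducible under ``seed``; no candidate outside bounds is ever
    evaluated (mutations are clipped).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if population < 2:
        raise ValueError("population must be >= 2")
    rng = np.random.default_rng(seed)
    pop = [_sample(bounds, rng) for _ in range(population)]
    fitness = [float(objective(p)) for p in pop]
    evaluations = population
    best_i = int(np.argmin(fitness))
    best_params, best_fitness = dict(pop[best_i]), fitness[best_i]
    history = []
    for _ in range(iterations):
        idx = rng.choice(population, size=min(tournament, population), replace=False)
        champion = min(idx, key=lambda i: fitness[i])
        mutant = _mutate(pop[champion], bounds, rng)
        f = float(objective(mutant))
        evaluations += 1
        worst = int(np.argmax(fitness))
        pop[worst], fitness[worst] = mutant, f
        if f < best_fitness:
            best_params, best_fitness = dict(mutant), f
        history.append(best_fitness)
    return EvolutionResult(best_params, best_fitness, history, evaluations)


def evolve_hyperparameters(
    family: str,
    train: pd.DataFrame,
    population: int = 200,
    tournament: int = 40,
    iterations: int = 800,
    seed: int = 0,
    encoder=None,
    bounds: dict[str, tuple] | None = None,
) -> tuple[ModelSpec, EvolutionResult]:
    """Search a family's hyperparameters by LOGO-CV RMSE on ``train``."""
    bounds = bounds or DEFAULT_BOUNDS[family]
    cache: dict[str, float] = {}
    folds = encode_folds(train, encoder)  # fold encodings are spec-independent

    def objective(params: dict) -> float:
        spec = ModelSpec(family, params)
        key = spec.key()
        if key not in cache:
            cache[key] = cv_score(spec, folds=folds, seed=seed).mean_rmse
        return cache[key]

    result = evolve(
        objective, bounds, population=population, tournament=tournament,
        iterations=iterations, seed=seed,
    )
    return ModelSpec(family, result.best_params), result
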