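"""Standard continuous test functions and a random-search baseline.

All functions are written in maximization form (negated classics), matching
the optimizer's canonical direction; the global maximum of each is 0.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .optimizer import SearchSpace, StrategyParams, run

__all__ = ["sphere", "rastrigin", "rosenbrock", "BENCHMARKS", "random_search", "benchmark_run"]


def sphere(x: np.ndarray) -> float:
    return -float(np.sum(np.asarray(x) ** 2))


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x)
    return -float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x)
    return -float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


BENCHMARKS: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": sphere,
    "rastrigin": rastrigin,
    "rosenbrock": rosenbrock,
}


def random_search(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    budget: int,
    seed: int,
) -> tuple[np.ndarray, float]:
    """Best of `budget` i.i.d. uniform draws; the no-structure baseline."""
    rng = np.random.default_rng(seed)
    points = space.sample(rng, budget)
    values = np.array([objective(p) for p in points])
    k = int(np.argmax(values))
    return points[k], float(values[k])


def benchmark_run(
    function: str,
    dim: int,
    pop: int,
    iters: int,
    seed: int,
    lower: float = -0.5,
    upper: float = 0.5,
) -> dict:
    """One seeded optimizer run vs. a random search at equal evaluation budget."""
    objective = BENCHMARKS[function]
    space = SearchSpace.cube(dim, lower, upper)
    n_evals = {"count": 0}

    def counted(x: np.ndarray) -> float:
        n_evals["count"] += 1
        return objective(x)

    params = StrategyParams(maxg=iters, seed=seed)
    best_x, best_f, history = run(counted, space, pop, iters, params)
    _, rs_best = random_search(objective, space, n_evals["count"], seed)
    return {
        "function": function,
        "dim": dim,
        "pop": pop,
        "iters": iters,
        "seed": seed,
        "evaluations": n_evals["count"],
        "best_fitness": best_f,
        "random_search_best": rs_best,
        "best_position": [float(v) for v in best_x],
        "history": history,
    }
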