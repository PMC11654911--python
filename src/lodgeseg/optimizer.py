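"""Population metaheuristic with adaptive oscillation, guidance, and mutation.

This module implements a box-bounded continuous maximizer in the AFOA family
(aptenodytes forsteri optimization, a penguin-huddling-inspired swarm method)
with the APOM modifications: an oscillation adaptive perturbation strategy that
probes symmetrically around the incumbent best (strategy I), a simplified
differential move around the best driven by the memory difference of two random
individuals (strategy II), a globalized velocity move toward a random individual
and the mover's own memory (strategy III), a random-reset mutation, and an
adaptive probability that shifts the mix from exploration (II) early to
exploitation (I/III/mutation) late.

The canonical direction is maximization; minimize by negating the objective.
All randomness flows through one ``numpy.random.Generator`` per run, with draws
consumed in population order, so a (seed, config) pair determines the full
history.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "Individual",
    "PerturbationTerms",
    "GuidanceCoefficients",
    "StrategyParams",
    "OptimizerState",
    "Strategy",
    "ObjectiveEvaluationError",
    "init_population",
    "compute_perturbation",
    "strategy_one",
    "guidance_coefficient",
    "strategy_two",
    "strategy_three",
    "mutate",
    "selection_probability",
    "select_strategy",
    "step",
    "run",
]

Objective = Callable[[np.ndarray], Any]


class ObjectiveEvaluationError(RuntimeError):
    """Raised when the objective returns a non-finite value."""


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded continuous search domain [lower, upper]^dim."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 1 or upper.shape != lower.shape or lower.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal, positive length")
        if not np.all(lower < upper):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @classmethod
    def cube(cls, dim: int, lower: float = -0.5, upper: float = 0.5) -> "SearchSpace":
        return cls(np.full(dim, lower), np.full(dim, upper))

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray:
        size = self.dim if n is None else (n, self.dim)
        return rng.uniform(self.lower, self.upper, size=size)


@dataclass
class Individual:
    """A candidate solution with velocity and elitist personal memory."""

    position: np.ndarray
    velocity: np.ndarray
    memory_position: np.ndarray
    memory_fitness: float
    fitness: float
    record: Any = None          # raw objective payload for the current position
    memory_record: Any = None   # payload at the personal best

    def remember_if_better(self) -> None:
        if self.fitness > self.memory_fitness:
            self.memory_fitness = self.fitness
            self.memory_position = self.position.copy()
            self.memory_record = self.record


@dataclass(frozen=True)
class PerturbationTerms:
    """Oscillation step of strategy I: adaptive amount, step, perturbation."""

    lam: np.ndarray
    v: np.ndarray
    beta: np.ndarray
    q: int


@dataclass(frozen=True)
class GuidanceCoefficients:
    """Distance-damped attraction coefficient a = exp(-d / (2 * dim^0.8))."""

    a: float
    d: float
    dim: int


@dataclass(frozen=True)
class StrategyParams:
    """Knobs of the adaptive selection rule and mutation.

    base_prob is the floor of the selection probability Pr; exponent_g shapes
    its growth (Pr = min(1, base_prob + (ti/maxg)^(2*g))); mutation_one_prob is
    the per-dimension reset probability of the mutation mask.
    """

    maxg: int
    seed: int = 0
    base_prob: float = 0.3
    exponent_g: float = 1.0
    mutation_one_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.maxg < 0:
            raise ValueError("maxg must be nonnegative")
        if not 0.0 < self.base_prob < 1.0:
            raise ValueError("base_prob must lie in (0, 1)")
        if not 0.0 <= self.mutation_one_prob <= 1.0:
            raise ValueError("mutation_one_prob must lie in [0, 1]")


class Strategy(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    MUTATE = "MUTATE"


@dataclass
class OptimizerState:
    population: list[Individual]
    global_best: Individual
    iteration: int
    history: list[dict]
    rng: np.random.Generator
    n_evals: int = 0


def _call_objective(objective: Objective, x: np.ndarray, who: str) -> tuple[float, Any]:
    out = objective(x)
    if isinstance(out, tuple):
        fit, record = float(out[0]), out[1]
    else:
        fit, record = float(out), None
    if not math.isfinite(fit):
        raise ObjectiveEvaluationError(f"objective returned non-finite value {fit!r} for {who}")
    return fit, record


def init_population(
    space: SearchSpace, n: int, objective: Objective, params: StrategyParams
) -> OptimizerState:
    """Uniform random population; velocities zero; memory = own position."""
    if n < 2:
        raise ValueError("population size must be at least 2")
    rng = np.random.default_rng(params.seed)
    population: list[Individual] = []
    for i in range(n):
        pos = space.sample(rng)
        fit, record = _call_objective(objective, pos, f"individual {i}")
        population.append(
            Individual(
                position=pos,
                velocity=np.zeros(space.dim),
                memory_position=pos.copy(),
                memory_fitness=fit,
                fitness=fit,
                record=record,
                memory_record=record,
            )
        )
    best = max(population, key=lambda ind: ind.fitness)
    state = OptimizerState(
        population=population,
        global_best=copy.deepcopy(best),
        iteration=0,
        history=[],
        rng=rng,
        n_evals=n,
    )
    return state


def compute_perturbation(
    t: int, space: SearchSpace, params: StrategyParams, rng: np.random.Generator
) -> PerturbationTerms:
    """Oscillation terms for iteration t (1-based, t <= maxg).

    lam_d = exp(-0.25 * Ub_d * (t - 0.3*maxg) / maxg) * r_d with r_d ~ U(0,1):
    above 1 early (wide probing), shrinking late.  v is the oscillation step,
    beta an occasional extra kick gated by the fair coin q.
    """
    if not 1 <= t <= params.maxg:
        raise ValueError(f"iteration t={t} outside [1, {params.maxg}]")
    r = rng.random(space.dim)
    lam = np.exp(-0.25 * space.upper * (t - 0.3 * params.maxg) / params.maxg) * r
    v = lam**0.8 * (lam / 4.0) * space.width
    q = int(rng.random() >= 0.5)
    beta = space.upper * q * lam
    return PerturbationTerms(lam=lam, v=v, beta=beta, q=q)


def _probe_pair(
    state: OptimizerState,
    objective: Objective,
    space: SearchSpace,
    params: StrategyParams,
    t: int,
) -> tuple[np.ndarray, float, Any]:
    """Strategy I core: evaluate X_b +/- (v+beta), return the better probe."""
    per = compute_perturbation(t, space, params, state.rng)
    delta = per.v + per.beta
    base = state.global_best.position
    plus = space.clip(base + delta)
    minus = space.clip(base - delta)
    fit_p, rec_p = _call_objective(objective, plus, "strategy-I +probe")
    fit_m, rec_m = _call_objective(objective, minus, "strategy-I -probe")
    state.n_evals += 2
    if fit_p >= fit_m:
        return plus, fit_p, rec_p
    return minus, fit_m, rec_m


def strategy_one(
    state: OptimizerState,
    objective: Objective,
    space: SearchSpace,
    params: StrategyParams,
) -> Individual:
    """Two-probe oscillation search around the archived best.

    The better probe becomes the working best; the elitist archive keeps the
    previous incumbent when both probes are worse.  Returns the archive best.
    """
    pos, fit, rec = _probe_pair(state, objective, space, params, max(state.iteration, 1))
    if fit > state.global_best.fitness:
        state.global_best = Individual(
            position=pos.copy(),
            velocity=np.zeros(space.dim),
            memory_position=pos.copy(),
            memory_fitness=fit,
            fitness=fit,
            record=rec,
            memory_record=rec,
        )
    return state.global_best


def guidance_coefficient(p: np.ndarray, q: np.ndarray, dim: int) -> GuidanceCoefficients:
    """a = exp(-d / (2 * dim^0.8)) with d the Euclidean distance of p and q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (dim,) or q.shape != (dim,):
        raise ValueError(f"expected two vectors of length {dim}, got {p.shape} and {q.shape}")
    d = float(np.linalg.norm(p - q))
    a = math.exp(-d / (2.0 * dim**0.8))
    return GuidanceCoefficients(a=a, d=d, dim=dim)


def strategy_two(
    i: int, state: OptimizerState, space: SearchSpace, rng: np.random.Generator
) -> np.ndarray:
    """Differential move around the best, scaled by memory-distance guidance.

    When the two sampled memories coincide the population has contracted, and
    the move falls back to a fixed-width random probe around the best.
    """
    n = len(state.population)
    if n < 2:
        raise ValueError("strategy II needs a population of at least 2")
    r1, r2 = rng.choice(n, size=2, replace=False)
    xm1 = state.population[r1].memory_position
    xm2 = state.population[r2].memory_position
    base = state.global_best.position
    draw = rng.random(space.dim)
    if np.array_equal(xm1, xm2):
        new = base + 0.25 * draw * space.width
    else:
        a = guidance_coefficient(xm1, xm2, space.dim).a
        new = base + a * draw * (xm1 - xm2)
    return space.clip(new)


def strategy_three(
    i: int, state: OptimizerState, space: SearchSpace, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity move toward a random individual and the mover's own memory."""
    n = len(state.population)
    if n < 2:
        raise ValueError("strategy III needs a population of at least 2")
    choices = [j for j in range(n) if j != i]
    r = choices[rng.integers(len(choices))]
    ind = state.population[i]
    other = state.population[r]
    a1 = guidance_coefficient(other.position, ind.position, space.dim).a
    a2 = guidance_coefficient(ind.memory_position, ind.position, space.dim).a
    velocity = (
        rng.random(space.dim) * ind.velocity
        + a1 * rng.random(space.dim) * (other.position - ind.position)
        + a2 * rng.random(space.dim) * (ind.memory_position - ind.position)
    )
    new = space.clip(ind.position + velocity)
    return new, velocity


def mutate(
    position: np.ndarray,
    space: SearchSpace,
    params: StrategyParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw a Bernoulli(mutation_one_prob) subset of coordinates uniformly.

    Coordinates whose mask is 0 are carried over bit-exactly, so the offspring
    inherits part of its parent while regaining diversity elsewhere.
    """
    position = np.asarray(position, dtype=float)
    mask = rng.random(space.dim) < params.mutation_one_prob
    fresh = space.sample(rng)
    return np.where(mask, fresh, position)


def selection_probability(ti: int, params: StrategyParams) -> float:
    """Pr = min(1, base_prob + (ti/maxg)^(2g)), non-decreasing in ti."""
    if params.maxg == 0:
        raise ValueError("maxg must be positive to evaluate the selection probability")
    if not 0 <= ti <= params.maxg:
        raise ValueError(f"ti={ti} outside [0, {params.maxg}]")
    return min(1.0, params.base_prob + (ti / params.maxg) ** (2.0 * params.exponent_g))


def select_strategy(ti: int, params: StrategyParams, rng: np.random.Generator) -> Strategy:
    """Dispatch: II with probability 1 - Pr(ti); otherwise I/III/MUTATE uniformly.

    Early on Pr is near its floor so the exploratory strategy II dominates;
    late Pr saturates at 1 and the exploitation moves take over.
    """
    pr = selection_probability(ti, params)
    if rng.random() >= pr:
        return Strategy.II
    u = rng.random()
    if u < 1.0 / 3.0:
        return Strategy.I
    if u < 2.0 / 3.0:
        return Strategy.III
    return Strategy.MUTATE


def step(
    state: OptimizerState,
    objective: Objective,
    space: SearchSpace,
    params: StrategyParams,
) -> OptimizerState:
    """Advance one iteration: each individual performs one dispatched move."""
    t = state.iteration + 1
    counts = {s.value: 0 for s in Strategy}
    for i, ind in enumerate(state.population):
        strat = select_strategy(state.iteration, params, state.rng)
        counts[strat.value] += 1
        if strat is Strategy.I:
            pos, fit, rec = _probe_pair(state, objective, space, params, t)
            ind.position, ind.fitness, ind.record = pos, fit, rec
        else:
            if strat is Strategy.II:
                pos = strategy_two(i, state, space, state.rng)
            elif strat is Strategy.III:
                pos, vel = strategy_three(i, state, space, state.rng)
                ind.velocity = vel
            else:
                pos = mutate(ind.position, space, params, state.rng)
            fit, rec = _call_objective(objective, pos, f"individual {i} at iteration {t}")
            state.n_evals += 1
            ind.position, ind.fitness, ind.record = pos, fit, rec
        ind.remember_if_better()
        if ind.fitness > state.global_best.fitness:
            state.global_best = copy.deepcopy(ind)
    state.iteration = t
    state.history.append(
        {
            "iteration": t,
            "best_fitness": float(state.global_best.fitness),
            "strategy_counts": counts,
        }
    )
    return state


def run(
    objective: Objective,
    space: SearchSpace,
    n: int,
    maxg: int,
    params: StrategyParams | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, float, list[dict]]:
    """Initialize and iterate maxg steps; return the elitist best and history."""
    if params is None:
        params = StrategyParams(maxg=maxg, seed=0 if seed is None else seed)
    elif params.maxg != maxg:
        raise ValueError("params.maxg must agree with the maxg argument")
    state = init_population(space, n, objective, params)
    for _ in range(maxg):
        step(state, objective, space, params)
    best = state.global_best
    return best.position.copy(), float(best.fitness), state.history
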