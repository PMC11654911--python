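"""Unit and property tests for the swarm optimizer primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodgeseg import optimizer as opt
from lodgeseg.benchmarks import sphere


class FakeRng:
    """Deterministic stand-in exposing the Generator methods the moves use."""

    def __init__(self, uniform=1.0, scalar=0.0, pair=(0, 1), integer=0):
        self.uniform = uniform
        self.scalar = scalar
        self.pair = pair
        self.integer = integer

    def random(self, size=None):
        if size is None:
            return self.scalar
        return np.full(size, self.uniform)

    def choice(self, n, size=2, replace=False):
        return np.array(self.pair[:size])

    def integers(self, n):
        return self.integer


def make_state(positions, objective, seed=0, maxg=10):
    dim = len(positions[0])
    space = opt.SearchSpace.cube(dim)
    params = opt.StrategyParams(maxg=maxg, seed=seed)
    state = opt.init_population(space, len(positions), objective, params)
    for ind, pos in zip(state.population, positions):
        pos = np.asarray(pos, dtype=float)
        ind.position = pos.copy()
        ind.fitness = float(objective(pos))
        ind.memory_position = pos.copy()
        ind.memory_fitness = ind.fitness
    best = max(state.population, key=lambda i: i.fitness)
    state.global_best = opt.copy.deepcopy(best)
    return state, space, params


class TestSearchSpaceAndInit:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            opt.SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_initial_population_within_box_and_reproducible(self):
        space = opt.SearchSpace.cube(3)
        params = opt.StrategyParams(maxg=5, seed=42)
        s1 = opt.init_population(space, 2, sphere, params)
        s2 = opt.init_population(space, 2, sphere, params)
        for ind in s1.population:
            assert np.all(ind.position >= -0.5) and np.all(ind.position <= 0.5)
            assert np.all(ind.velocity == 0)
        for a, b in zip(s1.population, s2.population):
            assert np.array_equal(a.position, b.position)

    def test_constant_objective_best(self):
        space = opt.SearchSpace.cube(4)
        state = opt.init_population(space, 3, lambda x: 7.0, opt.StrategyParams(maxg=1, seed=0))
        assert state.global_best.fitness == 7.0

    def test_global_best_matches_brute_force(self):
        # independent oracle: replay the seeded draws and evaluate by hand
        space = opt.SearchSpace.cube(5)
        params = opt.StrategyParams(maxg=1, seed=123)
        state = opt.init_population(space, 8, sphere, params)
        rng = np.random.default_rng(123)
        expected = max(sphere(rng.uniform(-0.5, 0.5, 5)) for _ in range(8))
        assert state.global_best.fitness == pytest.approx(expected, abs=0)

    def test_nonfinite_objective_names_individual(self):
        space = opt.SearchSpace.cube(2)
        with pytest.raises(opt.ObjectiveEvaluationError, match="individual"):
            opt.init_population(space, 2, lambda x: float("nan"), opt.StrategyParams(maxg=1))


class TestPerturbation:
    def test_beta_zero_when_coin_is_zero(self):
        space = opt.SearchSpace.cube(3)
        params = opt.StrategyParams(maxg=10, seed=0)
        per = opt.compute_perturbation(3, space, params, FakeRng(uniform=1.0, scalar=0.2))
        assert per.q == 0
        assert np.all(per.beta == 0)

    def test_unit_draw_at_reference_iteration(self):
        # at t = 0.3*maxg with r = 1 the adaptive amount is exp(0) = 1 and the
        # oscillation step is a quarter of the box width
        space = opt.SearchSpace.cube(3)
        params = opt.StrategyParams(maxg=10, seed=0)
        per = opt.compute_perturbation(3, space, params, FakeRng(uniform=1.0, scalar=0.9))
        assert per.lam == pytest.approx(np.ones(3))
        assert per.v == pytest.approx(0.25 * space.width)
        assert per.q == 1
        assert per.beta == pytest.approx(space.upper * per.lam)

    def test_amount_decays_with_iteration(self):
        space = opt.SearchSpace.cube(2)
        params = opt.StrategyParams(maxg=100, seed=0)
        early = opt.compute_perturbation(1, space, params, FakeRng(uniform=1.0, scalar=0.9))
        late = opt.compute_perturbation(100, space, params, FakeRng(uniform=1.0, scalar=0.9))
        assert np.all(early.lam > 1.0) and np.all(late.lam < 1.0)

    def test_iteration_out_of_range(self):
        space = opt.SearchSpace.cube(2)
        params = opt.StrategyParams(maxg=10, seed=0)
        with pytest.raises(ValueError):
            opt.compute_perturbation(11, space, params, FakeRng())


class TestGuidance:
    def test_identical_points_give_unit_coefficient(self):
        g = opt.guidance_coefficient(np.ones(4), np.ones(4), 4)
        assert g.a == 1.0 and g.d == 0.0

    def test_hand_value_one_dimension(self):
        g = opt.guidance_coefficient(np.array([0.0]), np.array([2.0]), 1)
        assert g.a == pytest.approx(math.exp(-1.0))

    def test_decreasing_in_distance(self):
        near = opt.guidance_coefficient(np.zeros(3), 0.1 * np.ones(3), 3)
        far = opt.guidance_coefficient(np.zeros(3), np.ones(3), 3)
        assert far.a < near.a

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            opt.guidance_coefficient(np.zeros(2), np.zeros(3), 3)


class TestMoves:
    def test_strategy_two_contracted_memories_fallback(self):
        state, space, _ = make_state([[0.0, 0.0], [0.0, 0.0]], sphere)
        new = opt.strategy_two(0, state, space, FakeRng(uniform=0.0))
        assert new == pytest.approx(state.global_best.position)
        new = opt.strategy_two(0, state, space, FakeRng(uniform=1.0))
        expected = space.clip(state.global_best.position + 0.25 * space.width)
        assert new == pytest.approx(expected)

    def test_strategy_two_stays_in_box(self):
        state, space, _ = make_state([[0.4, -0.3], [-0.2, 0.5]], sphere)
        rng = np.random.default_rng(0)
        for _ in range(50):
            new = opt.strategy_two(0, state, space, rng)
            assert np.all(new >= space.lower) and np.all(new <= space.upper)

    def test_strategy_three_fixed_point(self):
        state, space, _ = make_state([[0.1, 0.1], [0.1, 0.1]], sphere)
        new, vel = opt.strategy_three(0, state, space, FakeRng(uniform=1.0))
        assert new == pytest.approx(state.population[0].position)
        assert vel == pytest.approx(np.zeros(2))

    def test_strategy_three_hand_step(self):
        # 1-D, zero velocity, memory at own position, peer one unit away:
        # the move is exactly the guidance coefficient exp(-1/2)
        space = opt.SearchSpace(np.array([-2.0]), np.array([2.0]))
        params = opt.StrategyParams(maxg=5, seed=0)
        state = opt.init_population(space, 2, sphere, params)
        state.population[0].position = np.array([0.0])
        state.population[0].memory_position = np.array([0.0])
        state.population[0].velocity = np.array([0.0])
        state.population[1].position = np.array([1.0])
        new, vel = opt.strategy_three(0, state, space, FakeRng(uniform=1.0, integer=0))
        assert vel == pytest.approx([math.exp(-0.5)])
        assert new == pytest.approx([math.exp(-0.5)])


class TestMutation:
    def test_zero_probability_is_identity(self):
        space = opt.SearchSpace.cube(6)
        params = opt.StrategyParams(maxg=1, mutation_one_prob=0.0)
        x = np.linspace(-0.4, 0.4, 6)
        out = opt.mutate(x, space, params, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_unit_probability_redraws_everything(self):
        space = opt.SearchSpace.cube(50)
        params = opt.StrategyParams(maxg=1, mutation_one_prob=1.0)
        x = np.zeros(50)
        out = opt.mutate(x, space, params, np.random.default_rng(1))
        assert np.all(out != x)
        assert np.all(np.abs(out) <= 0.5)

    def test_unchanged_coordinates_bit_exact_and_fraction(self):
        space = opt.SearchSpace.cube(10_000)
        params = opt.StrategyParams(maxg=1, mutation_one_prob=0.6)
        x = np.random.default_rng(2).uniform(-0.5, 0.5, 10_000)
        out = opt.mutate(x, space, params, np.random.default_rng(3))
        changed = out != x
        assert 0.57 <= changed.mean() <= 0.63
        assert np.array_equal(out[~changed], x[~changed])


class TestAdaptiveSelection:
    def test_probability_endpoints_and_monotonicity(self):
        params = opt.StrategyParams(maxg=50, seed=0)
        assert opt.selection_probability(0, params) == pytest.approx(0.3)
        assert opt.selection_probability(50, params) == 1.0
        probs = [opt.selection_probability(t, params) for t in range(51)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_zero_maxg_rejected(self):
        with pytest.raises(ValueError):
            opt.selection_probability(0, opt.StrategyParams(maxg=0))

    def test_dispatch_frequencies(self):
        params = opt.StrategyParams(maxg=10, seed=0)
        rng = np.random.default_rng(5)
        draws = [opt.select_strategy(0, params, rng) for _ in range(100_000)]
        freq = {s: sum(d is s for d in draws) / len(draws) for s in opt.Strategy}
        assert freq[opt.Strategy.II] == pytest.approx(0.7, abs=0.01)
        for s in (opt.Strategy.I, opt.Strategy.III, opt.Strategy.MUTATE):
            assert freq[s] == pytest.approx(0.1, abs=0.01)
        late = [opt.select_strategy(10, params, rng) for _ in range(10_000)]
        assert opt.Strategy.II not in late


class TestStepAndRun:
    def test_constant_objective_keeps_best(self):
        space = opt.SearchSpace.cube(3)
        params = opt.StrategyParams(maxg=5, seed=1)
        state = opt.init_population(space, 4, lambda x: 2.5, params)
        for _ in range(5):
            opt.step(state, lambda x: 2.5, space, params)
        assert state.global_best.fitness == 2.5
        assert len(state.history) == 5

    def test_bounds_elitism_memory_after_run(self):
        space = opt.SearchSpace.cube(5)
        params = opt.StrategyParams(maxg=20, seed=3)
        state = opt.init_population(space, 6, sphere, params)
        for _ in range(20):
            opt.step(state, sphere, space, params)
            for ind in state.population:
                assert np.all(ind.position >= -0.5) and np.all(ind.position <= 0.5)
        bests = [h["best_fitness"] for h in state.history]
        assert all(b >= a for a, b in zip(bests, bests[1:]))
        for ind in state.population:
            # personal memory stores the position that achieved its fitness
            assert sphere(ind.memory_position) == pytest.approx(ind.memory_fitness)
            assert ind.memory_fitness >= ind.fitness - 1e-12

    def test_run_deterministic_and_zero_iterations(self):
        space = opt.SearchSpace.cube(4)
        x1, f1, h1 = opt.run(sphere, space, 5, 10, seed=9)
        x2, f2, h2 = opt.run(sphere, space, 5, 10, seed=9)
        assert np.array_equal(x1, x2) and f1 == f2 and h1 == h2
        x0, f0, h0 = opt.run(sphere, space, 5, 0, seed=9)
        assert h0 == [] and f0 <= 0.0

    def test_strategy_mix_shifts_from_exploration_to_exploitation(self):
        space = opt.SearchSpace.cube(3)
        params = opt.StrategyParams(maxg=40, seed=4)
        state = opt.init_population(space, 8, sphere, params)
        for _ in range(40):
            opt.step(state, sphere, space, params)
        first = sum(h["strategy_counts"]["II"] for h in state.history[:5]) / 40
        last = sum(h["strategy_counts"]["II"] for h in state.history[-5:]) / 40
        assert first > 0.5 and last < 0.15


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), dim=st.integers(1, 6), n=st.integers(2, 6))
def test_every_visited_position_is_inside_the_box(seed, dim, n):
    space = opt.SearchSpace.cube(dim)
    seen = []

    def watcher(x):
        seen.append(x.copy())
        return sphere(x)

    opt.run(watcher, space, n, 3, seed=seed)
    arr = np.array(seen)
    assert np.all(arr >= -0.5 - 1e-12) and np.all(arr <= 0.5 + 1e-12)
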