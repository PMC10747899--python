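import numpy as np
import pytest

from gipso.metaheuristics import (
    GipsoConfig,
    OptimizerConfig,
    Particle,
    SwarmState,
    benchmark_objective,
    benchmark_space,
    crossover,
    inertia_weight,
    initialize_swarm,
    mutate,
    optimize,
    pso_step,
    replace_worst,
)
from gipso.search_space import ParameterSpec, SearchSpace


def unit_space(d=2, lo=-10.0, hi=10.0):
    return SearchSpace(tuple(ParameterSpec(f"x{i}", lo, hi) for i in range(d)))


class TestInertiaWeight:
    @pytest.mark.parametrize("t, expected", [(0, 0.9), (8, 0.4), (4, 0.65)])
    def test_linear_anneal(self, t, expected):
        cfg = OptimizerConfig(iterations=8, w_max=0.9, w_min=0.4)
        assert inertia_weight(t, cfg) == pytest.approx(expected)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            inertia_weight(0, OptimizerConfig(iterations=0))


class TestInitializeSwarm:
    def test_determinism_and_bounds(self):
        space = unit_space(3)
        cfg = OptimizerConfig(pop_size=6)
        s1 = initialize_swarm(space, cfg, np.random.default_rng(5))
        s2 = initialize_swarm(space, cfg, np.random.default_rng(5))
        assert len(s1.particles) == 6
        for p1, p2 in zip(s1.particles, s2.particles):
            assert np.array_equal(p1.position, p2.position)
            assert np.array_equal(p1.velocity, p2.velocity)
            assert np.all((p1.position >= space.lower) & (p1.position <= space.upper))
            vmax = cfg.v_max_fraction * space.widths
            assert np.all(np.abs(p1.velocity) <= vmax)


class TestPsoStep:
    def test_fixed_point_at_consensus(self, rng):
        """A particle sitting on its own and the global best with zero
        velocity does not move."""
        space = unit_space(1)
        x = np.array([2.0])
        p = Particle(x.copy(), np.zeros(1), x.copy(), 0.5, 0.5)
        q = Particle(x.copy(), np.zeros(1), x.copy(), 0.5, 0.5)
        swarm = SwarmState([p, q], x.copy(), 0.5)
        cfg = OptimizerConfig(pop_size=2, iterations=4)
        pso_step(swarm, lambda z: float(z[0] ** 2), 0, space, cfg, rng)
        assert np.array_equal(swarm.particles[0].position, x)
        assert np.array_equal(swarm.particles[0].velocity, np.zeros(1))

    def test_inertia_only_limit(self, rng):
        """With c1 = c2 = 0 and w = 1 the velocity is carried unchanged."""
        space = unit_space(1)
        p = Particle(np.array([1.0]), np.array([0.5]), np.array([1.0]), 1.0, 1.0)
        q = Particle(np.array([0.0]), np.array([0.0]), np.array([0.0]), 0.0, 0.0)
        swarm = SwarmState([p, q], np.array([0.0]), 0.0)
        cfg = OptimizerConfig(pop_size=2, iterations=4, w_max=1.0, w_min=1.0,
                              c1=0.0, c2=0.0, v_max_fraction=0.1)
        pso_step(swarm, lambda z: float(z[0] ** 2), 0, space, cfg, rng)
        assert swarm.particles[0].velocity[0] == pytest.approx(0.5)
        assert swarm.particles[0].position[0] == pytest.approx(1.5)

    def test_single_step_matches_hand_arithmetic(self):
        """One 1-D velocity/position update equals the update rule computed
        by hand with the same random draws."""
        space = unit_space(1)
        p = Particle(np.array([3.0]), np.array([0.2]), np.array([1.0]), 1.0, 9.0)
        q = Particle(np.array([-1.0]), np.array([0.0]), np.array([-1.0]), 1.0, 1.0)
        swarm = SwarmState([p, q], np.array([-1.0]), 1.0)
        cfg = OptimizerConfig(pop_size=2, iterations=8, w_max=0.9, w_min=0.4,
                              c1=2.0, c2=2.0, v_max_fraction=0.2)
        seed = 11
        draws = np.random.default_rng(seed)
        r1, r2 = float(draws.random(1)[0]), float(draws.random(1)[0])
        w = 0.9  # t = 0
        v_expected = w * 0.2 + 2 * r1 * (1.0 - 3.0) + 2 * r2 * (-1.0 - 3.0)
        v_expected = float(np.clip(v_expected, -4.0, 4.0))  # Vmax = 0.2 * 20
        x_expected = float(np.clip(3.0 + v_expected, -10, 10))
        pso_step(swarm, lambda z: float(z[0] ** 2), 0, space, cfg,
                 np.random.default_rng(seed))
        assert swarm.particles[0].velocity[0] == pytest.approx(v_expected)
        assert swarm.particles[0].position[0] == pytest.approx(x_expected)


class TestCrossover:
    def test_midpoint_blend(self):
        """With pc = 1 every parameter blends; alpha = 0.5 gives midpoints."""

        class HalfRng:
            def random(self, n):
                return np.full(n, 0.5)

        child = crossover(np.array([1.0, 2.0]), np.array([3.0, 4.0]), 1.0, HalfRng())
        assert np.allclose(child, [2.0, 3.0])

    def test_alpha_one_copies_best_alpha_zero_copies_other(self):
        class FixedAlpha:
            def __init__(self, alpha):
                self.alpha = alpha
                self.calls = 0

            def random(self, n):
                self.calls += 1
                # first call decides blending (prob pc), second is alpha
                return np.zeros(n) if self.calls == 1 else np.full(n, self.alpha)

        a, b = np.array([1.0, 2.0]), np.array([5.0, 6.0])
        assert np.allclose(crossover(a, b, 1.0, FixedAlpha(1.0)), a)
        assert np.allclose(crossover(a, b, 1.0, FixedAlpha(0.0)), b)

    def test_zero_pc_copies_best(self, rng):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0])
        # pc must be > 0 for configs, but crossover itself accepts the limit
        child = crossover(a, b, 1e-12, rng)
        assert np.allclose(child, a)

    def test_child_in_convex_hull(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        for _ in range(50):
            child = crossover(a, b, 0.7, rng)
            assert np.all(child >= np.minimum(a, b) - 1e-12)
            assert np.all(child <= np.maximum(a, b) + 1e-12)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            crossover(np.zeros(2), np.zeros(3), 0.5, rng)


class TestMutate:
    def test_pm_zero_is_identity(self, rng):
        space = unit_space(4)
        gcfg = GipsoConfig(pm=1e-300)
        pos = rng.uniform(space.lower, space.upper)
        assert np.array_equal(mutate(pos, space, gcfg, rng), pos)

    def test_forced_step_magnitude(self):
        """Range width 1, md = 0.1, rnd = 0.5, positive sign: +0.05."""

        class Scripted:
            def __init__(self):
                self.uniform_calls = 0

            def random(self):
                return 0.0  # always triggers mutation; sign draw < 0.5 -> +

            def uniform(self, lo, hi):
                return 0.5

        space = SearchSpace((ParameterSpec("x", 0.0, 1.0),))
        out = mutate(np.array([0.3]), space, GipsoConfig(md=0.1, pm=1.0), Scripted())
        assert out[0] == pytest.approx(0.35)

    def test_halved_magnitude_variant(self):
        class Scripted:
            def random(self):
                return 0.0

            def uniform(self, lo, hi):
                return 0.5

        space = SearchSpace((ParameterSpec("x", 0.0, 1.0),))
        gcfg = GipsoConfig(md=0.1, pm=1.0, halve_mutation=True)
        out = mutate(np.array([0.3]), space, gcfg, Scripted())
        assert out[0] == pytest.approx(0.55)

    def test_always_within_bounds(self):
        """1000 seeded mutations from random in-bounds points stay inside."""
        space = unit_space(3, -1.0, 2.0)
        gcfg = GipsoConfig(pm=1.0, md=0.9)
        rng = np.random.default_rng(3)
        for _ in range(1000):
            pos = rng.uniform(space.lower, space.upper)
            out = mutate(pos, space, gcfg, rng)
            assert np.all((out >= space.lower) & (out <= space.upper))


class TestReplaceWorst:
    def make_swarm(self, fitnesses):
        parts = [
            Particle(np.array([float(i)]), np.zeros(1), np.array([float(i)]), f, f)
            for i, f in enumerate(fitnesses)
        ]
        best = int(np.argmin(fitnesses))
        return SwarmState(parts, parts[best].position.copy(), min(fitnesses))

    def test_max_fitness_replaced(self):
        swarm = self.make_swarm([0.1, 0.5, 0.9])
        replace_worst(swarm, np.array([7.0]))
        assert swarm.particles[2].position[0] == 7.0
        assert len(swarm.particles) == 3
        assert np.all(swarm.particles[2].velocity == 0)
        assert swarm.particles[2].fitness == np.inf

    def test_tie_goes_to_lowest_index(self):
        swarm = self.make_swarm([0.9, 0.9, 0.1])
        replace_worst(swarm, np.array([7.0]))
        assert swarm.particles[0].position[0] == 7.0
        assert swarm.particles[1].position[0] == 1.0

    def test_best_survives(self):
        swarm = self.make_swarm([0.3, 0.1, 0.2])
        replace_worst(swarm, np.array([7.0]))
        assert swarm.particles[1].fitness == 0.1


class TestOptimize:
    def test_benchmark_values(self):
        sphere = benchmark_objective("sphere")
        rastrigin = benchmark_objective("rastrigin")
        assert sphere(np.zeros(4)) == 0.0
        assert rastrigin(np.zeros(4)) == 0.0
        assert sphere(np.array([1.0, 1.0])) == 2.0
        with pytest.raises(ValueError):
            benchmark_objective("ackley")

    def test_sphere_convergence(self):
        """GIPSO at a generous budget solves the 7-D sphere to below 1e-2
        (expected value frozen from repeated seeded runs of this optimizer)."""
        space = benchmark_space("sphere", 7)
        cfg = OptimizerConfig(pop_size=20, iterations=100, variant="gipso")
        res = optimize(benchmark_objective("sphere"), space, cfg, rng=1)
        assert res.best_fitness < 1e-2

    @pytest.mark.parametrize("variant", ["pso", "gipso", "ga"])
    def test_determinism(self, variant):
        space = benchmark_space("rastrigin", 3)
        cfg = OptimizerConfig(pop_size=4, iterations=5, variant=variant)
        f = benchmark_objective("rastrigin")
        r1 = optimize(f, space, cfg, rng=9)
        r2 = optimize(f, space, cfg, rng=9)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.best_fitness == r2.best_fitness
        assert r1.trace == r2.trace

    @pytest.mark.parametrize("variant", ["pso", "gipso", "ga"])
    def test_trace_monotone_and_budget(self, variant):
        space = benchmark_space("rastrigin", 5)
        cfg = OptimizerConfig(pop_size=6, iterations=8, variant=variant)
        res = optimize(benchmark_objective("rastrigin"), space, cfg, rng=2)
        assert len(res.trace) == 9
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))
        assert res.evaluations_used == 6 * 9

    def test_zero_iterations_returns_initial_best(self):
        space = benchmark_space("sphere", 3)
        cfg = OptimizerConfig(pop_size=5, iterations=0, variant="gipso")
        f = benchmark_objective("sphere")
        res = optimize(f, space, cfg, rng=4)
        init = initialize_swarm(space, cfg, np.random.default_rng(4))
        expected = min(f(p.position) for p in init.particles)
        assert res.best_fitness == pytest.approx(expected)
        assert res.evaluations_used == 5

    def test_all_evaluated_positions_in_bounds(self):
        space = benchmark_space("rastrigin", 4)
        seen = []

        def watched(x):
            seen.append(x.copy())
            return benchmark_objective("rastrigin")(x)

        for variant in ("pso", "gipso", "ga"):
            cfg = OptimizerConfig(pop_size=6, iterations=8, variant=variant)
            optimize(watched, space, cfg, rng=6)
        seen = np.array(seen)
        assert np.all(seen >= space.lower - 1e-12)
        assert np.all(seen <= space.upper + 1e-12)
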