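"""Particle swarm optimization and its genetically inspired hybrid (GIPSO).

The swarm minimizes a black-box objective over a bounded box.  Classic PSO
moves each particle under inertia, a cognitive pull toward its personal best
and a social pull toward the global best, with a linearly annealed inertia
weight.  GIPSO adds, once per iteration, a genetic step: blend crossover of
the global best with a random agent, per-parameter mutation, and replacement
of the worst particle by the offspring.  The offspring's evaluation is
deferred to the next iteration's sweep, so GIPSO spends exactly the same
number of objective evaluations as PSO under the same budget.

A real-coded genetic algorithm baseline and standard benchmark objectives
(sphere, Rastrigin) are included for oracle testing of the optimizers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .search_space import SearchSpace, clip_to_bounds

__all__ = [
    "Particle",
    "SwarmState",
    "OptimizerConfig",
    "GipsoConfig",
    "OptimizationResult",
    "initialize_swarm",
    "inertia_weight",
    "pso_step",
    "crossover",
    "mutate",
    "replace_worst",
    "optimize",
    "benchmark_objective",
    "benchmark_space",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass
class Particle:
    """One search agent: position, velocity and personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    personal_best: np.ndarray
    personal_best_fitness: float = np.inf
    fitness: float = np.inf


@dataclass
class SwarmState:
    particles: list[Particle]
    global_best: np.ndarray
    global_best_fitness: float = np.inf
    iteration: int = 0

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([p.fitness for p in self.particles])


@dataclass(frozen=True)
class OptimizerConfig:
    """Swarm settings.  Defaults follow the canonical inertia-weight PSO
    (w annealed 0.9 -> 0.4, c1 = c2 = 2, velocity clamped to 10% of each
    dimension's range) at the small tuning budget used for hyperparameter
    search: 6 agents, 8 iterations."""

    pop_size: int = 6
    iterations: int = 8
    w_max: float = 0.9
    w_min: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    v_max_fraction: float = 0.1
    variant: str = "gipso"  # {"pso", "gipso", "ga"}

    def __post_init__(self) -> None:
        if not (0 < self.w_min <= self.w_max):
            raise ValueError("need 0 < w_min <= w_max")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.variant not in ("pso", "gipso", "ga"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass(frozen=True)
class GipsoConfig:
    """Genetic-step controls.

    pc : per-parameter probability that the offspring blends the two parents
         instead of copying the best agent (empirical default 0.1).
    md : mutation magnitude factor scaling the random in-range draw.
    pm : per-parameter mutation probability.
    halve_mutation : alternative magnitude rule using 0.5 * rnd instead of
         md * rnd (off by default).
    """

    pc: float = 0.1
    md: float = 0.1
    pm: float = 0.1
    halve_mutation: bool = False

    def __post_init__(self) -> None:
        for name in ("pc", "md", "pm"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)
    evaluations_used: int = 0


def _v_max(space: SearchSpace, config: OptimizerConfig) -> np.ndarray:
    return config.v_max_fraction * space.widths


def initialize_swarm(
    space: SearchSpace, config: OptimizerConfig, rng: np.random.Generator
) -> SwarmState:
    """Uniform positions within bounds, uniform velocities in [-Vmax, +Vmax].

    Fitnesses are unset (+inf) until the first evaluation sweep.
    """
    vmax = _v_max(space, config)
    particles = []
    for _ in range(config.pop_size):
        pos = rng.uniform(space.lower, space.upper)
        vel = rng.uniform(-vmax, vmax)
        particles.append(Particle(pos, vel, pos.copy()))
    return SwarmState(particles, particles[0].position.copy())


def inertia_weight(t: int, config: OptimizerConfig) -> float:
    """Linear anneal w_max -> w_min over the iteration budget T."""
    T = config.iterations
    if T == 0:
        raise ValueError("inertia weight undefined for a zero-iteration budget")
    return config.w_max - (config.w_max - config.w_min) / T * t


def _evaluate(swarm: SwarmState, objective: Objective) -> int:
    """Evaluate every particle at its current position; refresh bests.

    Returns the number of objective calls made (always pop_size).
    Lowest index wins fitness ties for the global best.
    """
    for p in swarm.particles:
        p.fitness = float(objective(p.position))
        if p.fitness < p.personal_best_fitness:
            p.personal_best_fitness = p.fitness
            p.personal_best = p.position.copy()
        if p.fitness < swarm.global_best_fitness:
            swarm.global_best_fitness = p.fitness
            swarm.global_best = p.position.copy()
    return len(swarm.particles)


def pso_step(
    swarm: SwarmState,
    objective: Objective,
    t: int,
    space: SearchSpace,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One velocity/position update sweep followed by re-evaluation.

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), clamped to +-Vmax;
    x <- x + v, clipped to the box.  r1, r2 are fresh uniform draws per
    particle and dimension.
    """
    w = inertia_weight(t, config)
    vmax = _v_max(space, config)
    for p in swarm.particles:
        r1 = rng.random(space.dimension)
        r2 = rng.random(space.dimension)
        p.velocity = (
            w * p.velocity
            + config.c1 * r1 * (p.personal_best - p.position)
            + config.c2 * r2 * (swarm.global_best - p.position)
        )
        np.clip(p.velocity, -vmax, vmax, out=p.velocity)
        p.position = clip_to_bounds(p.position + p.velocity, space)
    _evaluate(swarm, objective)
    swarm.iteration = t + 1
    return swarm


def crossover(
    best: Sequence[float],
    other: Sequence[float],
    pc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend crossover: per parameter, with probability pc the child takes
    alpha*a + (1-alpha)*b with alpha ~ U(0,1) drawn per parameter; otherwise
    it copies the best agent's parameter."""
    a = np.asarray(best, dtype=float)
    b = np.asarray(other, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"parent length mismatch: {a.shape} vs {b.shape}")
    blend = rng.random(a.shape[0]) < pc
    alpha = rng.random(a.shape[0])
    child = a.copy()
    child[blend] = alpha[blend] * a[blend] + (1 - alpha[blend]) * b[blend]
    return child


def mutate(
    position: Sequence[float],
    space: SearchSpace,
    gcfg: GipsoConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-parameter mutation: with probability pm, draw rnd uniform over the
    dimension's range width and add or subtract md*rnd (sign uniform), then
    clip back into the box."""
    pos = np.asarray(position, dtype=float).copy()
    widths = space.widths
    for k in range(space.dimension):
        if rng.random() < gcfg.pm:
            rnd = rng.uniform(0.0, widths[k])
            sign = 1.0 if rng.random() < 0.5 else -1.0
            magnitude = 0.5 * rnd if gcfg.halve_mutation else gcfg.md * rnd
            pos[k] += sign * magnitude
    return clip_to_bounds(pos, space)


def replace_worst(swarm: SwarmState, new_position: np.ndarray) -> SwarmState:
    """Replace the particle with the worst current fitness by a fresh agent.

    The newcomer starts with zero velocity and an unset fitness — its
    evaluation is deferred to the next iteration's sweep.  Ties for worst
    resolve to the lowest index.
    """
    worst = int(np.argmax(swarm.fitnesses))
    pos = np.asarray(new_position, dtype=float).copy()
    swarm.particles[worst] = Particle(
        position=pos,
        velocity=np.zeros_like(pos),
        personal_best=pos.copy(),
        personal_best_fitness=np.inf,
        fitness=np.inf,
    )
    return swarm


def _genetic_step(
    swarm: SwarmState,
    space: SearchSpace,
    gcfg: GipsoConfig,
    rng: np.random.Generator,
) -> None:
    """Crossover of the global best with a random other agent, mutation,
    then worst-replacement (the GIPSO introduction mechanism)."""
    best_idx = int(np.argmin(swarm.fitnesses))
    candidates = [i for i in range(len(swarm.particles)) if i != best_idx]
    partner = swarm.particles[int(rng.choice(candidates))]
    child = crossover(swarm.global_best, partner.position, gcfg.pc, rng)
    child = mutate(child, space, gcfg, rng)
    replace_worst(swarm, child)


def _counted(objective: Objective) -> tuple[Objective, list[int]]:
    counter = [0]

    def wrapped(x: np.ndarray) -> float:
        counter[0] += 1
        return objective(x)

    return wrapped, counter


def optimize(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    gcfg: GipsoConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> OptimizationResult:
    """Run the configured optimizer variant for its iteration budget.

    Returns the best-ever position, its fitness, a per-iteration trace of the
    global best (length T + 1, non-increasing) and the number of objective
    evaluations spent — pop_size * (T + 1) for every variant.
    """
    rng = np.random.default_rng(rng)
    gcfg = gcfg or GipsoConfig()
    if config.variant == "ga":
        return _optimize_ga(objective, space, config, gcfg, rng)

    obj, counter = _counted(objective)
    swarm = initialize_swarm(space, config, rng)
    _evaluate(swarm, obj)
    trace = [swarm.global_best_fitness]
    for t in range(config.iterations):
        pso_step(swarm, obj, t, space, config, rng)
        if config.variant == "gipso":
            _genetic_step(swarm, space, gcfg, rng)
        trace.append(swarm.global_best_fitness)
    logger.debug(
        "optimize variant=%s best=%.6g evals=%d",
        config.variant, swarm.global_best_fitness, counter[0],
    )
    return OptimizationResult(
        best_position=swarm.global_best.copy(),
        best_fitness=swarm.global_best_fitness,
        trace=trace,
        evaluations_used=counter[0],
    )


def _optimize_ga(
    objective: Objective,
    space: SearchSpace,
    config: OptimizerConfig,
    gcfg: GipsoConfig,
    rng: np.random.Generator,
) -> OptimizationResult:
    """Real-coded GA baseline: tournament selection (k=2), blend crossover,
    per-parameter mutation, elitism of 1.  Spends the same evaluation budget
    as the swarm variants."""
    obj, counter = _counted(objective)
    pop = rng.uniform(space.lower, space.upper, size=(config.pop_size, space.dimension))
    fit = np.array([obj(x) for x in pop])
    best_idx = int(np.argmin(fit))
    best_pos, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace = [best_fit]

    def tournament() -> np.ndarray:
        i, j = rng.integers(0, config.pop_size, size=2)
        return pop[i] if fit[i] <= fit[j] else pop[j]

    for _ in range(config.iterations):
        children = [best_pos.copy()]  # elitism
        while len(children) < config.pop_size:
            a, b = tournament(), tournament()
            alpha = rng.random(space.dimension)
            child = alpha * a + (1 - alpha) * b
            child = mutate(child, space, gcfg, rng)
            children.append(child)
        pop = np.array(children)
        fit = np.array([obj(x) for x in pop])
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_fit:
            best_fit = float(fit[gen_best])
            best_pos = pop[gen_best].copy()
        trace.append(best_fit)
    return OptimizationResult(best_pos, best_fit, trace, counter[0])


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x, dtype=float) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))


_BENCHMARKS: dict[str, tuple[Objective, float]] = {
    "sphere": (_sphere, 100.0),
    "rastrigin": (_rastrigin, 5.12),
}


def benchmark_objective(name: str) -> Objective:
    """Standard test function with minimum 0 at the origin."""
    try:
        return _BENCHMARKS[name][0]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}"
        ) from None


def benchmark_space(name: str, dimension: int) -> SearchSpace:
    """Conventional symmetric box for a named benchmark function."""
    from .search_space import ParameterSpec

    try:
        half = _BENCHMARKS[name][1]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}"
        ) from None
    return SearchSpace(
        tuple(ParameterSpec(f"x{i}", -half, half) for i in range(dimension))
    )
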