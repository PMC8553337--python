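"""mu+lambda evolution strategy with neutral search and fitness caching.

Each generation, ``lam`` offspring are created from the ``mu`` parents by
tournament selection followed by per-gene point mutation (no crossover).
Parents and offspring compete jointly for the ``mu`` slots of the next
generation; at equal fitness an offspring is preferred over a parent
(neutral search), which lets silent mutations accumulate and drift across
fitness plateaus.  Because silent mutations leave the phenotype unchanged,
fitness values are cached per canonical expression key: only genuinely new
expressions trigger a (potentially expensive) simulation.

The per-evaluation task sample is drawn once from the run seed and reused
in every generation, so fitness values are comparable across generations.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .cgp import (
    CompiledRule,
    ExpressionGraph,
    Genome,
    GraphDims,
    InvalidEvaluation,
    PrimitiveSet,
    decode,
    mutate,
    random_genome,
)

__all__ = [
    "EvolutionParams",
    "Individual",
    "FitnessCache",
    "EvolutionState",
    "tournament_select",
    "evaluate_with_cache",
    "aggregate_fitness",
    "step_generation",
    "evolve",
]

#: Fitness function contract: f(graph, sample_seeds) -> float.  May raise
#: InvalidEvaluation, which is absorbed as fitness -inf.
FitnessFn = Callable[[ExpressionGraph, tuple[int, ...]], float]


@dataclass
class EvolutionParams:
    mu: int = 4
    lam: int = 4
    n_generations: int = 100
    tournament_size: int = 1
    p_mutate: float = 0.3
    seed: int = 0
    n_sample_tasks: int = 1

    def __post_init__(self) -> None:
        if self.mu < 1 or self.lam < 1 or self.tournament_size < 1:
            raise ValueError("mu, lam and tournament_size must all be >= 1")


@dataclass
class Individual:
    genome: Genome
    key: str
    fitness: float | None = None
    graph: ExpressionGraph | None = None

    @classmethod
    def from_genome(cls, genome: Genome, primitives: PrimitiveSet) -> "Individual":
        graph = decode(genome, primitives)
        return cls(genome=genome, key=graph.key, graph=graph)


class FitnessCache:
    """Phenotype-level fitness cache keyed on (expression key, task-sample
    seeds).  A hit returns a value previously computed for an identical
    phenotype under the identical task sample; -inf is cached like any
    other value."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, tuple[int, ...]], float] = {}
        self.hits = 0
        self.misses = 0

    def __len__(self) -> int:
        return len(self._store)

    def get_or_compute(
        self, key: str, sample_seeds: tuple[int, ...], compute: Callable[[], float]
    ) -> float:
        k = (key, sample_seeds)
        if k in self._store:
            self.hits += 1
            return self._store[k]
        self.misses += 1
        value = compute()
        self._store[k] = value
        return value


@dataclass
class EvolutionState:
    parents: list[Individual]
    generation: int
    rng: np.random.Generator
    cache: FitnessCache
    sample_seeds: tuple[int, ...]
    history: list[dict] = field(default_factory=list)

    @property
    def best(self) -> Individual:
        return max(self.parents, key=lambda ind: ind.fitness)


def tournament_select(
    population: Sequence[Individual], size: int, rng: np.random.Generator
) -> Individual:
    """Best member of a uniformly drawn subset (without replacement).

    With size 1 this is a uniform random pick, the setting used throughout
    the plasticity searches; size == len(population) returns the global
    best.
    """
    if len(population) == 0:
        raise ValueError("empty population")
    if not 1 <= size <= len(population):
        raise ValueError("tournament size must lie in [1, len(population)]")
    idx = rng.choice(len(population), size=size, replace=False)
    return max((population[int(i)] for i in idx), key=lambda ind: ind.fitness)


def evaluate_with_cache(
    individual: Individual,
    fitness_fn: FitnessFn,
    cache: FitnessCache,
    sample_seeds: tuple[int, ...],
) -> float:
    """Evaluate an individual, skipping simulation on a cache hit.

    Invalid evaluations (division by zero etc.) and NaN results map to
    fitness -inf, so a malformed expression can never crash or poison a
    run."""

    def compute() -> float:
        try:
            v = float(fitness_fn(individual.graph, sample_seeds))
        except InvalidEvaluation:
            return float("-inf")
        return v if not math.isnan(v) else float("-inf")

    individual.fitness = cache.get_or_compute(individual.key, sample_seeds, compute)
    return individual.fitness


def aggregate_fitness(per_task_values: Sequence[float], mode: str = "mean") -> float:
    """Collapse per-task fitness values into a scalar: ``mean`` for the
    reward/error families, ``min`` for the correlation family.  Any -inf
    element is absorbing."""
    values = list(per_task_values)
    if not values:
        raise ValueError("need at least one per-task value")
    if any(v == float("-inf") for v in values):
        return float("-inf")
    if mode == "mean":
        return float(np.mean(values))
    if mode == "min":
        return float(np.min(values))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def step_generation(
    state: EvolutionState,
    fitness_fn: FitnessFn,
    params: EvolutionParams,
    primitives: PrimitiveSet,
) -> EvolutionState:
    """One generation of the mu+lambda strategy (mutation-only offspring,
    joint selection, offspring preferred at fitness ties)."""
    t0 = time.perf_counter()
    offspring: list[Individual] = []
    while len(offspring) < params.lam:
        parent = tournament_select(state.parents, params.tournament_size, state.rng)
        child_genome, _ = mutate(parent.genome, params.p_mutate, state.rng, primitives)
        offspring.append(Individual.from_genome(child_genome, primitives))
    for ind in offspring:
        evaluate_with_cache(ind, fitness_fn, state.cache, state.sample_seeds)

    # neutral search: offspring (flag 0) sort before parents (flag 1) at ties
    pool = [(ind, 0) for ind in offspring] + [(ind, 1) for ind in state.parents]
    pool.sort(key=lambda item: (-item[0].fitness, item[1]))
    state.parents = [ind for ind, _ in pool[: params.mu]]
    state.generation += 1

    best = state.best
    state.history.append(
        {
            "generation": state.generation,
            "best_fitness": best.fitness,
            "best_expression": best.key,
            "cache_hits": state.cache.hits,
            "cache_misses": state.cache.misses,
            "wall_time_s": round(time.perf_counter() - t0, 6),
        }
    )
    return state


def _derive_seeds(seed: int, n: int) -> tuple[int, ...]:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    return tuple(int(s) for s in rng.integers(0, 2**31 - 1, size=n))


def init_state(
    dims: GraphDims, primitives: PrimitiveSet, params: EvolutionParams
) -> EvolutionState:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(0,)))
    parents = [
        Individual.from_genome(random_genome(dims, primitives, rng), primitives)
        for _ in range(params.mu)
    ]
    return EvolutionState(
        parents=parents,
        generation=0,
        rng=rng,
        cache=FitnessCache(),
        sample_seeds=_derive_seeds(params.seed, params.n_sample_tasks),
    )


def evolve(
    fitness_fn: FitnessFn,
    dims: GraphDims,
    primitives: PrimitiveSet,
    params: EvolutionParams,
    log_path=None,
    target_fitness: float | None = None,
) -> EvolutionState:
    """Run the full evolutionary search.

    ``log_path`` (optional) receives one JSON line per generation.  The
    run stops early once ``target_fitness`` is reached, if given.
    """
    state = init_state(dims, primitives, params)
    for ind in state.parents:
        evaluate_with_cache(ind, fitness_fn, state.cache, state.sample_seeds)
    log = open(log_path, "w") if log_path is not None else None
    try:
        for _ in range(params.n_generations):
            step_generation(state, fitness_fn, params, primitives)
            if log is not None:
                rec = dict(state.history[-1])
                rec.pop("wall_time_s")  # keep replay logs byte-identical
                log.write(json.dumps(rec) + "\n")
            if target_fitness is not None and state.best.fitness >= target_fitness:
                break
    finally:
        if log is not None:
            log.close()
    return state


def rule_from_individual(ind: Individual, input_names=None) -> CompiledRule:
    return CompiledRule.from_graph(ind.graph, input_names=input_names)
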