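"""Constraint-aware NSGA-II engine for the facility-selection problem.

The genome is a vector of real-valued keys in [0, 1], one per candidate
facility, decoded to a binary selection at threshold 0.5.  This random-key
encoding lets the printed variation hyperparameters (SBX distribution index
2, polynomial-mutation index 5) act literally on the genome while the search
space stays binary; a configuration switch offers pure-binary operators
(uniform crossover, per-gene bit flip) for comparison.

Chromosome construction mirrors the three-step scheme: stochastic initial
selection, proximity-based demand allocation, and a consistency repair that
deselects any selected facility left with zero allocated demand points
(pushing its key back below threshold).  Repair never empties the selection:
an all-zero decode force-selects the facility with the largest key.

Selection pressure comes from ``tournament_rounds`` independent probabilistic
binary tournaments per generation on (rank, crowding), the better individual
winning with probability ``tournament_win_prob``; survivors of the combined
parent+offspring population are chosen by rank, then crowding distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .evaluation import (
    ParetoSet,
    SelectionPlan,
    contracts_from_selection,
    cost_coefficients,
    induce_allocation,
    _objectives_from_assignment,
    _workload_vector,
)
from .indicators import hypervolume_2d
from .instance import ProblemInstance

__all__ = [
    "Chromosome",
    "EngineConfig",
    "decode_and_repair",
    "initialize_population",
    "nondominated_sort",
    "crowding_distance",
    "evolve",
]


@dataclass
class Chromosome:
    """One individual: genome, repaired phenotype and fitness bookkeeping."""

    keys: np.ndarray
    selection: np.ndarray  # binary, after decoding and repair
    allocation_counts: np.ndarray  # demand points served per facility
    assignment: np.ndarray  # demand index -> facility index
    objectives: tuple[float, float]
    rank: int = -1
    crowding: float = 0.0

    def plan(self, instance: ProblemInstance) -> SelectionPlan:
        y = contracts_from_selection(instance, self.selection)
        w = _workload_vector(instance, self.assignment)
        return SelectionPlan(
            x=self.selection.astype(np.int8),
            y=y,
            z=self.assignment.copy(),
            w=w,
            objectives=self.objectives,
        )


@dataclass(frozen=True)
class EngineConfig:
    """NSGA-II hyperparameters.

    Defaults follow the study configuration: population 100, 500 generations,
    100 tournament rounds with win probability 0.9, SBX index 2 and
    polynomial-mutation index 5.  ``crossover_prob`` and ``mutation_prob``
    default to standard practice (0.9 and 1/n per gene); ``operators`` may be
    ``"real"`` (random keys, default) or ``"binary"``.
    """

    population_size: int = 100
    generations: int = 500
    tournament_rounds: int = 100
    tournament_win_prob: float = 0.9
    crossover_index: float = 2.0
    mutation_index: float = 5.0
    crossover_prob: float = 0.9
    mutation_prob: float | None = None  # None -> 1 / n_facilities
    operators: str = "real"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations < 0 or self.tournament_rounds <= 0:
            raise ValueError("population_size and tournament_rounds must be positive")
        for name in ("tournament_win_prob", "crossover_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.mutation_prob is not None and not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.operators not in ("real", "binary"):
            raise ValueError("operators must be 'real' or 'binary'")


def decode_and_repair(instance: ProblemInstance, keys: np.ndarray) -> Chromosome:
    """Decode keys to a selection, allocate, repair, and evaluate.

    Keys >= 0.5 select the facility.  An all-zero decode force-selects the
    argmax key.  After proximity allocation, every selected facility with
    zero allocated demand points is deselected and its key mapped below
    threshold; the allocation is unchanged because those facilities served
    nothing.
    """
    keys = np.asarray(keys, dtype=float)
    selection = keys >= 0.5
    if not selection.any():
        selection = selection.copy()
        selection[int(np.argmax(keys))] = True

    assignment = induce_allocation(instance, selection)
    counts = np.bincount(assignment, minlength=instance.n_facilities)
    unused = selection & (counts == 0)
    if unused.any():
        keys = keys.copy()
        keys[unused] = (keys[unused] - 0.5) * 0.999  # back below threshold
        selection = selection & ~unused

    y = contracts_from_selection(instance, selection)
    objectives = _objectives_from_assignment(instance, assignment, y)
    return Chromosome(
        keys=keys,
        selection=selection.astype(np.int8),
        allocation_counts=counts,
        assignment=assignment,
        objectives=objectives,
    )


def initialize_population(
    instance: ProblemInstance, config: EngineConfig, rng: np.random.Generator | None = None
) -> list[Chromosome]:
    """Stochastic initial population: independently uniform keys, each
    chromosome decoded, repaired and evaluated.  Deterministic per seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = instance.n_facilities
    if config.operators == "binary":
        all_keys = rng.integers(0, 2, size=(config.population_size, n)).astype(float)
    else:
        all_keys = rng.uniform(size=(config.population_size, n))
    pop = [decode_and_repair(instance, all_keys[i]) for i in range(config.population_size)]
    _assign_ranks_and_crowding(pop)
    return pop


def nondominated_sort(objectives: np.ndarray | Sequence[Sequence[float]]) -> list[np.ndarray]:
    """Sort objective pairs (minimization) into non-dominated fronts.

    a dominates b iff a <= b component-wise with at least one strict
    inequality; duplicates share a front.  Returns a list of index arrays,
    front 0 first.
    """
    F = np.asarray(objectives, dtype=float)
    if F.ndim != 2:
        raise ValueError("expected a 2-D array of objective vectors")
    if np.any(np.isnan(F)):
        raise ValueError("objective vectors contain NaN")
    n = len(F)
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dominates = le & lt  # dominates[a, b]: a dominates b

    n_dominators = dominates.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # defensive; cannot happen with a strict partial order
            raise RuntimeError("dominance relation is not acyclic")
        fronts.append(np.flatnonzero(current))
        remaining &= ~current
        n_dominators = dominates[remaining].sum(axis=0)
    return fronts


def crowding_distance(front_objectives: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Standard NSGA-II crowding distance for one front.

    Boundary points per objective get +inf; interior points accumulate the
    normalized gap between their neighbours in each objective's sorted order.
    A zero objective range contributes nothing.
    """
    F = np.asarray(front_objectives, dtype=float)
    n = len(F)
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for m in range(F.shape[1]):
        order = np.argsort(F[:, m], kind="stable")
        vals = F[order, m]
        rng_m = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng_m > 0:
            gaps = (vals[2:] - vals[:-2]) / rng_m
            interior = order[1:-1]
            finite = ~np.isinf(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _assign_ranks_and_crowding(pop: list[Chromosome]) -> list[np.ndarray]:
    objs = np.array([c.objectives for c in pop])
    fronts = nondominated_sort(objs)
    for r, front in enumerate(fronts):
        cd = crowding_distance(objs[front])
        for pos, idx in enumerate(front):
            pop[idx].rank = r
            pop[idx].crowding = float(cd[pos])
    return fronts


def _tournament(pop: list[Chromosome], rng: np.random.Generator, win_prob: float) -> Chromosome:
    i, j = rng.integers(0, len(pop), size=2)
    a, b = pop[int(i)], pop[int(j)]
    better, worse = (a, b) if (a.rank, -a.crowding) <= (b.rank, -b.crowding) else (b, a)
    return better if rng.uniform() < win_prob else worse


def _sbx_pair(
    k1: np.ndarray, k2: np.ndarray, eta: float, prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover on [0, 1]-bounded keys."""
    c1, c2 = k1.copy(), k2.copy()
    if rng.uniform() > prob:
        return c1, c2
    do = rng.uniform(size=len(k1)) < 0.5
    u = rng.uniform(size=len(k1))
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    mean = 0.5 * (k1 + k2)
    half = 0.5 * beta * np.abs(k1 - k2)
    c1[do] = np.clip(mean - half, 0.0, 1.0)[do]
    c2[do] = np.clip(mean + half, 0.0, 1.0)[do]
    return c1, c2


def _poly_mutate(
    keys: np.ndarray, eta: float, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Polynomial mutation on [0, 1]-bounded keys."""
    out = keys.copy()
    do = rng.uniform(size=len(keys)) < prob
    if not do.any():
        return out
    x = out[do]
    u = rng.uniform(size=x.size)
    lo = (2 * u) ** (1 / (eta + 1)) - 1  # u < 0.5 branch, delta in [-1, 0]
    hi = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
    # bounded form: scale the perturbation by the distance to the nearer bound
    delta = np.where(u < 0.5, lo * x, hi * (1 - x))
    out[do] = np.clip(x + delta, 0.0, 1.0)
    return out


def _binary_cross(
    k1: np.ndarray, k2: np.ndarray, prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = k1.copy(), k2.copy()
    if rng.uniform() > prob:
        return c1, c2
    swap = rng.uniform(size=len(k1)) < 0.5
    c1[swap], c2[swap] = k2[swap], k1[swap]
    return c1, c2


def _binary_mutate(keys: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    out = keys.copy()
    flip = rng.uniform(size=len(keys)) < prob
    out[flip] = 1.0 - out[flip]
    return out


def evolve(
    instance: ProblemInstance,
    config: EngineConfig,
    *,
    history: list | None = None,
) -> ParetoSet:
    """Run the (mu + lambda) NSGA-II loop and return the final first front.

    The returned front is deduplicated by repaired selection vector (first
    occurrence wins) and is deterministic per (instance, config, seed).  If
    ``history`` is a list, one record per generation is appended with the
    front size, best objectives and the rank-0 hypervolume against a
    reference point fixed from the initial population.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(instance, config, rng)
    n = instance.n_facilities
    mut_prob = config.mutation_prob if config.mutation_prob is not None else 1.0 / n

    hv_ref: np.ndarray | None = None
    if history is not None:
        objs0 = np.array([c.objectives for c in pop])
        hv_ref = objs0.max(axis=0) * 1.0 + 1e-9
        _log_generation(history, 0, pop, hv_ref)

    for gen in range(1, config.generations + 1):
        winners = [_tournament(pop, rng, config.tournament_win_prob)
                   for _ in range(config.tournament_rounds)]
        offspring: list[Chromosome] = []
        for t in range(0, len(winners) - 1, 2):
            p1, p2 = winners[t], winners[t + 1]
            if config.operators == "binary":
                k1, k2 = _binary_cross(p1.keys, p2.keys, config.crossover_prob, rng)
                k1 = _binary_mutate(k1, mut_prob, rng)
                k2 = _binary_mutate(k2, mut_prob, rng)
            else:
                k1, k2 = _sbx_pair(
                    p1.keys, p2.keys, config.crossover_index, config.crossover_prob, rng
                )
                k1 = _poly_mutate(k1, config.mutation_index, mut_prob, rng)
                k2 = _poly_mutate(k2, config.mutation_index, mut_prob, rng)
            offspring.append(decode_and_repair(instance, k1))
            offspring.append(decode_and_repair(instance, k2))
        if len(winners) % 2:
            keys = winners[-1].keys
            if config.operators == "binary":
                keys = _binary_mutate(keys, mut_prob, rng)
            else:
                keys = _poly_mutate(keys, config.mutation_index, mut_prob, rng)
            offspring.append(decode_and_repair(instance, keys))

        combined = pop + offspring
        objs = np.array([c.objectives for c in combined])
        fronts = nondominated_sort(objs)
        new_pop: list[Chromosome] = []
        for r, front in enumerate(fronts):
            cd = crowding_distance(objs[front])
            for pos, idx in enumerate(front):
                combined[idx].rank = r
                combined[idx].crowding = float(cd[pos])
            members = [combined[i] for i in front]
            if len(new_pop) + len(members) <= config.population_size:
                new_pop.extend(members)
            else:
                members.sort(key=lambda c: -c.crowding)
                new_pop.extend(members[: config.population_size - len(new_pop)])
                break
        pop = new_pop
        if history is not None:
            _log_generation(history, gen, pop, hv_ref)

    first = [c for c in pop if c.rank == 0]
    seen: set[tuple] = set()
    unique: list[Chromosome] = []
    for c in first:
        key = tuple(int(v) for v in c.selection)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return ParetoSet(plans=tuple(c.plan(instance) for c in unique))


def _log_generation(
    history: list, gen: int, pop: list[Chromosome], hv_ref: np.ndarray | None
) -> None:
    front_objs = np.array([c.objectives for c in pop if c.rank == 0])
    record = {
        "generation": gen,
        "front_size": len(front_objs),
        "best_f1": float(front_objs[:, 0].min()),
        "best_f2": float(front_objs[:, 1].min()),
    }
    if hv_ref is not None:
        record["hypervolume"] = hypervolume_2d(front_objs, tuple(hv_ref))
    history.append(record)
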