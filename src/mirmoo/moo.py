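"""Multi-objective evolutionary engine (NSGA-II) over binary miRNA subsets.

Solutions are fixed-length bit strings selecting a miRNA subset; all
objectives are minimised. The engine provides Pareto dominance, fast
non-dominated sorting, crowding distance, scattered crossover, uniform
bit-flip mutation, binary-tournament selection by (rank, crowding), and an
elitist generational loop with a spread-based stopping rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


class MooError(ValueError):
    pass


@dataclass
class GAConfig:
    """Evolutionary search settings.

    Defaults mirror the reference configuration: population 100, scattered
    crossover at 0.8, uniform mutation at 0.01, at most 50 generations,
    stopping early when the average change in Pareto-front spread over the
    stall window drops below ``spread_tolerance``, and a rank-1 front capped
    at ``pareto_fraction`` of the population during environmental selection.
    """

    population_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    max_generations: int = 50
    spread_tolerance: float = 1e-4
    pareto_fraction: float = 0.2
    stall_window: int = 5
    init_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate", "pareto_fraction", "init_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MooError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 2 or self.max_generations < 1:
            raise MooError("population_size >= 2 and max_generations >= 1 required")


@dataclass
class ParetoFront:
    """Mutually non-dominated solutions with crowding distances."""

    bits: list[np.ndarray]
    objectives: np.ndarray  # (n_solutions, k)
    crowding: np.ndarray

    def __len__(self) -> int:
        return len(self.bits)

    def selected(self, candidate_ids: Sequence[str]) -> list[tuple[str, ...]]:
        ids = np.asarray(candidate_ids, dtype=object)
        return [tuple(ids[b.astype(bool)]) for b in self.bits]


def dominates(u, v) -> bool:
    """True iff u is component-wise <= v and strictly < in some component."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise MooError(f"objective dimension mismatch: {u.shape} vs {v.shape}")
    return bool(np.all(u <= v) and np.any(u < v))


def non_dominated_sort(objectives) -> list[list[int]]:
    """Partition a population into Pareto fronts (lists of indices).

    Standard fast non-dominated sort: front 1 is the non-dominated set of the
    whole population, front i+1 is non-dominated once fronts <= i are removed.
    """
    F = np.asarray(objectives, dtype=float)
    n = F.shape[0]
    if n == 0:
        raise MooError("empty population")
    # vectorised pairwise dominance matrix: dom[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt

    n_dominators = dom.sum(axis=0)
    fronts: list[list[int]] = []
    remaining = n_dominators.copy()
    current = np.flatnonzero(remaining == 0)
    assigned = np.zeros(n, dtype=bool)
    while current.size:
        fronts.append(current.tolist())
        assigned[current] = True
        remaining = remaining - dom[current].sum(axis=0)
        remaining[assigned] = -1
        current = np.flatnonzero(remaining == 0)
    return fronts


def crowding_distance(front_objectives) -> np.ndarray:
    """Deb crowding distance: boundary members +inf, interior members the sum
    over objectives of the neighbour gap normalised by the objective range.

    Zero-width objective ranges contribute nothing. Order of members does not
    affect the values assigned to them.
    """
    F = np.asarray(front_objectives, dtype=float)
    n, k = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(k):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        rng = fj[-1] - fj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if rng > 0:
            dist[order[1:-1]] += (fj[2:] - fj[:-2]) / rng
    return dist


def scattered_crossover(parent1: np.ndarray, parent2: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-bit random parent choice under a fresh uniform mask."""
    if parent1.shape != parent2.shape:
        raise MooError("parent length mismatch")
    mask = rng.random(parent1.shape[0]) < 0.5
    return np.where(mask, parent1, parent2).astype(np.int8)


def uniform_mutation(bits: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with the given probability; repair empties."""
    if not 0.0 <= rate <= 1.0:
        raise MooError("mutation rate must be in [0, 1]")
    flips = rng.random(bits.shape[0]) < rate
    out = np.where(flips, 1 - bits, bits).astype(np.int8)
    return repair(out, rng)


def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """An empty subset is invalid (1/FR undefined): set one random bit."""
    if bits.any():
        return bits
    out = bits.copy()
    out[rng.integers(bits.shape[0])] = 1
    return out


def _front_spread(front_objs: np.ndarray, prev_extremes: np.ndarray | None):
    """Spread = drift of per-objective extreme points + dispersion of the
    finite crowding distances. Only its generation-to-generation change is
    used by the stopping rule."""
    extremes = front_objs.min(axis=0)
    drift = 0.0 if prev_extremes is None else float(np.linalg.norm(extremes - prev_extremes))
    cd = crowding_distance(front_objs)
    finite = cd[np.isfinite(cd)]
    dispersion = float(finite.std()) if finite.size else 0.0
    return drift + dispersion, extremes


def evolve(
    evaluator: Callable[[np.ndarray], Sequence[float]],
    n_bits: int,
    config: GAConfig | None = None,
) -> tuple[ParetoFront, dict]:
    """Run the elitist NSGA-II loop and return the final rank-1 front.

    ``evaluator`` maps a bit vector to a minimised objective vector; it is
    memoised on the bit pattern, so deterministic evaluators are evaluated at
    most once per subset. History records per-generation best objectives and
    front spread. Fully reproducible under ``config.seed``.
    """
    cfg = config or GAConfig()
    if n_bits < 1:
        raise MooError("candidate list must be non-empty")
    rng = np.random.default_rng(cfg.seed)

    cache: dict[bytes, np.ndarray] = {}

    def evaluate(b: np.ndarray) -> np.ndarray:
        key = b.tobytes()
        got = cache.get(key)
        if got is None:
            try:
                got = np.asarray(evaluator(b), dtype=float)
            except Exception as exc:  # pragma: no cover - propagation path
                raise MooError(f"evaluator failed on subset {np.flatnonzero(b)}: {exc}") from exc
            cache[key] = got
        return got

    pop = [repair((rng.random(n_bits) < cfg.init_prob).astype(np.int8), rng)
           for _ in range(cfg.population_size)]
    objs = np.array([evaluate(b) for b in pop])

    history: dict = {"best": [], "spread": [], "n_evaluations": 0}
    front1_cap = math.ceil(cfg.pareto_fraction * cfg.population_size)
    prev_extremes = None
    spread_changes: list[float] = []
    prev_spread = None

    for gen in range(cfg.max_generations):
        fronts = non_dominated_sort(objs)
        ranks = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, fr in enumerate(fronts):
            ranks[fr] = r
            crowd[fr] = crowding_distance(objs[fr])

        def tournament() -> int:
            i, j = rng.integers(len(pop)), rng.integers(len(pop))
            if ranks[i] != ranks[j]:
                return i if ranks[i] < ranks[j] else j
            if crowd[i] != crowd[j]:
                return i if crowd[i] > crowd[j] else j
            return min(i, j)

        offspring = []
        for _ in range(cfg.population_size):
            p1, p2 = pop[tournament()], pop[tournament()]
            child = scattered_crossover(p1, p2, rng) if rng.random() < cfg.crossover_rate else p1.copy()
            offspring.append(uniform_mutation(child, cfg.mutation_rate, rng))

        comb_pop = pop + offspring
        comb_objs = np.vstack([objs, np.array([evaluate(b) for b in offspring])])

        # elitist environmental selection: fill by front rank, rank-1 capped
        # at pareto_fraction of the population, ties broken by crowding then
        # by lower index (deterministic)
        comb_fronts = non_dominated_sort(comb_objs)
        next_idx: list[int] = []
        for r, fr in enumerate(comb_fronts):
            room = cfg.population_size - len(next_idx)
            if room <= 0:
                break
            cap = min(room, front1_cap) if r == 0 else room
            if len(fr) <= cap:
                next_idx.extend(fr)
            else:
                cd = crowding_distance(comb_objs[fr])
                order = sorted(range(len(fr)), key=lambda t: (-cd[t], fr[t]))
                next_idx.extend(fr[t] for t in order[:cap])
        while len(next_idx) < cfg.population_size:  # refill if rank-1 cap starved the pool
            pool = [i for i in range(len(comb_pop)) if i not in set(next_idx)]
            next_idx.append(pool[0])

        pop = [comb_pop[i] for i in next_idx]
        objs = comb_objs[next_idx]

        best_front = non_dominated_sort(objs)[0]
        spread, prev_extremes = _front_spread(objs[best_front], prev_extremes)
        history["best"].append(objs[best_front].min(axis=0).tolist())
        history["spread"].append(spread)
        if prev_spread is not None:
            spread_changes.append(abs(spread - prev_spread))
        prev_spread = spread
        if (
            len(spread_changes) >= cfg.stall_window
            and float(np.mean(spread_changes[-cfg.stall_window:])) < cfg.spread_tolerance
        ):
            break

    history["n_evaluations"] = len(cache)
    history["n_generations"] = len(history["spread"])

    # final rank-1 front, deduplicated on bit pattern, capped per pareto_fraction
    fr1 = non_dominated_sort(objs)[0]
    seen: set[bytes] = set()
    uniq = []
    for i in fr1:
        key = pop[i].tobytes()
        if key not in seen:
            seen.add(key)
            uniq.append(i)
    f_objs = objs[uniq]
    cd = crowding_distance(f_objs)
    order = sorted(range(len(uniq)), key=lambda t: (-cd[t], uniq[t]))[:front1_cap]
    bits = [pop[uniq[t]].copy() for t in order]
    return ParetoFront(bits=bits, objectives=f_objs[order], crowding=cd[order]), history
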