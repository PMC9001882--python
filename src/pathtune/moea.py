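"""Constrained multiobjective differential evolution with spherical pruning.

A rand/1/bin differential-evolution loop with an external non-dominated
archive: every evaluated candidate is offered to the archive, archive
members re-enter the parent pool (external-archive elitism), constraints
are handled by feasibility dominance (a feasible solution beats any
infeasible one; infeasible solutions compare by total violation), and the
archive's spread is maintained by spherical pruning — normalized objective
vectors are binned into hyperspherical sectors and at most one
representative (the smallest-norm member) survives per sector.

The optimizer is fully deterministic given the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .objectives import DecisionSpace

__all__ = [
    "Individual",
    "Archive",
    "MOEAConfig",
    "MOEAResult",
    "dominates",
    "constrained_compare",
    "de_trial",
    "spherical_prune",
    "hypervolume",
    "run_moea",
]


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff objective vector ``a`` Pareto-dominates ``b`` (minimization)."""
    a = tuple(a)
    b = tuple(b)
    if len(a) != len(b):
        raise ValueError(f"objective vectors differ in length: {len(a)} vs {len(b)}")
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


@dataclass
class Individual:
    theta: np.ndarray
    objectives: Tuple[float, ...]
    violation: float = 0.0
    eval_id: int = -1
    pertinent: bool = True  # within the optional objective-space caps

    @property
    def feasible(self) -> bool:
        return self.violation == 0.0 and all(math.isfinite(v) for v in self.objectives)


def constrained_compare(a: Individual, b: Individual) -> int:
    """Deb's feasibility rules: -1 if ``a`` preferred, +1 if ``b``, 0 if neither."""
    if a.feasible and not b.feasible:
        return -1
    if b.feasible and not a.feasible:
        return 1
    if not a.feasible and not b.feasible:
        if a.violation < b.violation:
            return -1
        if b.violation < a.violation:
            return 1
        return 0
    if dominates(a.objectives, b.objectives):
        return -1
    if dominates(b.objectives, a.objectives):
        return 1
    return 0


# ---------------------------------------------------------------------------
# spherical pruning
# ---------------------------------------------------------------------------

def _normalize(obj_matrix: np.ndarray) -> np.ndarray:
    """Min–max normalize columns to the archive's ideal/nadir box."""
    ideal = obj_matrix.min(axis=0)
    nadir = obj_matrix.max(axis=0)
    span = nadir - ideal
    out = np.zeros_like(obj_matrix, dtype=float)
    ok = span > 0
    out[:, ok] = (obj_matrix[:, ok] - ideal[ok]) / span[ok]
    return out


def sector_index(v: np.ndarray, arcs: int) -> Tuple[int, ...]:
    """Hyperspherical sector of a normalized nonnegative objective vector.

    The m-1 angular coordinates of v are binned uniformly over [0, pi/2]
    into ``arcs`` divisions each.
    """
    m = v.size
    idx = []
    for k in range(m - 1):
        tail = float(np.linalg.norm(v[k + 1:]))
        ang = math.atan2(tail, float(v[k]))  # in [0, pi/2] for v >= 0
        j = int(ang / (math.pi / 2.0) * arcs)
        idx.append(min(j, arcs - 1))
    return tuple(idx)


def spherical_prune(members: Sequence[Individual], arcs: int) -> List[Individual]:
    """Keep at most one member per spherical sector (smallest normalized norm).

    Ties break on the smaller normalized norm, then the smaller eval_id.
    """
    if len(members) <= 1:
        return list(members)
    obj = np.array([m.objectives for m in members], dtype=float)
    norm_obj = _normalize(obj)
    best: Dict[Tuple[int, ...], Tuple[float, int, Individual]] = {}
    for member, v in zip(members, norm_obj):
        sec = sector_index(v, arcs)
        key = (float(np.linalg.norm(v)), member.eval_id)
        if sec not in best or key < best[sec][:2]:
            best[sec] = (key[0], key[1], member)
    kept = [entry[2] for entry in best.values()]
    kept.sort(key=lambda m: m.eval_id)
    return kept


# ---------------------------------------------------------------------------
# archive
# ---------------------------------------------------------------------------

@dataclass
class Archive:
    """External non-dominated store with capacity-triggered spherical pruning.

    Invariants: members are mutually non-dominated; if any feasible member
    exists, all members are feasible (an infeasible-only archive holds the
    single lowest-violation individual seen).
    """

    capacity: int = 100
    arcs: int = 50
    members: List[Individual] = field(default_factory=list)

    def add(self, cand: Individual) -> bool:
        """Offer a candidate; returns True if it entered the archive."""
        if not all(math.isfinite(v) for v in cand.objectives) and cand.violation == 0.0:
            return False
        has_feasible = any(m.feasible for m in self.members)
        if cand.feasible and not has_feasible:
            self.members = [cand]
            return True
        if not cand.feasible:
            if has_feasible:
                return False
            if not math.isfinite(cand.violation):
                return False
            if not self.members:
                self.members = [cand]
                return True
            if cand.violation < self.members[0].violation:
                self.members = [cand]
                return True
            return False
        for m in self.members:
            if dominates(m.objectives, cand.objectives) or tuple(m.objectives) == tuple(
                cand.objectives
            ):
                return False
        self.members = [
            m for m in self.members if not dominates(cand.objectives, m.objectives)
        ]
        self.members.append(cand)
        if len(self.members) > self.capacity:
            self.members = spherical_prune(self.members, self.arcs)
        return True

    def objective_matrix(self) -> np.ndarray:
        return np.array([m.objectives for m in self.members], dtype=float)

    def thetas(self) -> np.ndarray:
        return np.array([m.theta for m in self.members], dtype=float)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# differential evolution
# ---------------------------------------------------------------------------

def _repair_bounds(theta: np.ndarray, bounds: DecisionSpace) -> np.ndarray:
    """Reflect out-of-bounds coordinates back into the box, then clip."""
    lo = np.asarray(bounds.lower)
    up = np.asarray(bounds.upper)
    t = np.array(theta, float)
    for _ in range(8):  # repeated reflection for far-out points
        below = t < lo
        above = t > up
        if not (below.any() or above.any()):
            break
        t[below] = 2 * lo[below] - t[below]
        t[above] = 2 * up[above] - t[above]
    return np.clip(t, lo, up)


def de_trial(
    population: np.ndarray,
    index: int,
    F: float,
    CR: float,
    rng: np.random.Generator,
    bounds: DecisionSpace,
    mutant_pool: Optional[np.ndarray] = None,
) -> np.ndarray:
    """rand/1/bin trial vector for population member ``index``.

    The three mutation parents are drawn (distinct, excluding ``index``)
    from ``mutant_pool`` when given — population stacked with archive
    members — otherwise from the population itself.  Bounds are enforced
    by reflection; integer (copy-number) coordinates are rounded.
    """
    pool = population if mutant_pool is None else mutant_pool
    n_pool, dim = pool.shape
    if n_pool < 4:
        raise ValueError("mutation pool must hold at least 4 distinct members")
    candidates = [j for j in range(n_pool) if j != index]
    r1, r2, r3 = rng.choice(len(candidates), size=3, replace=False)
    x1, x2, x3 = (pool[candidates[r]] for r in (r1, r2, r3))
    mutant = x1 + F * (x2 - x3)
    cross = rng.random(dim) < CR
    cross[rng.integers(dim)] = True  # at least one mutated coordinate
    trial = np.where(cross, mutant, population[index])
    trial = _repair_bounds(trial, bounds)
    return bounds.round_integers(trial)


# ---------------------------------------------------------------------------
# hypervolume (minimization, exact, small fronts)
# ---------------------------------------------------------------------------

def _nondominated(points: List[Tuple[float, ...]]) -> List[Tuple[float, ...]]:
    kept = []
    for p in points:
        if any(dominates(q, p) or q == p for q in kept):
            continue
        kept = [q for q in kept if not dominates(p, q)]
        kept.append(p)
    return kept


def hypervolume(points: Sequence[Sequence[float]], ref: Sequence[float]) -> float:
    """Exact dominated hypervolume of a minimization front w.r.t. ``ref``.

    Recursive slicing on the first objective; adequate for the archive
    sizes used here (hundreds of points, 2–3 objectives).
    """
    ref = tuple(float(r) for r in ref)
    pts = [tuple(float(v) for v in p) for p in points]
    pts = [p for p in pts if all(v < r for v, r in zip(p, ref))]
    if not pts:
        return 0.0
    if len(ref) == 1:
        return ref[0] - min(p[0] for p in pts)
    if len(ref) == 2:
        # sorted sweep: O(n log n), no explicit dominance filtering needed
        pts.sort(key=lambda p: (p[0], p[1]))
        total = 0.0
        best_j2 = ref[1]
        for j1, j2 in pts:
            if j2 < best_j2:
                total += (ref[0] - j1) * (best_j2 - j2)
                best_j2 = j2
        return total
    pts = _nondominated(pts)
    pts.sort(key=lambda p: p[0])
    total = 0.0
    for k, p in enumerate(pts):
        upper = pts[k + 1][0] if k + 1 < len(pts) else ref[0]
        width = upper - p[0]
        if width <= 0:
            continue
        slab = [q[1:] for q in pts[: k + 1]]
        total += width * hypervolume(slab, ref[1:])
    return total


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MOEAConfig:
    population_size: int = 20
    generations: int = 50
    F: float = 0.8
    CR: float = 0.9
    max_evaluations: Optional[int] = None
    seed: int = 0
    arcs: int = 50
    capacity: int = 100
    archive_parent: bool = True   # archive members join the mutation pool
    hv_ref: Optional[Tuple[float, ...]] = None  # fixed hypervolume reference
    # pertinency bounds in objective space: solutions with any objective at
    # or above its cap are kept in the log but never archived
    objective_caps: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("differential evolution needs a population of >= 4")
        if not 0.0 < self.F <= 2.0:
            raise ValueError("F must be in (0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")


@dataclass
class MOEAResult:
    archive: Archive
    log: pd.DataFrame
    config: MOEAConfig
    seed: int
    n_evaluations: int
    hv_history: List[float] = field(default_factory=list)
    archive_history: List[np.ndarray] = field(default_factory=list)
    objective_names: Tuple[str, ...] = ()

    def archive_frame(self) -> pd.DataFrame:
        """Final archive as a tidy table (one row per stored design)."""
        rows = []
        names = self.log.attrs["theta_names"]
        for m in sorted(self.archive.members, key=lambda m: m.eval_id):
            row = {"solution_id": m.eval_id}
            row.update({f"theta_{n}": v for n, v in zip(names, m.theta)})
            row.update(
                {n: v for n, v in zip(self.objective_names, m.objectives)}
            )
            row["violation"] = m.violation
            row["feasible"] = m.feasible
            rows.append(row)
        return pd.DataFrame(rows)


def _theta_key(theta: np.ndarray) -> Tuple[str, ...]:
    return tuple(f"{v:.12g}" for v in theta)


def run_moea(problem, config: MOEAConfig) -> MOEAResult:
    """Run the archive-assisted differential-evolution loop on a MOP.

    ``problem`` exposes ``bounds`` (a :class:`DecisionSpace`),
    ``objective_names`` and ``evaluate(theta) -> (objectives, violation)``.
    Evaluations are cached on theta rounded to 12 significant digits, so
    revisited candidates cost nothing and stay deterministic.

    ``hv_history`` records, per generation, the hypervolume of the
    cumulative non-dominated front of all feasible evaluations (a
    non-decreasing convergence measure) when ``config.hv_ref`` is set.
    """
    bounds: DecisionSpace = problem.bounds
    budget = config.max_evaluations
    if budget is not None and budget < config.population_size:
        raise ValueError("evaluation budget smaller than the population size")

    rng = np.random.default_rng(config.seed)
    dim = len(bounds)
    lo = np.asarray(bounds.lower)
    up = np.asarray(bounds.upper)

    cache: Dict[Tuple[str, ...], Tuple[Tuple[float, ...], float]] = {}
    log_rows: List[dict] = []
    eval_counter = 0
    # non-dominated set of every feasible evaluation: the run's best known
    # front approximation (unbounded; the working archive below is the
    # capacity-limited store used during evolution)
    cumulative_front: List[Individual] = []

    def evaluate(theta: np.ndarray, gen: int) -> Individual:
        nonlocal eval_counter, cumulative_front
        key = _theta_key(theta)
        if key in cache:
            objs, viol = cache[key]
            return Individual(theta.copy(), objs, viol, eval_id=-1)
        objs, viol = problem.evaluate(theta)
        objs = tuple(float(v) for v in objs)
        viol = float(viol)
        ind = Individual(theta.copy(), objs, viol, eval_id=eval_counter)
        cache[key] = (objs, viol)
        row = {"eval_id": eval_counter, "generation": gen}
        row.update({f"theta_{n}": float(v) for n, v in zip(bounds.names, theta)})
        row.update({n: v for n, v in zip(problem.objective_names, objs)})
        row["violation"] = viol
        row["feasible"] = ind.feasible
        log_rows.append(row)
        eval_counter += 1
        if config.objective_caps is not None:
            if any(v >= cap for v, cap in zip(objs, config.objective_caps)):
                ind.pertinent = False  # logged, but never archived
        if ind.feasible and ind.pertinent:
            p = objs
            if not any(
                dominates(q.objectives, p) or q.objectives == p
                for q in cumulative_front
            ):
                cumulative_front = [
                    q for q in cumulative_front if not dominates(p, q.objectives)
                ] + [ind]
        return ind

    archive = Archive(capacity=config.capacity, arcs=config.arcs)

    # initial population, uniform in the box
    population: List[Individual] = []
    init = lo + rng.random((config.population_size, dim)) * (up - lo)
    for i in range(config.population_size):
        theta = bounds.round_integers(init[i])
        ind = evaluate(theta, gen=0)
        population.append(ind)
        if ind.pertinent:
            archive.add(ind)

    hv_history: List[float] = []
    archive_history: List[np.ndarray] = []

    def close_generation() -> None:
        if config.hv_ref is not None:
            hv_history.append(
                hypervolume([q.objectives for q in cumulative_front], config.hv_ref)
            )
        archive_history.append(archive.objective_matrix())

    close_generation()

    any_success = any(
        all(math.isfinite(v) for v in ind.objectives) for ind in population
    )

    for gen in range(1, config.generations + 1):
        if budget is not None and eval_counter >= budget:
            break
        pop_thetas = np.array([ind.theta for ind in population])
        if config.archive_parent and len(archive) > 0:
            pool = np.vstack([pop_thetas, archive.thetas()])
        else:
            pool = pop_thetas
        for i in range(config.population_size):
            if budget is not None and eval_counter >= budget:
                break
            trial_theta = de_trial(
                pop_thetas, i, config.F, config.CR, rng, bounds, mutant_pool=pool
            )
            trial = evaluate(trial_theta, gen)
            if all(math.isfinite(v) for v in trial.objectives):
                any_success = True
            if trial.pertinent:
                archive.add(trial)
            if constrained_compare(trial, population[i]) < 0:
                population[i] = trial
        close_generation()

    if not any_success:
        raise RuntimeError("every candidate evaluation failed; no archive produced")

    # the returned archive is the capacity-pruned cumulative front: globally
    # non-dominated over the whole run, not just among surviving members
    if cumulative_front:
        final = list(cumulative_front)
        if len(final) > config.capacity:
            final = spherical_prune(final, config.arcs)
        archive.members = sorted(final, key=lambda m: m.eval_id)

    log = pd.DataFrame(log_rows)
    log.attrs["theta_names"] = tuple(bounds.names)
    return MOEAResult(
        archive=archive,
        log=log,
        config=config,
        seed=config.seed,
        n_evaluations=eval_counter,
        hv_history=hv_history,
        archive_history=archive_history,
        objective_names=tuple(problem.objective_names),
    )
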