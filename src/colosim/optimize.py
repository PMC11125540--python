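"""Schedule-space search.

Exhaustive enumeration and brute force for up to two colonoscopies, Kung's
divide-and-conquer non-dominated filter over the four objectives, and an
archive-based mixed-integer metaheuristic (ant-colony/evolutionary style
proposals with constraint repair) for three and four colonoscopies.

All candidate schedules are scored by a :class:`ScheduleEvaluator`, which
replays them against shared presimulated replicate cohorts (common random
numbers) and ranks by the median objective across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .engine import presimulate, replay_cohort
from .outcomes import OBJECTIVE_NAMES, CohortOutcomes, ObjectiveVector, compute_objectives
from .params import ParamBundle, ValidationError
from .screening import MAX_AGE, MAX_COLONOSCOPIES, MIN_AGE, MIN_GAP, validate_schedule


def enumerate_schedules(k: int, min_age: int = MIN_AGE, max_age: int = MAX_AGE,
                        min_gap: int = MIN_GAP) -> list:
    """All valid k-colonoscopy schedules, lexicographically ordered."""
    if not 0 <= k <= MAX_COLONOSCOPIES:
        raise ValidationError(f"k must be in 0..{MAX_COLONOSCOPIES}")
    if k == 0:
        return [()]
    ages = range(min_age, max_age + 1)
    return [c for c in combinations(ages, k)
            if all(b - a >= min_gap for a, b in zip(c, c[1:]))]


# ---------------------------------------------------------------------------
# Evaluator (CRN replicate harness)
# ---------------------------------------------------------------------------


class ScheduleEvaluator:
    """Scores schedules against shared no-screening baselines.

    ``replicates`` independent cohorts are presimulated once (seeds derived
    from ``base_seed``); every schedule is replayed on all of them, so
    differences between schedules are paired at the person level.  Results
    are cached by schedule.
    """

    def __init__(self, bundle: ParamBundle, n: int = 200_000, replicates: int = 3,
                 base_seed: int = 0, colonoscopy=None, risk_scale: float = 1.0):
        self.bundle = bundle
        self.n = n
        self.replicates = replicates
        self.base_seed = base_seed
        self.colonoscopy = colonoscopy
        if risk_scale != 1.0:
            nh = bundle.natural_history.to_dict()
            from .params import NaturalHistoryParams

            nhp = NaturalHistoryParams.from_dict(nh)
            nhp.adenoma_init_rate = nhp.adenoma_init_rate * risk_scale
            self.bundle = ParamBundle(
                natural_history=nhp, colonoscopy=bundle.colonoscopy,
                costs=bundle.costs, life_table=bundle.life_table,
                guideline=bundle.guideline,
            )
        self._cohorts = None
        self._baselines = None
        self._cache: dict = {}
        self.evaluations = 0

    def seeds(self) -> list:
        return [self.base_seed + 1000 * r for r in range(self.replicates)]

    def _ensure_cohorts(self):
        if self._cohorts is None:
            self._cohorts = [presimulate(self.n, self.bundle, seed=s)
                             for s in self.seeds()]
            self._baselines = [
                CohortOutcomes.from_record(
                    replay_cohort(c, self.bundle, ()), c, self.bundle.costs)
                for c in self._cohorts
            ]

    @property
    def baselines(self):
        self._ensure_cohorts()
        return self._baselines

    def evaluate(self, schedule) -> "EvaluatedSchedule":
        ages = tuple(int(a) for a in schedule)
        if ages in self._cache:
            return self._cache[ages]
        validate_schedule(ages)
        self._ensure_cohorts()
        per_rep = []
        lyg = []
        outcomes = []
        for c, base in zip(self._cohorts, self._baselines):
            rec = replay_cohort(c, self.bundle, ages, colonoscopy=self.colonoscopy)
            o = CohortOutcomes.from_record(rec, c, self.bundle.costs)
            outcomes.append(o)
            per_rep.append(compute_objectives(o, base).as_array())
            lyg.append((base.lyl_raw - o.lyl_raw) / self.n * 1000.0)
        med = np.median(np.array(per_rep), axis=0)
        ev = EvaluatedSchedule(
            schedule=ages,
            objectives=ObjectiveVector(*med),
            per_replicate=np.array(per_rep),
            lyg_per_1000=float(np.median(lyg)),
            outcomes=outcomes,
            seeds=tuple(self.seeds()),
        )
        self._cache[ages] = ev
        self.evaluations += 1
        return ev


@dataclass
class EvaluatedSchedule:
    schedule: tuple
    objectives: ObjectiveVector
    per_replicate: np.ndarray = None
    lyg_per_1000: float = float("nan")
    outcomes: list = None
    seeds: tuple = ()

    def objective(self, name: str) -> float:
        return self.objectives.by_name(name)


# ---------------------------------------------------------------------------
# Brute force
# ---------------------------------------------------------------------------


@dataclass
class BruteForceResult:
    best: dict            # objective name -> EvaluatedSchedule
    landscape: list       # every EvaluatedSchedule, in enumeration order

    def to_frame(self):
        import pandas as pd

        rows = []
        for ev in self.landscape:
            row = {f"age_{i+1}": a for i, a in enumerate(ev.schedule)}
            for nm, v in zip(OBJECTIVE_NAMES, ev.objectives.as_array()):
                row[nm] = v
            row["lyg_per_1000"] = ev.lyg_per_1000
            rows.append(row)
        return pd.DataFrame(rows)


def brute_force_optimize(
    k: int,
    evaluator: ScheduleEvaluator,
    objectives=OBJECTIVE_NAMES,
    schedules=None,
) -> BruteForceResult:
    """Evaluate every valid schedule (k <= 2) and take per-objective argmaxes.

    Ties break to the lexicographically earliest schedule (enumeration
    order).  A restricted candidate list may be supplied (coarse grids,
    local refinement)."""
    if k > 2 and schedules is None:
        raise ValidationError("brute force is only supported for k <= 2; "
                              "use metaheuristic_search")
    cands = schedules if schedules is not None else enumerate_schedules(k)
    evaluated = [evaluator.evaluate(s) for s in cands]
    best = {}
    for name in objectives:
        idx = int(np.argmax([ev.objective(name) for ev in evaluated]))
        best[name] = evaluated[idx]
    return BruteForceResult(best=best, landscape=evaluated)


def refine_local(
    evaluator: ScheduleEvaluator,
    start: tuple,
    objective: str,
    radius: int = 3,
    max_rounds: int = 10,
) -> EvaluatedSchedule:
    """Hill-climb on the integer lattice around a schedule, until no
    neighbour improves the objective.  Moves are single-age shifts of up to
    ±radius and whole-schedule translations (the optima sit on diagonal
    ridges, which coordinate moves alone cannot follow)."""
    current = evaluator.evaluate(start)
    for _ in range(max_rounds):
        improved = False
        k = len(current.schedule)
        moves = []
        for i in range(k):
            for d in range(-radius, radius + 1):
                if d != 0:
                    shift = [0] * k
                    shift[i] = d
                    moves.append(shift)
        for d in range(-radius, radius + 1):
            if d != 0:
                moves.append([d] * k)
        neighbours = set()
        for shift in moves:
            cand = sorted(a + s for a, s in zip(current.schedule, shift))
            if not (MIN_AGE <= cand[0] and cand[-1] <= MAX_AGE):
                continue
            if any(b - a < MIN_GAP for a, b in zip(cand, cand[1:])):
                continue
            neighbours.add(tuple(cand))
        for nb in sorted(neighbours):
            ev = evaluator.evaluate(nb)
            if ev.objective(objective) > current.objective(objective):
                current = ev
                improved = True
        if not improved:
            break
    return current


# ---------------------------------------------------------------------------
# Kung's non-dominated filter
# ---------------------------------------------------------------------------


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Componentwise >= with at least one strict > (maximization)."""
    return bool(np.all(a >= b) and np.any(a > b))


def kung_front(points) -> list:
    """Indices of the non-dominated subset of ``points`` (maximization).

    Kung's divide-and-conquer: sort by the first coordinate descending,
    recursively filter halves, then drop bottom-half points dominated by the
    surviving top half.  Duplicate copies of a kept point are all retained.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return []
    order = np.lexsort(tuple(-pts[:, c] for c in range(pts.shape[1] - 1, -1, -1)))

    def front(idx):
        if len(idx) <= 1:
            return list(idx)
        mid = len(idx) // 2
        top = front(idx[:mid])
        bottom = front(idx[mid:])
        kept = []
        for j in bottom:
            if not any(dominates(pts[i], pts[j]) for i in top):
                kept.append(j)
        return top + kept

    return sorted(front(list(order)))


# ---------------------------------------------------------------------------
# Pareto archive + metaheuristic
# ---------------------------------------------------------------------------


@dataclass
class ParetoArchive:
    """Set of evaluated schedules with no internal domination."""

    members: list = field(default_factory=list)

    def insert(self, ev: EvaluatedSchedule) -> bool:
        v = ev.objectives.as_array()
        if any(tuple(m.schedule) == tuple(ev.schedule) for m in self.members):
            return False
        for m in self.members:
            if dominates(m.objectives.as_array(), v):
                return False
        self.members = [m for m in self.members
                        if not dominates(v, m.objectives.as_array())]
        self.members.append(ev)
        return True

    def best(self, objective: str) -> EvaluatedSchedule:
        return max(self.members, key=lambda m: m.objective(objective))

    def schedules(self) -> list:
        return [m.schedule for m in self.members]


def repair_schedule(ages, k: int, rng=None,
                    min_age: int = MIN_AGE, max_age: int = MAX_AGE,
                    min_gap: int = MIN_GAP) -> tuple:
    """Project an arbitrary integer age vector onto the feasible set:
    sort, clamp to [min_age, max_age], then push ages apart to restore the
    minimum gap (left-to-right, then right-to-left against the upper bound)."""
    a = sorted(int(round(x)) for x in ages)[:k]
    while len(a) < k:
        a.append(a[-1] + min_gap if a else min_age)
    a = [min(max(x, min_age), max_age) for x in a]
    for i in range(1, k):
        a[i] = max(a[i], a[i - 1] + min_gap)
    a[-1] = min(a[-1], max_age)
    for i in range(k - 2, -1, -1):
        a[i] = min(a[i], a[i + 1] - min_gap)
    a[0] = max(a[0], min_age)  # feasible for k <= 4 since span <= 70
    for i in range(1, k):
        a[i] = max(a[i], a[i - 1] + min_gap)
    return tuple(a)


def _random_schedule(k: int, rng: np.random.Generator) -> tuple:
    return repair_schedule(rng.integers(MIN_AGE, MAX_AGE + 1, size=k), k, rng)


def metaheuristic_search(
    k: int,
    evaluator: ScheduleEvaluator,
    iterations: int = 30,
    population: int = 10,
    seed: int = 0,
    sigma0: float = 8.0,
) -> ParetoArchive:
    """Archive-based multi-objective integer search for k in {3, 4}.

    Each generation proposes ``population`` age vectors by perturbing
    archive members (Gaussian integer steps whose scale decays over the
    run, an ant-colony-style intensification), repairs them onto the
    constraint set, evaluates them with the shared CRN evaluator, and
    updates the non-dominated archive.  Seed-reproducible; like any
    stochastic search it carries no optimality guarantee.
    """
    if iterations < 0 or population <= 0:
        raise ValidationError("budget must be positive")
    rng = np.random.default_rng(seed)
    archive = ParetoArchive()
    for _ in range(population):
        archive.insert(evaluator.evaluate(_random_schedule(k, rng)))
    for it in range(iterations):
        sigma = max(1.0, sigma0 * (1.0 - it / max(iterations, 1)))
        members = archive.members
        for _ in range(population):
            if members and rng.random() < 0.85:
                base = members[rng.integers(len(members))].schedule
            else:
                base = _random_schedule(k, rng)
            prop = np.array(base, dtype=float) + rng.normal(0.0, sigma, size=k)
            archive.insert(evaluator.evaluate(repair_schedule(prop, k, rng)))
    return archive


def balanced_solution(members: list) -> EvaluatedSchedule:
    """Archive member minimizing the maximum relative shortfall from the
    per-objective maxima (one defensible reading of a 'balanced' choice)."""
    arr = np.array([m.objectives.as_array() for m in members])
    best = arr.max(axis=0)
    scale = np.where(np.abs(best) > 1e-9, np.abs(best), 1.0)
    shortfall = (best[None, :] - arr) / scale[None, :]
    return members[int(np.argmin(shortfall.max(axis=1)))]
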