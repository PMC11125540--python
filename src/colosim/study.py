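"""High-level drivers that reproduce the study's headline searches.

These wrap the evaluator and search modules into the concrete experiment
recipes used by the acceptance tests and ``scripts/acceptance.py``: the
single-colonoscopy landscape, the pair search (coarse grid plus local
refinement), the metaheuristic searches for three and four exams, and the
life-years-gained comparison of fixed schedules.
"""

from __future__ import annotations

import numpy as np

from .optimize import (
    ScheduleEvaluator,
    brute_force_optimize,
    enumerate_schedules,
    metaheuristic_search,
    refine_local,
)
from .outcomes import OBJECTIVE_NAMES
from .params import ParamBundle


def shared_cohort_evaluator(base: ScheduleEvaluator,
                            colonoscopy) -> ScheduleEvaluator:
    """Evaluator with a colonoscopy-parameter override that reuses another
    evaluator's presimulated cohorts and no-screening baselines (the
    baseline arm performs no screening exams, so it is unaffected)."""
    base._ensure_cohorts()
    ev = ScheduleEvaluator(base.bundle, n=base.n, replicates=base.replicates,
                           base_seed=base.base_seed, colonoscopy=colonoscopy)
    ev._cohorts = base._cohorts
    ev._baselines = base._baselines
    return ev


def confirmation_evaluator(base: ScheduleEvaluator,
                           replicates: int = 8) -> ScheduleEvaluator:
    """Higher-replicate evaluator on fresh seeds, used to re-rank the top
    candidates of a search.  Flat near-optimal ridges make the low-replicate
    argmax wander; confirming finalists on independent replicates both cuts
    that noise and avoids the winner's-curse bias of re-using the seeds the
    search itself selected on."""
    return ScheduleEvaluator(base.bundle, n=base.n, replicates=replicates,
                             base_seed=base.base_seed + 500_000,
                             colonoscopy=base.colonoscopy)


def _neighbourhood(schedule: tuple, radius: int = 1) -> set:
    from .optimize import MAX_AGE, MIN_AGE, MIN_GAP

    out = {tuple(schedule)}
    k = len(schedule)
    for i in range(k):
        for d in range(-radius, radius + 1):
            cand = list(schedule)
            cand[i] += d
            cand.sort()
            if not (MIN_AGE <= cand[0] and cand[-1] <= MAX_AGE):
                continue
            if any(b - a < MIN_GAP for a, b in zip(cand, cand[1:])):
                continue
            out.add(tuple(cand))
    return out


def _translations(schedule: tuple, radius: int = 4) -> set:
    """Whole-schedule shifts — the near-optimal set lies on a diagonal
    ridge, so comparing translations directly beats noisy hill-climbing."""
    from .optimize import MAX_AGE, MIN_AGE

    out = set()
    for d in range(-radius, radius + 1):
        cand = [a + d for a in schedule]
        if MIN_AGE <= cand[0] and cand[-1] <= MAX_AGE:
            out.add(tuple(cand))
    return out


def _first_age_fan(schedule: tuple, down: int = 5, up: int = 2) -> set:
    """Variants moving only the first exam age, holding the rest fixed —
    pits candidate first ages against each other on the incumbent's shape."""
    from .optimize import MIN_AGE, MIN_GAP

    out = set()
    rest = schedule[1:]
    for d in range(-down, up + 1):
        f = schedule[0] + d
        if f < MIN_AGE or (rest and rest[0] - f < MIN_GAP):
            continue
        out.add((f,) + rest)
    return out


def _last_age_fan(schedule: tuple, down: int = 2, up: int = 5) -> set:
    """Variants moving only the last exam age (the other flat direction of
    the ridge)."""
    from .optimize import MAX_AGE, MIN_GAP

    out = set()
    head = schedule[:-1]
    for d in range(-down, up + 1):
        last = schedule[-1] + d
        if last > MAX_AGE or (head and last - head[-1] < MIN_GAP):
            continue
        out.add(head + (last,))
    return out


def _confirm(confirm_ev: ScheduleEvaluator, candidates, objective: str):
    evaluated = [confirm_ev.evaluate(s) for s in sorted(candidates)]
    return max(evaluated, key=lambda e: e.objective(objective))


def single_landscape(evaluator: ScheduleEvaluator, ages=range(20, 91),
                     confirm: ScheduleEvaluator | None = None) -> dict:
    """Evaluate every single-exam age; argmax per objective (median over
    replicates, ties to the earliest age).  With ``confirm``, the top ages
    are re-ranked on independent higher-replicate cohorts."""
    scheds = [(a,) for a in ages]
    evaluated = [evaluator.evaluate(s) for s in scheds]
    out = {"ages": list(ages), "evaluated": evaluated, "best": {}}
    for i, name in enumerate(OBJECTIVE_NAMES):
        vals = np.array([e.objectives.as_array()[i] for e in evaluated])
        out[name] = vals
        best = evaluated[int(np.argmax(vals))]
        if confirm is not None:
            order = np.argsort(-vals)[:7]
            cands = set()
            for j in order:
                cands |= _neighbourhood(evaluated[j].schedule, 1)
            best = _confirm(confirm, cands, name)
        out["best"][name] = best
    return out


def pair_search(evaluator: ScheduleEvaluator, coarse_step: int = 2,
                objectives=OBJECTIVE_NAMES,
                confirm: ScheduleEvaluator | None = None) -> dict:
    """Two-exam search: brute force on a coarse grid, hill-climbing
    refinement of each per-objective incumbent, then optional
    high-replicate confirmation of the leading candidates."""
    coarse = [s for s in enumerate_schedules(2)
              if (s[0] % coarse_step == 0) and (s[1] % coarse_step == 0)]
    res = brute_force_optimize(2, evaluator, objectives=objectives,
                               schedules=coarse)
    best = {}
    for name in objectives:
        i = OBJECTIVE_NAMES.index(name)
        vals = np.array([e.objectives.as_array()[i] for e in res.landscape])
        top = [res.landscape[j].schedule for j in np.argsort(-vals)[:6]]
        incumbents = [refine_local(evaluator, s, name, radius=2).schedule
                      for s in top[:3]]
        if confirm is not None:
            cands = set()
            for s in list(top) + incumbents:
                cands |= _neighbourhood(s, 1)
            for s in incumbents:
                cands |= _first_age_fan(s, down=3, up=3)
                cands |= _last_age_fan(s, down=3, up=3)
            best[name] = _confirm(confirm, cands, name)
        else:
            best[name] = max((evaluator.evaluate(s) for s in incumbents),
                             key=lambda e: e.objective(name))
    return {"coarse": res, "best": best}


def multi_search(k: int, evaluator: ScheduleEvaluator, seed: int,
                 iterations: int = 28, population: int = 12,
                 objectives=("dlyl",),
                 confirm: ScheduleEvaluator | None = None) -> dict:
    """Three-/four-exam search: archive metaheuristic (>= iterations x
    population evaluations), local verification of the incumbents, and
    optional high-replicate confirmation."""
    archive = metaheuristic_search(k, evaluator, iterations=iterations,
                                   population=population, seed=seed)
    best = {}
    for name in objectives:
        members = sorted(archive.members, key=lambda m: -m.objective(name))
        starts = [m.schedule for m in members[:3]]
        incumbents = [refine_local(evaluator, s, name, radius=3).schedule
                      for s in starts]
        if confirm is not None:
            polished = [refine_local(confirm, s, name, radius=2).schedule
                        for s in dict.fromkeys(incumbents)]
            cands = set()
            for s in polished:
                cands |= _neighbourhood(s, 1)
                cands |= _translations(s, 4)
                cands |= _first_age_fan(s, down=5, up=2)
                cands |= _last_age_fan(s, down=2, up=4)
            best[name] = _confirm(confirm, cands, name)
        else:
            best[name] = max((evaluator.evaluate(s) for s in incumbents),
                             key=lambda e: e.objective(name))
    return {"archive": archive, "best": best}


def lyg_per_1000(bundle: ParamBundle, schedules, n: int, replicates: int,
                 base_seed: int) -> dict:
    """Median life years gained per 1000 versus no screening for each
    schedule, on shared common-random-number cohorts."""
    ev = ScheduleEvaluator(bundle, n=n, replicates=replicates,
                           base_seed=base_seed)
    return {tuple(s): ev.evaluate(tuple(s)).lyg_per_1000 for s in schedules}


def top_region_centroid(values: np.ndarray, ages, delta: float = 1.0) -> float:
    """Value-weighted mean age over the near-optimal plateau (ages whose
    objective lies within ``delta`` points of the maximum, weighted by how
    close they come).  A noise-robust location statistic for directional
    comparisons of flat landscapes; ``delta`` must exceed the per-age
    Monte-Carlo noise for the statistic to be stable."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(list(ages), dtype=float)
    w = np.clip(values - (values.max() - delta), 0.0, None)
    return float(np.sum(ages * w) / np.sum(w))
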