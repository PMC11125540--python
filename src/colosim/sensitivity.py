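"""One-way sensitivity scans, bound scenarios, rank-sum testing and
risk-stratified (personalized) schedule optimization."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .optimize import (
    ScheduleEvaluator,
    brute_force_optimize,
    enumerate_schedules,
    metaheuristic_search,
    refine_local,
)
from .outcomes import OBJECTIVE_NAMES
from .params import (
    ColonoscopyParams,
    NaturalHistoryParams,
    ParamBundle,
    ValidationError,
)

log = logging.getLogger(__name__)

#: parameters supported by one-way scans; values are capped at 1 where the
#: underlying quantity is a probability.
SCAN_PARAMETERS = ("adenoma_risk", "detection", "adherence", "survival", "complications")
DEFAULT_MULTIPLIERS = (0.5, 0.75, 0.9, 1.0, 1.1, 1.25, 1.5)


def _rebundle(bundle: ParamBundle, nh=None, colo=None) -> ParamBundle:
    return ParamBundle(
        natural_history=nh if nh is not None else bundle.natural_history,
        colonoscopy=colo if colo is not None else bundle.colonoscopy,
        costs=bundle.costs, life_table=bundle.life_table,
        guideline=bundle.guideline,
    )


def apply_multiplier(bundle: ParamBundle, parameter: str, mult: float) -> ParamBundle:
    """Scaled copy of a bundle; probabilities are silently capped at 1."""
    if parameter not in SCAN_PARAMETERS:
        raise ValidationError(
            f"unknown scan parameter {parameter!r}; choose from {SCAN_PARAMETERS}")
    if mult <= 0:
        raise ValidationError("multiplier must be > 0")
    if parameter == "adenoma_risk":
        nh = NaturalHistoryParams.from_dict(bundle.natural_history.to_dict())
        nh.adenoma_init_rate = nh.adenoma_init_rate * mult
        return _rebundle(bundle, nh=nh)
    if parameter == "survival":
        nh = NaturalHistoryParams.from_dict(bundle.natural_history.to_dict())
        capped = np.minimum(nh.survival_5yr * mult, 1.0)
        if np.any(nh.survival_5yr * mult > 1.0):
            log.info("survival multiplier %.2f capped at 100%%", mult)
        nh.survival_5yr = capped
        return _rebundle(bundle, nh=nh)
    colo = ColonoscopyParams.from_dict(bundle.colonoscopy.to_dict())
    if parameter == "detection":
        scaled = colo.detection_sensitivity * mult
        if np.any(scaled > 1.0):
            log.info("detection multiplier %.2f capped at 100%%", mult)
        colo.detection_sensitivity = np.minimum(scaled, 1.0)
    elif parameter == "adherence":
        if colo.adherence * mult > 1.0:
            log.info("adherence multiplier %.2f capped at 100%%", mult)
        colo.adherence = min(colo.adherence * mult, 1.0)
    elif parameter == "complications":
        colo.complication_prob = {
            k: min(v * mult, 1.0) for k, v in colo.complication_prob.items()
        }
    return _rebundle(bundle, colo=colo)


@dataclass
class ScanSpec:
    parameter: str
    multipliers: tuple = DEFAULT_MULTIPLIERS
    objectives: tuple = OBJECTIVE_NAMES
    k: int = 1

    def __post_init__(self):
        if self.parameter not in SCAN_PARAMETERS:
            raise ValidationError(f"unknown scan parameter {self.parameter!r}")
        if any(m <= 0 for m in self.multipliers):
            raise ValidationError("multipliers must be > 0")


def _optimum_for(bundle, k, n, replicates, base_seed, objectives,
                 meta_budget=(30, 12)):
    """Per-objective optimal schedules for one bundle (brute force for
    k <= 2, metaheuristic + local refinement for k >= 3)."""
    ev = ScheduleEvaluator(bundle, n=n, replicates=replicates, base_seed=base_seed)
    out = {}
    if k <= 2:
        res = brute_force_optimize(k, ev, objectives=objectives)
        for name in objectives:
            out[name] = res.best[name]
    else:
        archive = metaheuristic_search(k, ev, iterations=meta_budget[0],
                                       population=meta_budget[1], seed=base_seed)
        for name in objectives:
            out[name] = refine_local(ev, archive.best(name).schedule, name)
    return out, ev


def one_way_scan(
    spec: ScanSpec,
    bundle: ParamBundle,
    n: int = 100_000,
    replicates: int = 3,
    base_seed: int = 0,
) -> list:
    """Optimal schedules per multiplier (includes the x1 baseline row).

    Returns a list of dict rows: multiplier, objective, schedule, value,
    replicate spread (min/max over replicates of the objective at the
    optimum).  The same seeds are used for every multiplier so the x1 row
    reproduces the baseline optimum exactly.
    """
    rows = []
    mults = sorted(set(spec.multipliers) | {1.0})
    for m in mults:
        scaled = apply_multiplier(bundle, spec.parameter, m)
        best, _ = _optimum_for(scaled, spec.k, n, replicates, base_seed,
                               spec.objectives)
        for name, evd in best.items():
            j = OBJECTIVE_NAMES.index(name)
            rows.append({
                "parameter": spec.parameter,
                "multiplier": m,
                "objective": name,
                "schedule": evd.schedule,
                "value": evd.objective(name),
                "replicate_min": float(evd.per_replicate[:, j].min()),
                "replicate_max": float(evd.per_replicate[:, j].max()),
            })
    return rows


# ---------------------------------------------------------------------------
# Bound scenarios
# ---------------------------------------------------------------------------


def survival_hazard_ratio(bundle: ParamBundle, hr: float) -> ParamBundle:
    """CRC mortality varied by a hazard ratio: per-stage 5-year survival S
    becomes S**hr (hazard-scale mapping of the death probability)."""
    if hr <= 0:
        raise ValidationError("hazard ratio must be > 0")
    nh = NaturalHistoryParams.from_dict(bundle.natural_history.to_dict())
    nh.survival_5yr = nh.survival_5yr ** hr
    return _rebundle(bundle, nh=nh)


def total_complication_scenario(bundle: ParamBundle, total: float) -> ParamBundle:
    """Rescale complication probabilities so their sum hits ``total``,
    preserving the perforation/bleeding/serosa-burn mix."""
    colo = ColonoscopyParams.from_dict(bundle.colonoscopy.to_dict())
    cur = sum(colo.complication_prob.values())
    f = 0.0 if cur == 0 else total / cur
    colo.complication_prob = {k: v * f for k, v in colo.complication_prob.items()}
    return _rebundle(bundle, colo=colo)


def cecal_intubation_scenario(bundle: ParamBundle, rate: float) -> ParamBundle:
    """Rescale the three landmark-passage probabilities uniformly so their
    product (the cecal intubation rate) hits ``rate``."""
    colo = ColonoscopyParams.from_dict(bundle.colonoscopy.to_dict())
    cur = colo.cecal_intubation_rate()
    f = (rate / cur) ** (1.0 / 3.0)
    colo.reach_prob_splenic = min(colo.reach_prob_splenic * f, 1.0)
    colo.reach_prob_hepatic = min(colo.reach_prob_hepatic * f, 1.0)
    colo.reach_prob_cecum = min(colo.reach_prob_cecum * f, 1.0)
    return _rebundle(bundle, colo=colo)


def bound_scenarios(
    bundle: ParamBundle,
    schedule: tuple,
    n: int = 100_000,
    replicates: int = 3,
    base_seed: int = 0,
    hazard_ratios=(0.39, 1.0, 2.0),
    complication_totals=(0.001, 0.015),
    intubation_rates=(0.70,),
) -> list:
    """Evaluate the named bound scenarios at a fixed schedule."""
    from .optimize import ScheduleEvaluator

    rows = []
    scenarios = [("baseline", bundle)]
    scenarios += [(f"survival_hr_{hr}", survival_hazard_ratio(bundle, hr))
                  for hr in hazard_ratios]
    scenarios += [(f"complications_{t}", total_complication_scenario(bundle, t))
                  for t in complication_totals]
    scenarios += [(f"intubation_{r}", cecal_intubation_scenario(bundle, r))
                  for r in intubation_rates]
    for name, b in scenarios:
        ev = ScheduleEvaluator(b, n=n, replicates=replicates, base_seed=base_seed)
        evd = ev.evaluate(schedule)
        base = ev.baselines
        rows.append({
            "scenario": name,
            "schedule": tuple(schedule),
            "mortality_reduction_pct": evd.objectives.mortality_reduction_pct,
            "incidence_reduction_pct": evd.objectives.incidence_reduction_pct,
            "dlyl_reduction_pct": evd.objectives.discounted_lyl_reduction_pct,
            "cost_reduction_pct": evd.objectives.cost_reduction_pct,
            "baseline_crc_deaths_per_1000":
                float(np.median([b_.crc_deaths / b_.n * 1000 for b_ in base])),
            "screened_crc_deaths_per_1000":
                float(np.median([o.crc_deaths / o.n * 1000 for o in evd.outcomes])),
            "complication_deaths":
                int(np.median([o.complication_deaths for o in evd.outcomes])),
        })
    return rows


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(a, b) -> tuple:
    """Two-sided rank-sum test of two replicate samples.

    Returns ``(W, p)`` where W is the rank-sum of the first sample.  Exact
    null enumeration is used for combined n <= 20 without ties; otherwise
    the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = np.unique(combined).size == combined.size
    if np.all(combined == combined[0]):
        w = float(stats.rankdata(combined)[: a.size].sum())
        return w, 1.0  # complete overlap
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U -> rank sum
    return w, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# Personalization
# ---------------------------------------------------------------------------


@dataclass
class RiskStratification:
    """High/low risk split with population-mean-1 multipliers.

    Solves ``f*m_high + (1-f)*m_low = 1`` and ``m_high = rr * m_low``.
    """

    risk_ratio: float
    high_fraction: float = 0.25
    m_low: float = field(init=False)
    m_high: float = field(init=False)

    def __post_init__(self):
        if self.risk_ratio <= 0 or not 0 < self.high_fraction < 1:
            raise ValidationError("invalid stratification")
        self.m_low = 1.0 / ((1.0 - self.high_fraction)
                            + self.high_fraction * self.risk_ratio)
        self.m_high = self.risk_ratio * self.m_low


def stratify_and_optimize(
    strat: RiskStratification,
    bundle: ParamBundle,
    k: int = 1,
    objectives=("dlyl",),
    n: int = 100_000,
    replicates: int = 3,
    base_seed: int = 0,
    by_sex: bool = False,
) -> dict:
    """Optimal schedules per risk group (adenoma initiation scaled by the
    group multiplier); optionally also per sex on the unscaled bundle."""
    out = {}
    for group, m in (("low", strat.m_low), ("high", strat.m_high)):
        scaled = apply_multiplier(bundle, "adenoma_risk", m)
        best, _ = _optimum_for(scaled, k, n, replicates, base_seed, objectives)
        out[group] = {name: evd.schedule for name, evd in best.items()}
    if by_sex:
        for sex_name, frac in (("female", 0.0), ("male", 1.0)):
            ev = ScheduleEvaluator(bundle, n=n, replicates=replicates,
                                   base_seed=base_seed)
            # sex-specific cohorts via dedicated evaluator
            ev._cohorts = None

            from .engine import presimulate as _presim, replay_cohort as _replay
            from .outcomes import CohortOutcomes as _CO

            cohorts = [_presim(n, bundle, seed=s, sex_fraction_male=frac)
                       for s in ev.seeds()]
            ev._cohorts = cohorts
            ev._baselines = [
                _CO.from_record(_replay(c, bundle, ()), c, bundle.costs)
                for c in cohorts
            ]
            if k <= 2:
                res = brute_force_optimize(k, ev, objectives=objectives)
                out[sex_name] = {nm: res.best[nm].schedule for nm in objectives}
            else:
                archive = metaheuristic_search(k, ev, seed=base_seed)
                out[sex_name] = {
                    nm: refine_local(ev, archive.best(nm).schedule, nm).schedule
                    for nm in objectives
                }
    return out
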