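"""Cohort-level outcome measures, objectives, per-1000 summaries and ICERs.

All screening effects are expressed relative to the paired no-screening arm
simulated on identical latent histories (common random numbers).  Life years
lost are measured against each person's own counterfactual other-cause death
quarter, so they capture exactly the years lost to CRC death and to fatal
procedure complications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .engine import CAUSE_COMPLICATION, CAUSE_CRC, Cohort, RawCohortRecord, discount_factors
from .params import MAX_Q, QPY, CostParams


def discount(amount: float, age_years: float, rate: float, anchor_age: float = 20.0) -> float:
    """Present value of ``amount`` accrued at ``age_years``.

    The factor is ``(1+rate)^-(age - anchor)``, clamped to 1 before the
    anchor age (flows before the anchor are not inflated).
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    exponent = max(age_years - anchor_age, 0.0)
    return amount / (1.0 + rate) ** exponent


def _life_year_tables(costs: CostParams) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (raw, discounted) life years lived by start of each quarter."""
    disc = discount_factors(costs.discount_rate_annual, costs.discount_anchor_age)
    raw = np.concatenate([[0.0], np.cumsum(np.full(MAX_Q, 1.0 / QPY))])
    dly = np.concatenate([[0.0], np.cumsum(disc / QPY)])
    return raw, dly


@dataclass
class CohortOutcomes:
    """Aggregated outcomes of one arm."""

    n: int
    schedule_ages: tuple
    crc_cases: int
    crc_deaths: int
    complication_deaths: int
    total_life_years: float
    discounted_life_years: float
    lyl_raw: float   # life years lost to CRC death and procedure deaths
    lyl_disc: float
    total_cost: float
    discounted_cost: float
    colonoscopies_screening: int
    colonoscopies_surveillance: int
    colonoscopies_diagnostic: int
    polypectomies: int
    complications: int

    @property
    def colonoscopies_total(self) -> int:
        return (self.colonoscopies_screening + self.colonoscopies_surveillance
                + self.colonoscopies_diagnostic)

    def per_1000(self, value: float) -> float:
        return value / self.n * 1000.0

    @classmethod
    def from_record(cls, rec: RawCohortRecord, cohort: Cohort,
                    costs: CostParams) -> "CohortOutcomes":
        raw_ly, disc_ly = _life_year_tables(costs)
        death_q = rec.death_q
        odq = cohort.other_death_q
        return cls(
            n=rec.n,
            schedule_ages=rec.schedule_ages,
            crc_cases=int((rec.dx_q >= 0).sum()),
            crc_deaths=int((rec.cause == CAUSE_CRC).sum()),
            complication_deaths=int((rec.cause == CAUSE_COMPLICATION).sum()),
            total_life_years=float(raw_ly[death_q].sum()),
            discounted_life_years=float(disc_ly[death_q].sum()),
            lyl_raw=float((raw_ly[odq] - raw_ly[death_q]).sum()),
            lyl_disc=float((disc_ly[odq] - disc_ly[death_q]).sum()),
            total_cost=float(rec.cost_raw.sum()),
            discounted_cost=float(rec.cost_disc.sum()),
            colonoscopies_screening=int(rec.colo_screen.sum()),
            colonoscopies_surveillance=int(rec.colo_surveillance.sum()),
            colonoscopies_diagnostic=int(rec.colo_diagnostic.sum()),
            polypectomies=int(rec.polypectomies.sum()),
            complications=int(rec.complications.sum()),
        )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n", "schedule_ages", "crc_cases", "crc_deaths",
            "complication_deaths", "total_life_years", "discounted_life_years",
            "lyl_raw", "lyl_disc", "total_cost", "discounted_cost",
            "colonoscopies_screening", "colonoscopies_surveillance",
            "colonoscopies_diagnostic", "polypectomies", "complications",
        )}


TREATMENT_CATEGORIES = ("initial", "followup", "terminal", "post_5y_zero")


def treatment_category(quarter: int, dx_q: int, death_q: int,
                       crc_death: bool, horizon_q: int = 20) -> str:
    """Treatment-cost category of one post-diagnosis quarter.

    Quarters run from diagnosis (inclusive) to death (exclusive).  Exactly
    one category applies, with precedence terminal (last 4 quarters before a
    CRC death) > initial (first 4 quarters after diagnosis) > follow-up;
    treatment stops ``horizon_q`` quarters after diagnosis.
    """
    if quarter < dx_q or quarter >= death_q:
        raise ValueError("quarter outside the diagnosis..death interval")
    if quarter >= dx_q + horizon_q:
        return "post_5y_zero"
    if crc_death and quarter >= death_q - 4:
        return "terminal"
    if quarter < dx_q + 4:
        return "initial"
    return "followup"


def accrue_costs(
    dx_q: int,
    death_q: int,
    dx_stage: int,
    crc_death: bool,
    costs: CostParams,
    procedure_quarters=(),
    polypectomy_quarters=(),
    complication_events=(),
) -> dict:
    """Cost ledger for one diagnosed person (pure reference implementation).

    Returns raw and discounted totals plus the per-quarter treatment
    category assignment; the engine's in-replay accrual follows the same
    rules (terminal > initial > follow-up, 5-year horizon, quarter-
    granularity discounting).  ``complication_events`` are (quarter, type)
    pairs.
    """
    disc = discount_factors(costs.discount_rate_annual, costs.discount_anchor_age)
    raw = 0.0
    dsc = 0.0
    categories = {}
    for t in range(dx_q, death_q):
        cat = treatment_category(t, dx_q, death_q, crc_death,
                                 costs.treatment_horizon_q)
        categories[t] = cat
        if cat == "post_5y_zero":
            continue
        idx = {"initial": 0, "followup": 1, "terminal": 2}[cat]
        amount = costs.treatment_cost[dx_stage - 1, idx]
        raw += amount
        dsc += amount * disc[min(t, MAX_Q - 1)]
    for t in procedure_quarters:
        raw += costs.colonoscopy_cost
        dsc += costs.colonoscopy_cost * disc[min(t, MAX_Q - 1)]
    for t in polypectomy_quarters:
        raw += costs.polypectomy_surcharge
        dsc += costs.polypectomy_surcharge * disc[min(t, MAX_Q - 1)]
    for t, ctype in complication_events:
        amount = costs.complication_cost[ctype]
        raw += amount
        dsc += amount * disc[min(t, MAX_Q - 1)]
    if not crc_death:
        raw += costs.death_unrelated_terminal_cost
        dsc += costs.death_unrelated_terminal_cost * disc[min(death_q, MAX_Q - 1)]
    return {"raw": raw, "discounted": dsc, "categories": categories}


OBJECTIVE_NAMES = ("mortality", "incidence", "dlyl", "cost")


@dataclass
class ObjectiveVector:
    """Percent reductions versus the no-screening arm (higher = better)."""

    mortality_reduction_pct: float
    incidence_reduction_pct: float
    discounted_lyl_reduction_pct: float
    cost_reduction_pct: float
    missing: tuple = field(default_factory=tuple)

    def as_array(self) -> np.ndarray:
        return np.array([
            self.mortality_reduction_pct,
            self.incidence_reduction_pct,
            self.discounted_lyl_reduction_pct,
            self.cost_reduction_pct,
        ])

    def by_name(self, name: str) -> float:
        return dict(zip(OBJECTIVE_NAMES, self.as_array()))[name]


def _reduction(baseline: float, screened: float) -> tuple[float, bool]:
    if baseline == 0:
        return math.nan, True
    return 100.0 * (baseline - screened) / baseline, False


def compute_objectives(screened: CohortOutcomes,
                       baseline: CohortOutcomes) -> ObjectiveVector:
    """Four percent-reduction objectives of a screened arm vs no screening.

    Life-years-lost includes CRC deaths and fatal procedure complications.
    A zero baseline component yields NaN and is listed in ``missing``.
    """
    if screened.n != baseline.n:
        raise ValueError("arms must have the same cohort size")
    vals = {}
    missing = []
    for name, b, s in (
        ("mortality", baseline.crc_deaths + baseline.complication_deaths,
         screened.crc_deaths + screened.complication_deaths),
        ("incidence", baseline.crc_cases, screened.crc_cases),
        ("dlyl", baseline.lyl_disc, screened.lyl_disc),
        ("cost", baseline.total_cost, screened.total_cost),
    ):
        v, miss = _reduction(b, s)
        vals[name] = v
        if miss:
            missing.append(name)
    return ObjectiveVector(
        mortality_reduction_pct=vals["mortality"],
        incidence_reduction_pct=vals["incidence"],
        discounted_lyl_reduction_pct=vals["dlyl"],
        cost_reduction_pct=vals["cost"],
        missing=tuple(missing),
    )


def summary_metrics(screened: CohortOutcomes, baseline: CohortOutcomes) -> dict:
    """Per-1000 effectiveness metrics of a screened arm."""
    n = screened.n
    lyg = baseline.lyl_raw - screened.lyl_raw
    dlyg = baseline.lyl_disc - screened.lyl_disc
    cases_prevented = baseline.crc_cases - screened.crc_cases
    colos = screened.colonoscopies_total
    out = {
        "lyg_per_1000": lyg / n * 1000.0,
        "dlyg_per_1000": dlyg / n * 1000.0,
        "colonoscopies_per_1000": colos / n * 1000.0,
        "colonoscopies_per_lyg": colos / lyg if lyg > 0 else math.nan,
        "colonoscopies_per_case_prevented": (
            colos / cases_prevented if cases_prevented > 0 else math.nan
        ),
    }
    return out


def icer(a: CohortOutcomes, b: CohortOutcomes) -> dict:
    """Incremental cost per discounted life year gained, strategy a vs b.

    ``a`` should save more discounted life years than ``b``; if not, the
    arms are swapped and the result flagged.  Negative values mean cost
    saving.  Equal effectiveness yields NaN with ``undefined=True``.
    """
    dly_a = b.lyl_disc - a.lyl_disc  # a saves this much more than b... relative to
    # common baseline: use lyl difference directly (lower lyl = more dLY saved)
    swapped = False
    if dly_a < 0:
        a, b = b, a
        dly_a = -dly_a
        swapped = True
    if dly_a == 0:
        return {"icer": math.nan, "undefined": True, "swapped": swapped}
    dcost = a.discounted_cost - b.discounted_cost
    return {"icer": dcost / dly_a, "undefined": False, "swapped": swapped}
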