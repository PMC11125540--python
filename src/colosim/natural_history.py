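"""Object-level disease engine: one person, one quarter at a time.

This is the reference implementation of the natural-history rules — adenoma
initiation, six-stage adenoma progression, the direct path from normal
mucosa, four-stage preclinical cancer with symptomatic detection, CRC and
other-cause death.  It steps a :class:`Person` through 3-month increments
and is deliberately simple and slow; large-cohort work goes through
:mod:`colosim.engine`, which draws whole trajectories at once from the same
Markov rules.  Tests verify the two routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import presimulate, replay_cohort
from .params import (
    CRC_DEATH_WINDOW_Q,
    MAX_Q,
    LifeTable,
    NaturalHistoryParams,
    ParamBundle,
    ValidationError,
)


@dataclass
class Adenoma:
    stage: int                 # 1..6, only ever increases
    location: int              # segment index into SEGMENTS
    age_initiated: int         # quarters
    speed: float = 1.0         # lesion growth-rate factor (mixture draw)
    removed: bool = False

    def is_advanced(self, boundary: int) -> bool:
        return self.stage > boundary


@dataclass
class Cancer:
    stage: int                 # 1..4 (I..IV)
    status: str                # preclinical / symptomatic / screen_detected
    origin: str                # adenoma_pathway / direct_path
    location: int
    age_initiated: int         # quarters
    age_diagnosed: int | None = None
    crc_death_age: int | None = None


@dataclass
class Person:
    id: int
    sex: int                   # 0 female, 1 male
    risk_multiplier: float
    age_q: int = 0
    adenomas: list = field(default_factory=list)
    cancers: list = field(default_factory=list)
    alive: bool = True
    age_death: int | None = None
    cause_death: str | None = None   # other / crc / complication
    next_colonoscopy_due: int | None = None
    procedure_log: list = field(default_factory=list)
    cost_raw: float = 0.0
    cost_disc: float = 0.0

    @property
    def diagnosed(self) -> bool:
        return any(c.age_diagnosed is not None for c in self.cancers)


def init_cohort(
    n: int,
    sex_fraction_male: float,
    params: NaturalHistoryParams,
    seed: int,
) -> list[Person]:
    """Persons at age 0, no lesions, i.i.d. mean-1 risk multipliers."""
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.Generator(np.random.MT19937(seed))
    sex = (rng.random(n) < sex_fraction_male).astype(int)
    sig = params.risk_heterogeneity_sigma
    if sig > 0:
        mult = rng.lognormal(params.risk_lognormal_mu(), sig, size=n)
    else:
        mult = np.ones(n)
    return [Person(id=i, sex=int(sex[i]), risk_multiplier=float(mult[i]))
            for i in range(n)]


def schedule_crc_death(
    cancer: Cancer, params: NaturalHistoryParams, rng: np.random.Generator
) -> Cancer:
    """Decide, at diagnosis, whether and when this cancer kills.

    With probability ``1 - survival_5yr[stage at diagnosis]`` a death
    quarter is drawn from the death-delay distribution.  The 5-year window
    is anchored at cancer initiation by default (a config switch anchors it
    at diagnosis, since published survival rates are diagnosis-based); under
    the initiation anchor a diagnosis falling outside the window means the
    cancer is no longer lethal.
    """
    stage = cancer.stage
    if rng.random() < params.survival_5yr[stage - 1]:
        return cancer
    delay = int(
        np.searchsorted(
            np.cumsum(params.crc_death_time_distribution), rng.random(), side="right"
        )
        + 1
    )
    dx = cancer.age_diagnosed if cancer.age_diagnosed is not None else cancer.age_initiated
    if params.death_window_anchor == "diagnosis":
        cancer.crc_death_age = dx + delay
        return cancer
    if dx >= cancer.age_initiated + CRC_DEATH_WINDOW_Q:
        return cancer  # window already closed
    death = max(cancer.age_initiated + delay, dx + 1)
    cancer.crc_death_age = min(death, cancer.age_initiated + CRC_DEATH_WINDOW_Q)
    return cancer


def _draw_location(params: NaturalHistoryParams, rng, direct: bool) -> int:
    p = params.direct_location_distribution() if direct else params.location_distribution
    return int(rng.choice(len(p), p=p))


def step_quarter(
    person: Person,
    params: NaturalHistoryParams,
    life_table: LifeTable,
    rng: np.random.Generator,
) -> Person:
    """Advance one 3-month increment of the natural history (no screening).

    Fixed event order within the quarter: (1) other-cause death,
    (2) adenoma initiation, (3) adenoma progression / transition to
    preclinical cancer, (4) direct-path cancer, (5) preclinical stage
    progression and symptomatic detection, (6) scheduled CRC death.
    """
    if not person.alive:
        raise ValidationError("cannot step a dead person")
    q = person.age_q

    # (1) other-cause death
    if rng.random() < life_table.q[person.sex, min(q, MAX_Q - 1)]:
        person.alive = False
        person.age_death = q
        person.cause_death = "other"
        return person

    # after diagnosis the person is under treatment: the disease process
    # stops (subsequent primaries are out of scope) and only the scheduled
    # CRC death and other-cause mortality remain in play
    if person.diagnosed:
        for ca in person.cancers:
            if ca.crc_death_age is not None and ca.crc_death_age <= q:
                person.alive = False
                person.age_death = q
                person.cause_death = "crc"
                return person
        person.age_q = q + 1
        return person

    # (2) adenoma initiation (Poisson hazard x individual risk)
    rate = params.adenoma_init_rate[person.sex, min(q, MAX_Q - 1)] * person.risk_multiplier
    for _ in range(rng.poisson(rate)):
        speed = float(params.progression_speed_values[
            rng.choice(params.progression_speed_values.shape[0],
                       p=params.progression_speed_probs)])
        person.adenomas.append(
            Adenoma(stage=1, location=_draw_location(params, rng, False),
                    age_initiated=q, speed=speed)
        )

    # (3) adenoma progression / adenoma -> preclinical cancer
    for ad in person.adenomas:
        if ad.removed or ad.stage > 6:
            continue
        c = min(params.adenoma_to_preclinical_prob[ad.stage - 1] * ad.speed, 0.98)
        if rng.random() < c:
            person.cancers.append(
                Cancer(stage=1, status="preclinical", origin="adenoma_pathway",
                       location=ad.location, age_initiated=q + 1)
            )
            ad.removed = True  # consumed by malignant transformation
        elif ad.stage < 6 and rng.random() < min(
                params.stage_progression_prob[ad.stage - 1] * ad.speed, 0.98):
            ad.stage += 1

    # (4) direct-path cancer from normal mucosa
    d_rate = params.direct_path_rate[person.sex, min(q, MAX_Q - 1)]
    for _ in range(rng.poisson(d_rate)):
        onset = int(rng.choice(4, p=params.stage_at_direct_onset)) + 1
        person.cancers.append(
            Cancer(stage=onset, status="preclinical", origin="direct_path",
                   location=_draw_location(params, rng, True), age_initiated=q + 1)
        )

    # (5) preclinical progression and symptomatic detection
    for ca in person.cancers:
        if ca.age_diagnosed is not None or ca.age_initiated > q:
            continue
        d = params.symptomatic_detection_prob[ca.stage - 1]
        if rng.random() < d:
            ca.status = "symptomatic"
            ca.age_diagnosed = q
            schedule_crc_death(ca, params, rng)
        elif ca.stage < 4 and rng.random() < params.preclinical_stage_progression_prob[ca.stage - 1]:
            ca.stage += 1

    # (6) scheduled CRC death
    for ca in person.cancers:
        if ca.crc_death_age is not None and ca.crc_death_age <= q:
            person.alive = False
            person.age_death = q
            person.cause_death = "crc"
            return person

    person.age_q = q + 1
    return person


def simulate_person(
    person: Person,
    params: NaturalHistoryParams,
    life_table: LifeTable,
    rng: np.random.Generator,
    max_q: int = MAX_Q,
) -> Person:
    """Step a person from the current age to death (no screening)."""
    while person.alive and person.age_q < max_q:
        step_quarter(person, params, life_table, rng)
    if person.alive:  # hard cap at age 100
        person.alive = False
        person.age_death = MAX_Q
        person.cause_death = "other"
    return person


def run_cohort(
    n: int,
    bundle: ParamBundle,
    schedule_ages: tuple = (),
    seed: int = 0,
    sex_fraction_male: float = 0.5,
):
    """Simulate a full cohort and return its :class:`RawCohortRecord`.

    Delegates to the vectorized two-phase engine; with an empty schedule no
    screening occurs but symptomatic diagnosis still does.  The presimulated
    cohort is returned alongside the record so paired (common-random-number)
    arms can be replayed against the same latent histories.
    """
    cohort = presimulate(n, bundle, seed=seed, sex_fraction_male=sex_fraction_male)
    record = replay_cohort(cohort, bundle, schedule_ages=schedule_ages)
    return cohort, record
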