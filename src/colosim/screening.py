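"""Colonoscopy intervention model.

Schedules, the per-procedure model (anatomical reach, per-lesion detection,
polypectomy, complications) and guideline surveillance.  The per-person
operations act on the object-level :class:`~colosim.natural_history.Person`;
cohort-scale screening goes through :func:`apply_screening`, which replays a
schedule over a presimulated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Cohort, RawCohortRecord, replay_cohort
from .natural_history import Person
from .params import (
    SEGMENT_REACH_LEVEL,
    ColonoscopyParams,
    ParamBundle,
    SurveillanceGuideline,
    ValidationError,
)

MIN_AGE, MAX_AGE, MIN_GAP, MAX_COLONOSCOPIES = 20, 90, 5, 4


@dataclass(frozen=True)
class Schedule:
    """Sorted integer screening ages with the study's constraint semantics:
    ages within [20, 90], pairwise gaps of at least 5 years, at most 4."""

    ages: tuple

    def __post_init__(self):
        object.__setattr__(self, "ages", tuple(int(a) for a in self.ages))

    def __len__(self):
        return len(self.ages)

    def __iter__(self):
        return iter(self.ages)


def validate_schedule(ages) -> Schedule:
    """Validate a list of ages, naming the violated constraint on failure."""
    ages = list(ages)
    for a in ages:
        if int(a) != a:
            raise ValidationError(f"screening age {a} is not an integer")
    ages = sorted(int(a) for a in ages)
    if len(ages) > MAX_COLONOSCOPIES:
        raise ValidationError(
            f"at most {MAX_COLONOSCOPIES} colonoscopies allowed, got {len(ages)}"
        )
    for a in ages:
        if not (MIN_AGE <= a <= MAX_AGE):
            raise ValidationError(
                f"screening age {a} outside allowed range [{MIN_AGE}, {MAX_AGE}]"
            )
    for x, y in zip(ages, ages[1:]):
        if y - x < MIN_GAP:
            raise ValidationError(
                f"gap between ages {x} and {y} is below the minimum of {MIN_GAP} years"
            )
    return Schedule(tuple(ages))


@dataclass
class ColonoscopyResult:
    """Findings of one exam, categorized for surveillance."""

    reach_level: int                     # 0..3 (3 = cecum reached)
    adenomas_detected: int = 0
    advanced_detected: int = 0
    cancer_detected: bool = False
    cancer_stage: int = 0
    polypectomy: bool = False
    complications: list = field(default_factory=list)
    fatal_complication: bool = False

    @property
    def findings_category(self) -> str:
        if self.cancer_detected:
            return "cancer_detected"
        if self.adenomas_detected >= 3 or self.advanced_detected > 0:
            return "3plus_or_advanced"
        if self.adenomas_detected >= 1:
            return "1_2_early"
        return "no_adenoma"


def perform_colonoscopy(
    person: Person,
    params: ColonoscopyParams,
    rng: np.random.Generator,
    boundary: int = 4,
) -> ColonoscopyResult:
    """One colonoscopy on an attending, alive person (object-level).

    Reach is drawn as sequential landmark-passage Bernoullis (rectum to
    cecum, truncated at the first failure); each lesion in a visualized
    segment is detected independently with its stage sensitivity.  Detected
    adenomas are removed; a detected preclinical cancer becomes
    screen-detected.  Complications may be fatal.
    """
    if not person.alive:
        raise ValidationError("cannot scope a dead person")
    reach = 0
    if rng.random() < params.reach_prob_splenic:
        reach = 1
        if rng.random() < params.reach_prob_hepatic:
            reach = 2
            if rng.random() < params.reach_prob_cecum:
                reach = 3
    res = ColonoscopyResult(reach_level=reach)

    for ad in person.adenomas:
        if ad.removed or SEGMENT_REACH_LEVEL[ad.location] > reach:
            continue
        if rng.random() < params.detection_sensitivity[ad.stage - 1]:
            ad.removed = True
            res.adenomas_detected += 1
            if ad.is_advanced(boundary):
                res.advanced_detected += 1
    res.polypectomy = res.adenomas_detected > 0

    for ca in person.cancers:
        if ca.age_diagnosed is not None or ca.age_initiated > person.age_q:
            continue
        if SEGMENT_REACH_LEVEL[ca.location] > reach:
            continue
        if rng.random() < params.cancer_detection_sensitivity:
            ca.status = "screen_detected"
            ca.age_diagnosed = person.age_q
            if not res.cancer_detected:
                res.cancer_detected = True
                res.cancer_stage = ca.stage

    mult = params.complication_polypectomy_multiplier if res.polypectomy else 1.0
    for ctype in ("perforation", "bleeding", "serosa_burn"):
        if rng.random() < min(params.complication_prob[ctype] * mult, 1.0):
            res.complications.append(ctype)
            if rng.random() < params.complication_fatality[ctype]:
                res.fatal_complication = True
                person.alive = False
                person.age_death = person.age_q
                person.cause_death = "complication"
                break
    person.procedure_log.append(("colonoscopy", person.age_q, res.findings_category))
    return res


def next_surveillance(
    result: ColonoscopyResult, guideline: SurveillanceGuideline,
    age_years: float | None = None,
) -> float | None:
    """Years until the next surveillance exam, or ``None`` to resume
    screening (clean exam, or past the surveillance stopping age)."""
    cat = result.findings_category
    if cat == "no_adenoma":
        return None
    if cat == "1_2_early":
        interval = guideline.interval_low_risk
    elif cat in ("3plus_or_advanced", "cancer_detected"):
        interval = guideline.interval_high_risk
    else:  # pragma: no cover - categories are closed
        raise ValidationError(f"unknown findings category {cat!r}")
    if age_years is not None and age_years + interval > guideline.stopping_age:
        return None
    return interval


def apply_screening(
    cohort: Cohort,
    schedule,
    bundle: ParamBundle,
    colonoscopy: ColonoscopyParams | None = None,
) -> RawCohortRecord:
    """Replay a validated screening schedule over a presimulated cohort.

    At each scheduled age an alive, undiagnosed person attends with the
    adherence probability (independent per invitation by default);
    surveillance overrides remaining screening invitations while active;
    screening, surveillance and diagnostic colonoscopies are logged
    separately.
    """
    sched = schedule if isinstance(schedule, Schedule) else validate_schedule(schedule)
    return replay_cohort(cohort, bundle, schedule_ages=sched.ages,
                         colonoscopy=colonoscopy)
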