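"""Vectorized cohort engine.

The engine works in two phases so that many screening schedules can be
evaluated cheaply against identical disease histories (common random
numbers):

1. :func:`presimulate` draws, once per cohort, every person's other-cause
   death quarter and the full latent trajectory of every lesion (adenoma
   stage-entry quarters, preclinical-cancer onset, cancer stage-entry
   quarters, symptomatic-detection quarter, survival and death-delay
   uniforms).  Because all transitions are Markov with geometric sojourns,
   drawing whole trajectories up front is distributionally identical to
   stepping quarter by quarter.

2. :func:`replay_cohort` walks one screening schedule over the frozen
   trajectories: exams remove detected adenomas (cancelling their downstream
   cancers), screen-detect preclinical cancers, draw complications and drive
   guideline surveillance.  All exam-level randomness comes from a
   counter-based hash of per-person/per-lesion keys, so two schedules see
   identical draws wherever their exam sequences coincide.

Costs and (discounted) life years are accrued inside the replay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    CRC_DEATH_WINDOW_Q,
    MAX_Q,
    QPY,
    SEGMENT_REACH_LEVEL,
    ParamBundle,
    ValidationError,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


INF_Q = 1_000_000  # "never happens" quarter sentinel


# ---------------------------------------------------------------------------
# Phase 1: latent natural-history trajectories
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Frozen latent disease histories for ``n`` persons."""

    n: int
    seed: int
    sex: np.ndarray            # (n,) 0 female / 1 male
    risk_mult: np.ndarray      # (n,)
    other_death_q: np.ndarray  # (n,)
    person_key: np.ndarray     # (n,) uint64

    lesion_start: np.ndarray   # (n+1,) CSR offsets into lesion arrays
    les_is_direct: np.ndarray  # (L,) uint8
    les_location: np.ndarray   # (L,)
    les_stage_entry: np.ndarray  # (L, 6) adenoma stage entry quarters
    les_cancer_q: np.ndarray     # (L,)
    les_c_entry: np.ndarray      # (L, 4) cancer stage entry quarters
    les_sympt_q: np.ndarray      # (L,)
    les_sympt_stage: np.ndarray  # (L,)
    les_u_surv: np.ndarray       # (L,)
    les_death_delay: np.ndarray  # (L,) 1..20
    les_key: np.ndarray          # (L,) uint64

    @property
    def n_lesions(self) -> int:
        return self.les_is_direct.shape[0]

    def adenoma_presence_at(self, quarter: int, boundary: int):
        """(has_early, has_advanced) boolean person arrays at a quarter,
        for the no-screening trajectory."""
        stage = (self.les_stage_entry <= quarter).sum(axis=1)
        is_adenoma = (
            (self.les_is_direct == 0)
            & (self.les_stage_entry[:, 0] <= quarter)
            & (self.les_cancer_q > quarter)
        )
        owner = np.repeat(
            np.arange(self.n), np.diff(self.lesion_start)
        )
        early = is_adenoma & (stage <= boundary) & (stage >= 1)
        adv = is_adenoma & (stage > boundary)
        has_early = np.bincount(owner[early], minlength=self.n) > 0
        has_adv = np.bincount(owner[adv], minlength=self.n) > 0
        return has_early, has_adv


def _sample_geometric(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    return rng.geometric(p, size=size).astype(np.int64)


def presimulate(
    n: int,
    bundle: ParamBundle,
    seed: int,
    sex: np.ndarray | None = None,
    risk_mult: np.ndarray | None = None,
    sex_fraction_male: float = 0.5,
) -> Cohort:
    """Draw a cohort of latent natural histories (no screening applied).

    The base generator is Mersenne-Twister seeded by ``seed``; identical
    ``(n, seed, bundle)`` give bit-identical cohorts.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    nh = bundle.natural_history
    lt = bundle.life_table
    rng = np.random.Generator(np.random.MT19937(seed))

    if sex is None:
        sex = (rng.random(n) < sex_fraction_male).astype(np.int8)
    else:
        sex = np.asarray(sex, dtype=np.int8)
    if risk_mult is None:
        sig = nh.risk_heterogeneity_sigma
        if sig > 0:
            risk_mult = rng.lognormal(nh.risk_lognormal_mu(), sig, size=n)
        else:
            risk_mult = np.ones(n)
    else:
        risk_mult = np.asarray(risk_mult, dtype=np.float64)

    other_death_q = lt.sample_death_quarter(sex, rng)
    person_key = rng.integers(0, 2**63 - 1, size=n, dtype=np.uint64)

    # --- adenoma initiations: per-person Poisson with sex-specific shape ---
    lam_sex = nh.adenoma_init_rate.sum(axis=1)  # (2,)
    mean_counts = risk_mult * lam_sex[sex]
    a_counts = rng.poisson(mean_counts)
    a_owner = np.repeat(np.arange(n), a_counts)
    a_total = int(a_counts.sum())
    a_init = np.zeros(a_total, dtype=np.int64)
    for s in (0, 1):
        m = sex[a_owner] == s
        k = int(m.sum())
        if k == 0:
            continue
        tot = lam_sex[s]
        if tot <= 0:
            continue
        cdf = np.cumsum(nh.adenoma_init_rate[s]) / tot
        a_init[m] = np.searchsorted(cdf, rng.random(k), side="right")
    a_loc = rng.choice(
        np.arange(8), size=a_total, p=nh.location_distribution
    ).astype(np.int8)
    # per-lesion growth-rate factor (slow/fast mixture)
    a_speed = nh.progression_speed_values[
        rng.choice(nh.progression_speed_values.shape[0], size=a_total,
                   p=nh.progression_speed_probs)
    ]

    # --- adenoma stage chain: geometric sojourns with cancer branching ---
    a_stage_entry = np.full((a_total, 6), INF_Q, dtype=np.int64)
    a_cancer_q = np.full(a_total, INF_Q, dtype=np.int64)
    if a_total:
        a_stage_entry[:, 0] = a_init
    t_cur = a_init.copy()
    active = np.ones(a_total, dtype=bool)
    for s in range(6):
        g = nh.stage_progression_prob[s] if s < 5 else 0.0
        c = nh.adenoma_to_preclinical_prob[s]
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        cl = np.minimum(c * a_speed[idx], 0.98)
        gl = np.minimum(g * a_speed[idx], 0.98)
        e = cl + (1.0 - cl) * gl
        stuck = e <= 0
        active[idx[stuck]] = False
        idx = idx[~stuck]
        if idx.size == 0:
            continue
        e = e[~stuck]
        cl = cl[~stuck]
        G = rng.geometric(e).astype(np.int64)
        exit_t = np.minimum(t_cur[idx] + G, INF_Q)
        to_cancer = rng.random(idx.size) < (cl / e)
        ci = idx[to_cancer]
        a_cancer_q[ci] = exit_t[to_cancer]
        active[ci] = False
        pi = idx[~to_cancer]
        if s < 5:
            a_stage_entry[pi, s + 1] = exit_t[~to_cancer]
            t_cur[pi] = exit_t[~to_cancer]
        else:
            active[pi] = False

    # --- direct-path cancers: Poisson from normal mucosa ---
    lam_d = nh.direct_path_rate.sum(axis=1)
    d_counts = rng.poisson(lam_d[sex])
    d_owner = np.repeat(np.arange(n), d_counts)
    d_total = int(d_counts.sum())
    d_onset = np.zeros(d_total, dtype=np.int64)
    for s in (0, 1):
        m = sex[d_owner] == s
        k = int(m.sum())
        if k == 0 or lam_d[s] <= 0:
            continue
        cdf = np.cumsum(nh.direct_path_rate[s]) / lam_d[s]
        d_onset[m] = np.searchsorted(cdf, rng.random(k), side="right")
    d_loc = rng.choice(
        np.arange(8), size=d_total, p=nh.direct_location_distribution()
    ).astype(np.int8)
    d_onset_stage = (
        rng.choice(np.arange(4), size=d_total, p=nh.stage_at_direct_onset) + 1
    ).astype(np.int64)

    # --- merge lesions, sort into per-person CSR blocks ---
    L = a_total + d_total
    is_direct = np.concatenate(
        [np.zeros(a_total, np.uint8), np.ones(d_total, np.uint8)]
    )
    owner = np.concatenate([a_owner, d_owner])
    location = np.concatenate([a_loc, d_loc])
    stage_entry = np.vstack(
        [a_stage_entry, np.full((d_total, 6), INF_Q, dtype=np.int64)]
    ) if L else np.zeros((0, 6), np.int64)
    cancer_q = np.concatenate([a_cancer_q, d_onset])
    onset_stage = np.concatenate(
        [np.ones(a_total, np.int64), d_onset_stage]
    )
    sort_key = np.minimum(
        stage_entry[:, 0] if L else np.zeros(0, np.int64), cancer_q
    )
    order = np.lexsort((sort_key, owner))
    is_direct, owner, location = is_direct[order], owner[order], location[order]
    stage_entry, cancer_q, onset_stage = (
        stage_entry[order], cancer_q[order], onset_stage[order]
    )

    # --- preclinical cancer course (stage progression vs symptomatic dx) ---
    c_entry = np.full((L, 4), INF_Q, dtype=np.int64)
    sympt_q = np.full(L, INF_Q, dtype=np.int64)
    sympt_stage = np.zeros(L, dtype=np.int8)
    has_cancer = cancer_q < INF_Q
    for s in range(4):
        fill = has_cancer & (onset_stage > s)
        c_entry[fill, s] = cancer_q[fill]
    cur = onset_stage.copy()
    t_c = cancer_q.copy()
    active = has_cancer.copy()
    for s in range(4):
        d = nh.symptomatic_detection_prob[s]
        g = nh.preclinical_stage_progression_prob[s] if s < 3 else 0.0
        e = d + (1.0 - d) * g
        idx = np.flatnonzero(active & (cur == s + 1))
        if idx.size == 0:
            continue
        if e <= 0:
            active[idx] = False
            continue
        G = _sample_geometric(rng, e, idx.size)
        succ = np.minimum(t_c[idx] + G - 1, INF_Q)
        detect = rng.random(idx.size) < (d / e)
        di = idx[detect]
        sympt_q[di] = succ[detect]
        sympt_stage[di] = s + 1
        active[di] = False
        pi = idx[~detect]
        if s < 3:
            c_entry[pi, s + 1] = np.minimum(succ[~detect] + 1, INF_Q)
            t_c[pi] = np.minimum(succ[~detect] + 1, INF_Q)
            cur[pi] = s + 2
        else:
            active[pi] = False

    u_surv = rng.random(L)
    delay_cdf = np.cumsum(nh.crc_death_time_distribution)
    delay_cdf[-1] = 1.0
    death_delay = (
        np.searchsorted(delay_cdf, rng.random(L), side="right") + 1
    ).astype(np.int64)
    les_key = rng.integers(0, 2**63 - 1, size=L, dtype=np.uint64)

    lesion_start = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(owner, minlength=n), out=lesion_start[1:])

    return Cohort(
        n=n, seed=seed, sex=sex, risk_mult=risk_mult,
        other_death_q=other_death_q.astype(np.int64), person_key=person_key,
        lesion_start=lesion_start, les_is_direct=is_direct,
        les_location=location, les_stage_entry=stage_entry,
        les_cancer_q=cancer_q, les_c_entry=c_entry, les_sympt_q=sympt_q,
        les_sympt_stage=sympt_stage, les_u_surv=u_surv,
        les_death_delay=death_delay, les_key=les_key,
    )


# ---------------------------------------------------------------------------
# Counter-based uniforms (splitmix64)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _u01(key, counter, purpose):
    h = _mix64(key ^ _mix64(np.uint64(counter) * np.uint64(0x9E3779B97F4A7C15)
                            ^ np.uint64(purpose) * np.uint64(0xC2B2AE3D27D4EB4F)))
    return (h >> np.uint64(11)) * (1.0 / 9007199254740992.0)


# ---------------------------------------------------------------------------
# Phase 2: schedule replay
# ---------------------------------------------------------------------------

CAUSE_OTHER, CAUSE_CRC, CAUSE_COMPLICATION = 0, 1, 2
MODE_NONE, MODE_SYMPTOMATIC, MODE_SCREEN = 0, 1, 2


@njit(cache=True)
def _replay_kernel(
    # persons
    other_death_q, person_key,
    # lesions (CSR)
    lesion_start, les_is_direct, les_location, les_stage_entry,
    les_cancer_q, les_c_entry, les_sympt_q, les_sympt_stage,
    les_u_surv, les_death_delay, les_key,
    # schedule & guideline (quarters)
    schedule_q, surv_low_q, surv_high_q, surv_stop_q,
    # colonoscopy params
    reach_probs, sens6, cancer_sens, comp_prob, comp_poly_mult, comp_fatal,
    adherence, per_person_adherence,
    # natural history
    survival_5yr, anchor_is_dx, boundary, seg_reach_level,
    # costs
    colo_cost, poly_cost, comp_cost, treat_cost, death_unrel_cost,
    disc_q, horizon_q,
    # outputs
    out_death_q, out_cause, out_dx_q, out_dx_stage, out_dx_mode,
    out_colo_screen, out_colo_surv, out_colo_diag,
    out_polypectomy, out_complications, out_adenomas_removed,
    out_cost_raw, out_cost_disc,
):
    n = other_death_q.shape[0]
    L = les_is_direct.shape[0]
    removed = np.zeros(L, dtype=np.uint8)
    k = schedule_q.shape[0]

    for p in range(n):
        odq = other_death_q[p]
        pk = person_key[p]
        l0, l1 = lesion_start[p], lesion_start[p + 1]

        attends_any = True
        if per_person_adherence == 1:
            attends_any = _u01(pk, 0, 99) < adherence

        sched_idx = 0
        exam_counter = 0
        invitation_counter = 0
        under_surv = False
        surv_next = INF_Q

        dx_q = -1
        dx_stage = 0
        dx_mode = MODE_NONE
        dx_les = -1
        death_q = odq
        cause = CAUSE_OTHER
        cost_raw = 0.0
        cost_disc = 0.0
        dead_by_complication = False

        while True:
            # next exam
            if under_surv:
                next_exam = surv_next
                is_surv = True
            else:
                next_exam = schedule_q[sched_idx] if sched_idx < k else INF_Q
                is_surv = False

            # earliest symptomatic diagnosis among live lesions
            s_q = INF_Q
            s_les = -1
            for j in range(l0, l1):
                if removed[j] == 0 and les_sympt_q[j] < s_q:
                    s_q = les_sympt_q[j]
                    s_les = j
            if s_q < next_exam and s_q < odq:
                dx_q = s_q
                dx_stage = les_sympt_stage[s_les]
                dx_mode = MODE_SYMPTOMATIC
                dx_les = s_les
                out_colo_diag[p] += 1
                cost_raw += colo_cost
                cost_disc += colo_cost * disc_q[min(s_q, MAX_Q - 1)]
                break

            if next_exam >= odq or next_exam >= INF_Q:
                break  # dies undiagnosed (other causes) or schedule exhausted

            e = next_exam
            if not is_surv:
                sched_idx += 1
                invitation_counter += 1
                if per_person_adherence == 1:
                    if not attends_any:
                        continue
                else:
                    if _u01(pk, invitation_counter, 1) >= adherence:
                        continue
            exam_counter += 1
            if is_surv:
                out_colo_surv[p] += 1
                under_surv = False
                surv_next = INF_Q
            else:
                out_colo_screen[p] += 1

            # anatomical reach
            reach_level = 0
            if _u01(pk, exam_counter, 2) < reach_probs[0]:
                reach_level = 1
                if _u01(pk, exam_counter, 3) < reach_probs[1]:
                    reach_level = 2
                    if _u01(pk, exam_counter, 4) < reach_probs[2]:
                        reach_level = 3

            # lesion inspection
            n_det_adenoma = 0
            n_det_advanced = 0
            det_cancer_les = -1
            det_cancer_stage = 0
            for j in range(l0, l1):
                if removed[j]:
                    continue
                if seg_reach_level[les_location[j]] > reach_level:
                    continue
                if les_is_direct[j] == 0 and les_stage_entry[j, 0] <= e < les_cancer_q[j]:
                    stage = 0
                    for s in range(6):
                        if les_stage_entry[j, s] <= e:
                            stage = s + 1
                    if _u01(les_key[j], exam_counter, 5) < sens6[stage - 1]:
                        removed[j] = 1
                        n_det_adenoma += 1
                        if stage > boundary:
                            n_det_advanced += 1
                elif les_cancer_q[j] <= e:
                    if _u01(les_key[j], exam_counter, 5) < cancer_sens:
                        cstage = 0
                        for s in range(4):
                            if les_c_entry[j, s] <= e:
                                cstage = s + 1
                        if det_cancer_les < 0:
                            det_cancer_les = j
                            det_cancer_stage = cstage

            did_polypectomy = n_det_adenoma > 0
            out_adenomas_removed[p] += n_det_adenoma
            cost = colo_cost + (poly_cost if did_polypectomy else 0.0)
            cost_raw += cost
            cost_disc += cost * disc_q[min(e, MAX_Q - 1)]
            if did_polypectomy:
                out_polypectomy[p] += 1

            # complications (screening and surveillance exams)
            mult = comp_poly_mult if did_polypectomy else 1.0
            for c in range(3):
                pc = comp_prob[c] * mult
                if pc > 1.0:
                    pc = 1.0
                if _u01(pk, exam_counter, 10 + c) < pc:
                    out_complications[p] += 1
                    cost_raw += comp_cost[c]
                    cost_disc += comp_cost[c] * disc_q[min(e, MAX_Q - 1)]
                    if _u01(pk, exam_counter, 20 + c) < comp_fatal[c]:
                        death_q = e
                        cause = CAUSE_COMPLICATION
                        dead_by_complication = True
                        break
            if dead_by_complication:
                break

            if det_cancer_les >= 0:
                dx_q = e
                dx_stage = det_cancer_stage
                dx_mode = MODE_SCREEN
                dx_les = det_cancer_les
                break

            # surveillance decision
            if n_det_adenoma >= 3 or n_det_advanced > 0:
                interval = surv_high_q
            elif n_det_adenoma >= 1:
                interval = surv_low_q
            else:
                interval = 0
            if interval > 0 and e + interval <= surv_stop_q:
                under_surv = True
                surv_next = e + interval
            else:
                under_surv = False
                surv_next = INF_Q
            # screening invitations that fell during surveillance are overridden
            while sched_idx < k and schedule_q[sched_idx] <= e:
                sched_idx += 1

        # ----- outcome resolution -----
        if dx_q >= 0 and not dead_by_complication:
            surv = survival_5yr[dx_stage - 1]
            if les_u_surv[dx_les] >= surv:
                init_q = les_cancer_q[dx_les]
                dd = les_death_delay[dx_les]
                if anchor_is_dx == 1:
                    cdq = dx_q + dd
                    possible = True
                else:
                    possible = dx_q < init_q + CRC_DEATH_WINDOW_Q
                    cdq = init_q + dd
                    if cdq <= dx_q:
                        cdq = dx_q + 1
                    if cdq > init_q + CRC_DEATH_WINDOW_Q:
                        cdq = init_q + CRC_DEATH_WINDOW_Q
                if possible and cdq <= odq:
                    death_q = cdq
                    cause = CAUSE_CRC

        # ----- treatment costs -----
        if dx_q >= 0:
            end = dx_q + horizon_q
            if death_q < end:
                end = death_q
            for t in range(dx_q, end):
                if cause == CAUSE_CRC and t >= death_q - 4:
                    period = 2  # terminal
                elif t < dx_q + 4:
                    period = 0  # initial
                else:
                    period = 1  # follow-up
                ct = treat_cost[dx_stage - 1, period]
                cost_raw += ct
                cost_disc += ct * disc_q[min(t, MAX_Q - 1)]
            if cause != CAUSE_CRC:
                cost_raw += death_unrel_cost
                cost_disc += death_unrel_cost * disc_q[min(death_q, MAX_Q - 1)]

        out_death_q[p] = death_q
        out_cause[p] = cause
        out_dx_q[p] = dx_q
        out_dx_stage[p] = dx_stage
        out_dx_mode[p] = dx_mode
        out_cost_raw[p] = cost_raw
        out_cost_disc[p] = cost_disc


@dataclass
class RawCohortRecord:
    """Per-person outcomes of one simulated arm."""

    n: int
    schedule_ages: tuple
    death_q: np.ndarray
    cause: np.ndarray       # 0 other, 1 crc, 2 complication
    dx_q: np.ndarray        # -1 if never diagnosed
    dx_stage: np.ndarray
    dx_mode: np.ndarray     # 0 none, 1 symptomatic, 2 screen-detected
    colo_screen: np.ndarray
    colo_surveillance: np.ndarray
    colo_diagnostic: np.ndarray
    polypectomies: np.ndarray
    complications: np.ndarray
    adenomas_removed: np.ndarray
    cost_raw: np.ndarray
    cost_disc: np.ndarray

    def to_dataframe(self, cohort: "Cohort | None" = None):
        """Per-person event table; pass the source cohort to include the
        person id, sex and risk multiplier columns."""
        import pandas as pd

        extra = {}
        if cohort is not None:
            extra = {"id": np.arange(self.n), "sex": cohort.sex,
                     "risk_multiplier": cohort.risk_mult}
        return pd.DataFrame(
            {
                **extra,
                "death_q": self.death_q,
                "cause": self.cause,
                "dx_q": self.dx_q,
                "dx_stage": self.dx_stage,
                "dx_mode": self.dx_mode,
                "colo_screen": self.colo_screen,
                "colo_surveillance": self.colo_surveillance,
                "colo_diagnostic": self.colo_diagnostic,
                "polypectomies": self.polypectomies,
                "complications": self.complications,
                "adenomas_removed": self.adenomas_removed,
                "cost_raw": self.cost_raw,
                "cost_disc": self.cost_disc,
            }
        )

    def to_csv(self, path, cohort: "Cohort | None" = None) -> None:
        self.to_dataframe(cohort).to_csv(path, index=False)


def discount_factors(rate: float, anchor_age: float) -> np.ndarray:
    """Discount factor for each quarter of age, clamped to 1 before anchor."""
    ages = (np.arange(MAX_Q) + 0.5) / QPY
    f = (1.0 + rate) ** (-(ages - anchor_age))
    return np.minimum(f, 1.0)


def replay_cohort(
    cohort: Cohort,
    bundle: ParamBundle,
    schedule_ages: tuple = (),
    colonoscopy=None,
) -> RawCohortRecord:
    """Apply one screening schedule to a presimulated cohort.

    ``schedule_ages`` is a tuple of integer ages in years (may be empty for
    the no-screening arm).  ``colonoscopy`` overrides the bundle's procedure
    parameters (used by sensitivity scans).
    """
    colo = colonoscopy if colonoscopy is not None else bundle.colonoscopy
    nh = bundle.natural_history
    costs = bundle.costs
    gl = bundle.guideline
    n = cohort.n

    schedule_q = np.asarray([int(a) * QPY for a in schedule_ages], dtype=np.int64)
    disc_q = discount_factors(costs.discount_rate_annual, costs.discount_anchor_age)

    out = {
        name: np.zeros(n, dtype=np.int64)
        for name in (
            "death_q", "cause", "dx_q", "dx_stage", "dx_mode",
            "colo_screen", "colo_surv", "colo_diag",
            "polypectomy", "complications", "adenomas_removed",
        )
    }
    out["dx_q"][:] = -1
    cost_raw = np.zeros(n)
    cost_disc = np.zeros(n)

    comp_keys = ("perforation", "bleeding", "serosa_burn")
    _replay_kernel(
        cohort.other_death_q, cohort.person_key,
        cohort.lesion_start, cohort.les_is_direct, cohort.les_location,
        cohort.les_stage_entry, cohort.les_cancer_q, cohort.les_c_entry,
        cohort.les_sympt_q, cohort.les_sympt_stage, cohort.les_u_surv,
        cohort.les_death_delay, cohort.les_key,
        schedule_q,
        int(round(gl.interval_low_risk * QPY)),
        int(round(gl.interval_high_risk * QPY)),
        int(round(gl.stopping_age * QPY)),
        np.array([colo.reach_prob_splenic, colo.reach_prob_hepatic,
                  colo.reach_prob_cecum]),
        colo.detection_sensitivity, colo.cancer_detection_sensitivity,
        np.array([colo.complication_prob[k] for k in comp_keys]),
        colo.complication_polypectomy_multiplier,
        np.array([colo.complication_fatality[k] for k in comp_keys]),
        colo.adherence, 1 if colo.adherence_mode == "per_person" else 0,
        nh.survival_5yr, 1 if nh.death_window_anchor == "diagnosis" else 0,
        nh.early_advanced_boundary, SEGMENT_REACH_LEVEL,
        costs.colonoscopy_cost, costs.polypectomy_surcharge,
        np.array([costs.complication_cost[k] for k in comp_keys]),
        costs.treatment_cost, costs.death_unrelated_terminal_cost,
        disc_q, costs.treatment_horizon_q,
        out["death_q"], out["cause"], out["dx_q"], out["dx_stage"],
        out["dx_mode"], out["colo_screen"], out["colo_surv"], out["colo_diag"],
        out["polypectomy"], out["complications"], out["adenomas_removed"],
        cost_raw, cost_disc,
    )
    return RawCohortRecord(
        n=n, schedule_ages=tuple(int(a) for a in schedule_ages),
        death_q=out["death_q"], cause=out["cause"], dx_q=out["dx_q"],
        dx_stage=out["dx_stage"], dx_mode=out["dx_mode"],
        colo_screen=out["colo_screen"],
        colo_surveillance=out["colo_surv"],
        colo_diagnostic=out["colo_diag"],
        polypectomies=out["polypectomy"],
        complications=out["complications"],
        adenomas_removed=out["adenomas_removed"],
        cost_raw=cost_raw, cost_disc=cost_disc,
    )
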