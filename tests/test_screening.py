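import numpy as np
import pytest

from colosim import ValidationError, make_default_params, presimulate, replay_cohort
from colosim.natural_history import Adenoma, Cancer, Person
from colosim.outcomes import CohortOutcomes
from colosim.params import ColonoscopyParams, ParamBundle, SurveillanceGuideline
from colosim.screening import (
    ColonoscopyResult,
    apply_screening,
    next_surveillance,
    perform_colonoscopy,
    validate_schedule,
)
from tests.conftest import null_colonoscopy, perfect_colonoscopy


class TestValidateSchedule:
    def test_standard_screening_valid(self):
        s = validate_schedule([50, 60, 70])
        assert s.ages == (50, 60, 70)

    def test_gap_violation(self):
        with pytest.raises(ValidationError, match="gap"):
            validate_schedule([50, 52])

    def test_range_violation(self):
        with pytest.raises(ValidationError, match="range"):
            validate_schedule([19])
        with pytest.raises(ValidationError, match="range"):
            validate_schedule([91])

    def test_too_many(self):
        with pytest.raises(ValidationError, match="at most"):
            validate_schedule([20, 30, 40, 50, 60])

    def test_non_integer(self):
        with pytest.raises(ValidationError, match="integer"):
            validate_schedule([50.5])

    def test_sorts_input(self):
        assert validate_schedule([70, 50, 60]).ages == (50, 60, 70)


def person_with_lesion(stage=5, location=7, age_q=220):
    p = Person(id=0, sex=0, risk_multiplier=1.0, age_q=age_q)
    p.adenomas.append(Adenoma(stage=stage, location=location, age_initiated=200))
    return p


class TestPerformColonoscopy:
    def test_perfect_exam_detects_everything(self, default_bundle):
        colo = perfect_colonoscopy(default_bundle)
        rng = np.random.default_rng(0)
        p = Person(id=0, sex=0, risk_multiplier=1.0, age_q=220)
        for loc in range(8):
            p.adenomas.append(Adenoma(stage=2, location=loc, age_initiated=200))
        res = perform_colonoscopy(p, colo, rng)
        assert res.adenomas_detected == 8
        assert all(a.removed for a in p.adenomas)

    def test_reach_truncation_protects_cecum(self, default_bundle):
        d = perfect_colonoscopy(default_bundle).to_dict()
        d["reach_prob_splenic"] = 0.0  # never past the splenic flexure
        colo = ColonoscopyParams.from_dict(d)
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = person_with_lesion(stage=5, location=0)  # cecal lesion
            res = perform_colonoscopy(p, colo, rng)
            assert res.adenomas_detected == 0
            assert not p.adenomas[0].removed

    def test_stage5_detection_fraction(self, default_bundle):
        d = perfect_colonoscopy(default_bundle).to_dict()
        d["detection_sensitivity"] = [0.0, 0.0, 0.0, 0.0, 0.9, 0.9]
        colo = ColonoscopyParams.from_dict(d)
        rng = np.random.default_rng(2)
        n = 100_000
        detected = 0
        for _ in range(n):
            p = person_with_lesion(stage=5, location=7)
            detected += perform_colonoscopy(p, colo, rng).adenomas_detected
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(detected / n - 0.9) < 4 * se

    def test_dead_person_raises(self, default_bundle):
        p = person_with_lesion()
        p.alive = False
        with pytest.raises(ValidationError):
            perform_colonoscopy(p, default_bundle.colonoscopy, np.random.default_rng(0))

    def test_detects_preclinical_cancer(self, default_bundle):
        colo = perfect_colonoscopy(default_bundle)
        p = Person(id=0, sex=0, risk_multiplier=1.0, age_q=240)
        p.cancers.append(Cancer(stage=2, status="preclinical", origin="adenoma_pathway",
                                location=6, age_initiated=230))
        res = perform_colonoscopy(p, colo, np.random.default_rng(3))
        assert res.cancer_detected and res.cancer_stage == 2
        assert p.cancers[0].status == "screen_detected"
        assert p.cancers[0].age_diagnosed == 240


class TestNextSurveillance:
    def test_no_adenoma_resumes_screening(self):
        res = ColonoscopyResult(reach_level=3, adenomas_detected=0)
        assert next_surveillance(res, SurveillanceGuideline()) is None

    def test_high_risk_three_years(self):
        res = ColonoscopyResult(reach_level=3, adenomas_detected=3)
        assert next_surveillance(res, SurveillanceGuideline()) == 3.0
        res2 = ColonoscopyResult(reach_level=3, adenomas_detected=1, advanced_detected=1)
        assert next_surveillance(res2, SurveillanceGuideline()) == 3.0

    def test_low_risk_five_years(self):
        res = ColonoscopyResult(reach_level=3, adenomas_detected=2)
        assert next_surveillance(res, SurveillanceGuideline()) == 5.0

    def test_past_stopping_age(self):
        res = ColonoscopyResult(reach_level=3, adenomas_detected=3)
        assert next_surveillance(res, SurveillanceGuideline(), age_years=84) is None


class TestApplyScreening:
    def test_zero_adherence_equals_no_screening(self, default_bundle, cohort_50k):
        cohort, base, _ = cohort_50k
        d = default_bundle.colonoscopy.to_dict()
        d["adherence"] = 0.0
        rec = apply_screening(cohort, (50, 60, 70), default_bundle,
                              colonoscopy=ColonoscopyParams.from_dict(d))
        np.testing.assert_array_equal(rec.death_q, base.death_q)
        assert rec.colo_screen.sum() == 0

    def test_screening_count_matches_survival(self, default_bundle, cohort_50k):
        cohort, base, _ = cohort_50k
        rec = apply_screening(cohort, (55,), default_bundle)
        eligible = ((base.death_q > 55 * 4)
                    & ((base.dx_q < 0) | (base.dx_q >= 55 * 4))).sum()
        assert rec.colo_screen.sum() == pytest.approx(eligible, rel=0.01)

    def test_adherence_scales_attendance_linearly(self, default_bundle, cohort_50k):
        cohort, _, _ = cohort_50k
        counts = {}
        for p in (0.25, 0.5, 1.0):
            d = default_bundle.colonoscopy.to_dict()
            d["adherence"] = p
            rec = apply_screening(cohort, (55, 65), default_bundle,
                                  colonoscopy=ColonoscopyParams.from_dict(d))
            counts[p] = rec.colo_screen.sum()
        assert counts[0.5] == pytest.approx(0.5 * counts[1.0], rel=0.05)
        assert counts[0.25] == pytest.approx(0.25 * counts[1.0], rel=0.08)

    def test_screening_reduces_incidence(self, default_bundle, cohort_50k):
        cohort, base, base_out = cohort_50k
        rec = apply_screening(cohort, (55,), default_bundle,
                              colonoscopy=perfect_colonoscopy(default_bundle))
        screened = (rec.dx_q >= 0).mean()
        baseline = (base.dx_q >= 0).mean()
        se = np.sqrt(baseline * (1 - baseline) / cohort.n)
        assert screened < baseline - 3 * se

    def test_per_person_adherence_mode(self, default_bundle, cohort_50k):
        cohort, _, _ = cohort_50k
        d = default_bundle.colonoscopy.to_dict()
        d.update(adherence=0.5, adherence_mode="per_person")
        rec = apply_screening(cohort, (55, 60, 65), default_bundle,
                              colonoscopy=ColonoscopyParams.from_dict(d))
        # always/never: persons attend either all exams they survive to or none
        attended = rec.colo_screen
        assert attended.max() <= 3
        # about half the invited persons attend at least once
        frac = (attended > 0).sum() / (cohort.other_death_q > 55 * 4).sum()
        assert 0.4 < frac < 0.6

    def test_intensive_screening_bound(self, default_bundle):
        """5-yearly perfect exams from 20-90 with no direct path remove
        nearly all incidence (residual = fast inter-exam transitions)."""
        nh = default_bundle.natural_history.scaled(1.0, 0.0)  # direct path off
        bundle = ParamBundle(natural_history=nh,
                             colonoscopy=default_bundle.colonoscopy,
                             costs=default_bundle.costs,
                             life_table=default_bundle.life_table,
                             guideline=default_bundle.guideline)
        cohort = presimulate(50_000, bundle, seed=202)
        base = replay_cohort(cohort, bundle, ())
        ages = tuple(range(20, 91, 5))
        # bypass the 4-exam limit deliberately: intensive bound scenario
        rec = replay_cohort(cohort, bundle, ages,
                            colonoscopy=perfect_colonoscopy(bundle))
        base_cases = (base.dx_q >= 0).sum()
        screened_cases = (rec.dx_q >= 0).sum()
        assert base_cases > 0
        assert screened_cases < 0.05 * base_cases

    def test_no_ghost_cancers_after_removal(self, default_bundle):
        """With perfect detection and full reach, a removed adenoma never
        progresses: all remaining diagnoses predate the exam or are direct."""
        cohort = presimulate(30_000, default_bundle, seed=203)
        rec = replay_cohort(cohort, default_bundle, tuple(range(20, 91, 5)),
                            colonoscopy=perfect_colonoscopy(default_bundle))
        # any diagnosis after age 25 must be direct-path or an adenoma that
        # turned cancerous between exams; none may come from a lesion whose
        # adenoma phase spanned an exam (it would have been removed)
        owner = np.repeat(np.arange(cohort.n), np.diff(cohort.lesion_start))
        exam_qs = np.array([a * 4 for a in range(20, 91, 5)])
        bad = 0
        for j in np.flatnonzero((cohort.les_is_direct == 0)
                                & (cohort.les_cancer_q < 10**6)):
            p = owner[j]
            if rec.dx_q[p] < 0:
                continue
            start = cohort.les_stage_entry[j, 0]
            end = cohort.les_cancer_q[j]
            spanned = exam_qs[(exam_qs >= start) & (exam_qs < end)
                              & (exam_qs < rec.death_q[p])]
            # if an exam fell in the adenoma window before diagnosis,
            # the lesion was removed, so its cancer cannot be the diagnosis
            if spanned.size and rec.dx_q[p] >= end and rec.dx_mode[p] != 2:
                if (cohort.les_sympt_q[j] == rec.dx_q[p]):
                    bad += 1
        assert bad == 0
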