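import numpy as np
import pytest

from colosim import make_default_params, make_life_table, presimulate, replay_cohort
from colosim.natural_history import (
    Cancer,
    init_cohort,
    run_cohort,
    schedule_crc_death,
    simulate_person,
    step_quarter,
)
from colosim.params import (
    MAX_Q,
    NaturalHistoryParams,
    ParamBundle,
    ValidationError,
)
from tests.conftest import null_colonoscopy


def zero_life_table():
    lt = make_life_table(0.0, 0.0, 0.1, 1.0)
    return lt


def nh_with(default_bundle, **overrides) -> NaturalHistoryParams:
    d = default_bundle.natural_history.to_dict()
    d.update(overrides)
    return NaturalHistoryParams.from_dict(d)


class TestInitCohort:
    def test_determinism(self, default_bundle):
        a = init_cohort(10, 0.5, default_bundle.natural_history, seed=1)
        b = init_cohort(10, 0.5, default_bundle.natural_history, seed=1)
        assert [(p.sex, p.risk_multiplier) for p in a] == \
               [(p.sex, p.risk_multiplier) for p in b]

    def test_degenerate_heterogeneity(self, default_bundle):
        nh = nh_with(default_bundle, risk_heterogeneity_sigma=0.0)
        cohort = init_cohort(50, 0.5, nh, seed=2)
        assert all(p.risk_multiplier == 1.0 for p in cohort)

    def test_mean_risk_multiplier_near_one(self, default_bundle):
        cohort = init_cohort(100_000, 0.5, default_bundle.natural_history, seed=3)
        mult = np.array([p.risk_multiplier for p in cohort])
        se = mult.std() / np.sqrt(len(mult))
        assert abs(mult.mean() - 1.0) < 3 * se

    def test_invalid_n(self, default_bundle):
        with pytest.raises(ValidationError):
            init_cohort(0, 0.5, default_bundle.natural_history, seed=1)


class TestStepQuarter:
    def test_zero_rates_only_age_changes(self, default_bundle):
        nh = nh_with(default_bundle)
        nh.adenoma_init_rate = np.zeros_like(nh.adenoma_init_rate)
        nh.direct_path_rate = np.zeros_like(nh.direct_path_rate)
        lt = zero_life_table()
        person = init_cohort(1, 0.5, nh, seed=4)[0]
        rng = np.random.default_rng(0)
        step_quarter(person, nh, lt, rng)
        assert person.age_q == 1 and person.alive
        assert not person.adenomas and not person.cancers

    def test_dead_person_raises(self, default_bundle):
        person = init_cohort(1, 0.5, default_bundle.natural_history, seed=5)[0]
        person.alive = False
        with pytest.raises(ValidationError):
            step_quarter(person, default_bundle.natural_history,
                         default_bundle.life_table, np.random.default_rng(0))

    def test_blocked_chain_no_cancer_from_stage1(self, default_bundle):
        # conversion only from stage 6, progression off -> no cancers ever
        nh = nh_with(
            default_bundle,
            stage_progression_prob=[0.0] * 5,
            adenoma_to_preclinical_prob=[0, 0, 0, 0, 0, 0.5],
        )
        nh.direct_path_rate = np.zeros_like(nh.direct_path_rate)
        lt = zero_life_table()
        rng = np.random.default_rng(1)
        person = init_cohort(1, 0.5, nh, seed=6)[0]
        for _ in range(200):
            step_quarter(person, nh, lt, rng)
        assert not person.cancers

    def test_adenoma_count_poisson(self, default_bundle):
        # constant hazard h per quarter, progression off -> Poisson(h*T)
        h, T = 0.02, 100
        nh = nh_with(
            default_bundle,
            stage_progression_prob=[0.0] * 5,
            adenoma_to_preclinical_prob=[0.0] * 6,
            risk_heterogeneity_sigma=0.0,
        )
        nh.adenoma_init_rate = np.full_like(nh.adenoma_init_rate, h)
        nh.direct_path_rate = np.zeros_like(nh.direct_path_rate)
        lt_q = np.zeros((2, MAX_Q))
        lt_q[:, -1] = 1.0
        from colosim.params import LifeTable

        bundle = ParamBundle(
            natural_history=nh, colonoscopy=default_bundle.colonoscopy,
            costs=default_bundle.costs, life_table=LifeTable(q=lt_q),
            guideline=default_bundle.guideline)
        cohort = presimulate(100_000, bundle, seed=7)
        counts = np.diff(cohort.lesion_start)
        init_q = cohort.les_stage_entry[:, 0]
        owner = np.repeat(np.arange(cohort.n), counts)
        counts_T = np.bincount(owner[init_q < T], minlength=cohort.n)
        lam = h * T
        assert counts_T.mean() == pytest.approx(lam, rel=0.02)
        assert counts_T.var() == pytest.approx(lam, rel=0.05)
        from scipy import stats

        for k in range(5):
            p_emp = (counts_T == k).mean()
            p_th = stats.poisson.pmf(k, lam)
            se = np.sqrt(p_th * (1 - p_th) / cohort.n)
            assert abs(p_emp - p_th) < 4 * se


class TestScheduleCrcDeath:
    def test_survival_one_no_deaths(self, default_bundle):
        nh = nh_with(default_bundle, survival_5yr=[1.0] * 4)
        rng = np.random.default_rng(2)
        for _ in range(200):
            ca = Cancer(stage=3, status="symptomatic", origin="direct_path",
                        location=0, age_initiated=200, age_diagnosed=204)
            schedule_crc_death(ca, nh, rng)
            assert ca.crc_death_age is None

    def test_stage4_death_fraction_binomial(self, default_bundle):
        nh = nh_with(default_bundle, survival_5yr=[1.0, 1.0, 1.0, 0.2])
        rng = np.random.default_rng(3)
        n = 100_000
        deaths = 0
        for _ in range(n):
            ca = Cancer(stage=4, status="symptomatic", origin="direct_path",
                        location=0, age_initiated=200, age_diagnosed=202)
            schedule_crc_death(ca, nh, rng)
            deaths += ca.crc_death_age is not None
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(deaths / n - 0.8) < 4 * se

    def test_deaths_within_20_quarters_of_initiation(self, default_bundle):
        rng = np.random.default_rng(4)
        for _ in range(500):
            ca = Cancer(stage=4, status="symptomatic", origin="direct_path",
                        location=0, age_initiated=100, age_diagnosed=105)
            schedule_crc_death(ca, default_bundle.natural_history, rng)
            if ca.crc_death_age is not None:
                assert 100 < ca.crc_death_age <= 120


class TestMarkovOracle:
    def test_single_adenoma_occupancy_matches_matrix_powers(self, default_bundle):
        """Small-model oracle: one stage-1 adenoma, constant rates, no death;
        simulated state occupancy after T quarters vs explicit chain powers."""
        g = [0.08, 0.07, 0.06, 0.05, 0.04]
        c = [0.005, 0.008, 0.012, 0.02, 0.03, 0.05]
        nh = nh_with(default_bundle, stage_progression_prob=g,
                     adenoma_to_preclinical_prob=c,
                     symptomatic_detection_prob=[0.0] * 4)
        nh.adenoma_init_rate = np.zeros_like(nh.adenoma_init_rate)
        nh.direct_path_rate = np.zeros_like(nh.direct_path_rate)
        lt = zero_life_table()
        # oracle: states 0..5 = adenoma stages, 6 = cancer (absorbing)
        M = np.zeros((7, 7))
        for s in range(6):
            pc = c[s]
            pg = (1 - pc) * (g[s] if s < 5 else 0.0)
            M[s, 6] = pc
            if s < 5:
                M[s, s + 1] = pg
            M[s, s] = 1 - pc - pg
        M[6, 6] = 1.0
        T = 20
        expected = np.linalg.matrix_power(M.T, T) @ np.eye(7)[:, 0]

        n = 20_000
        rng = np.random.default_rng(5)
        from colosim.natural_history import Adenoma, Person

        occupancy = np.zeros(7)
        for i in range(n):
            p = Person(id=i, sex=0, risk_multiplier=1.0)
            p.adenomas.append(Adenoma(stage=1, location=0, age_initiated=0))
            for _ in range(T):
                step_quarter(p, nh, lt, rng)
            if p.cancers:
                occupancy[6] += 1
            else:
                occupancy[p.adenomas[0].stage - 1] += 1
        occupancy /= n
        for s in range(7):
            se = np.sqrt(max(expected[s] * (1 - expected[s]), 1e-9) / n)
            assert abs(occupancy[s] - expected[s]) <= 3 * se + 1e-9


class TestRunCohort:
    def test_zero_disease_life_years_match_life_table(self, null_bundle):
        cohort, rec = run_cohort(20_000, null_bundle, (), seed=8)
        pmf = null_bundle.life_table.death_quarter_pmf(0)
        expected_f = np.sum(np.arange(MAX_Q) * pmf)
        pmf_m = null_bundle.life_table.death_quarter_pmf(1)
        expected_m = np.sum(np.arange(MAX_Q) * pmf_m)
        for sex, expected in ((0, expected_f), (1, expected_m)):
            obs = rec.death_q[cohort.sex == sex]
            se = obs.std() / np.sqrt(obs.size)
            assert abs(obs.mean() - expected) < 3.5 * se
        np.testing.assert_array_equal(rec.death_q, cohort.other_death_q)

    def test_crn_contract_zero_sensitivity(self, default_bundle, cohort_50k):
        cohort, base, _ = cohort_50k
        rec = replay_cohort(cohort, default_bundle, (50, 60, 70),
                            colonoscopy=null_colonoscopy(default_bundle))
        np.testing.assert_array_equal(rec.death_q, base.death_q)
        np.testing.assert_array_equal(rec.dx_q, base.dx_q)
        assert rec.colo_screen.sum() > 0

    def test_monotone_hazard_property(self, default_bundle):
        base = presimulate(100_000, default_bundle, seed=9)
        rec0 = replay_cohort(base, default_bundle, ())
        doubled = ParamBundle(
            natural_history=default_bundle.natural_history.scaled(2.0, 1.0),
            colonoscopy=default_bundle.colonoscopy, costs=default_bundle.costs,
            life_table=default_bundle.life_table,
            guideline=default_bundle.guideline)
        c2 = presimulate(100_000, doubled, seed=9)
        rec2 = replay_cohort(c2, doubled, ())
        inc0 = (rec0.dx_q >= 0).mean()
        inc2 = (rec2.dx_q >= 0).mean()
        se = np.sqrt(inc0 * (1 - inc0) / 100_000)
        assert inc2 > inc0 - 3 * se

    def test_origin_exclusivity(self, default_bundle):
        nh_only_direct = default_bundle.natural_history.scaled(0.0, 1.0)
        b1 = ParamBundle(natural_history=nh_only_direct,
                         colonoscopy=default_bundle.colonoscopy,
                         costs=default_bundle.costs,
                         life_table=default_bundle.life_table,
                         guideline=default_bundle.guideline)
        c1 = presimulate(20_000, b1, seed=10)
        assert c1.n_lesions > 0 and np.all(c1.les_is_direct == 1)

        nh_only_adenoma = default_bundle.natural_history.scaled(1.0, 0.0)
        b2 = ParamBundle(natural_history=nh_only_adenoma,
                         colonoscopy=default_bundle.colonoscopy,
                         costs=default_bundle.costs,
                         life_table=default_bundle.life_table,
                         guideline=default_bundle.guideline)
        c2 = presimulate(20_000, b2, seed=10)
        assert c2.n_lesions > 0 and np.all(c2.les_is_direct == 0)

    def test_every_death_has_one_cause_and_age_cap(self, default_bundle, cohort_50k):
        cohort, base, _ = cohort_50k
        assert np.all(base.death_q <= MAX_Q)
        assert set(np.unique(base.cause)) <= {0, 1, 2}


class TestObjectEngineParity:
    def test_aggregate_agreement(self, default_bundle):
        """Dual-route check: stepping Person objects quarter-by-quarter vs
        the vectorized trajectory engine, on the same parameter bundle."""
        n = 4_000
        rng = np.random.Generator(np.random.MT19937(77))
        people = init_cohort(n, 0.5, default_bundle.natural_history, seed=77)
        for p in people:
            simulate_person(p, default_bundle.natural_history,
                            default_bundle.life_table, rng)
        obj_cases = np.mean([p.diagnosed for p in people])
        obj_deaths = np.mean([p.cause_death == "crc" for p in people])

        cohort = presimulate(200_000, default_bundle, seed=78)
        rec = replay_cohort(cohort, default_bundle, ())
        eng_cases = (rec.dx_q >= 0).mean()
        eng_deaths = (rec.cause == 1).mean()

        se_cases = np.sqrt(eng_cases * (1 - eng_cases) / n)
        se_deaths = np.sqrt(eng_deaths * (1 - eng_deaths) / n)
        assert abs(obj_cases - eng_cases) < 3.5 * se_cases
        assert abs(obj_deaths - eng_deaths) < 3.5 * se_deaths
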