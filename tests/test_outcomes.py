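import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colosim.outcomes import (
    CohortOutcomes,
    accrue_costs,
    compute_objectives,
    discount,
    icer,
    summary_metrics,
    treatment_category,
)


def outcomes(**kw):
    defaults = dict(
        n=1000, schedule_ages=(), crc_cases=50, crc_deaths=20,
        complication_deaths=0, total_life_years=75_000.0,
        discounted_life_years=30_000.0, lyl_raw=300.0, lyl_disc=80.0,
        total_cost=5_000_000.0, discounted_cost=2_000_000.0,
        colonoscopies_screening=800, colonoscopies_surveillance=150,
        colonoscopies_diagnostic=50, polypectomies=200, complications=3,
    )
    defaults.update(kw)
    return CohortOutcomes(**defaults)


class TestDiscount:
    def test_anchor_identity(self):
        assert discount(100.0, 20.0, 0.03) == pytest.approx(100.0)

    def test_closed_form_age_30(self):
        assert discount(100.0, 30.0, 0.03) == pytest.approx(100 / 1.03 ** 10)
        assert discount(100.0, 30.0, 0.03) == pytest.approx(74.41, abs=0.005)

    def test_zero_rate_identity(self):
        for age in (5, 20, 50, 99):
            assert discount(42.0, age, 0.0) == 42.0

    def test_pre_anchor_clamped(self):
        assert discount(100.0, 10.0, 0.03) == 100.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, 30.0, -0.01)


class TestAccrueCosts:
    def test_death_18_months_after_dx(self, default_bundle):
        """Six post-diagnosis quarters: 1-2 initial, 3-6 terminal
        (terminal takes precedence over initial and follow-up)."""
        costs = default_bundle.costs
        led = accrue_costs(dx_q=200, death_q=206, dx_stage=3, crc_death=True,
                           costs=costs)
        cats = [led["categories"][q] for q in range(200, 206)]
        assert cats == ["initial", "initial", "terminal", "terminal",
                        "terminal", "terminal"]

    def test_five_year_cap(self, default_bundle):
        led = accrue_costs(dx_q=200, death_q=226, dx_stage=1, crc_death=False,
                           costs=default_bundle.costs)
        for q in range(220, 226):
            assert led["categories"][q] == "post_5y_zero"

    def test_no_crc_single_colonoscopy_cost(self, default_bundle):
        costs = default_bundle.costs
        led = accrue_costs(dx_q=0, death_q=0, dx_stage=1, crc_death=True,
                           costs=costs, procedure_quarters=(140,))
        # dx_q == death_q: no treatment quarters; only the procedure
        assert led["raw"] == pytest.approx(costs.colonoscopy_cost)

    def test_conservation_every_quarter_one_category(self, default_bundle):
        rng = np.random.default_rng(0)
        for _ in range(200):
            dx = int(rng.integers(100, 350))
            death = dx + int(rng.integers(1, 60))
            crc = bool(rng.integers(2))
            led = accrue_costs(dx_q=dx, death_q=death, dx_stage=2,
                               crc_death=crc, costs=default_bundle.costs)
            assert sorted(led["categories"]) == list(range(dx, death))
            for cat in led["categories"].values():
                assert cat in ("initial", "followup", "terminal", "post_5y_zero")
            if crc:
                terminal = [q for q, c in led["categories"].items()
                            if c == "terminal"]
                assert all(q >= death - 4 for q in terminal)

    def test_discount_order_independence(self, default_bundle):
        """Summing per-quarter discounted flows equals discounting then
        summing (multiplicativity identity)."""
        costs = default_bundle.costs
        led = accrue_costs(dx_q=160, death_q=180, dx_stage=2, crc_death=True,
                           costs=costs)
        from colosim.engine import discount_factors

        disc = discount_factors(costs.discount_rate_annual,
                                costs.discount_anchor_age)
        manual = 0.0
        for q, cat in led["categories"].items():
            if cat == "post_5y_zero":
                continue
            idx = {"initial": 0, "followup": 1, "terminal": 2}[cat]
            manual += costs.treatment_cost[1, idx] * disc[q]
        assert led["discounted"] == pytest.approx(manual)

    def test_bad_quarter_rejected(self):
        with pytest.raises(ValueError):
            treatment_category(10, 20, 30, True)


class TestComputeObjectives:
    def test_identical_arms_zero(self):
        a = outcomes()
        v = compute_objectives(a, a)
        assert np.allclose(v.as_array(), 0.0)

    def test_perfect_screening_hundred_percent(self):
        v = compute_objectives(
            outcomes(crc_cases=0, crc_deaths=0), outcomes())
        assert v.incidence_reduction_pct == 100.0
        assert v.mortality_reduction_pct == 100.0

    def test_zero_baseline_flagged(self):
        v = compute_objectives(outcomes(), outcomes(crc_cases=0))
        assert math.isnan(v.incidence_reduction_pct)
        assert "incidence" in v.missing

    def test_antisymmetry_of_differences(self):
        a, b = outcomes(crc_deaths=10), outcomes(crc_deaths=30)
        d1 = b.crc_deaths - a.crc_deaths
        d2 = a.crc_deaths - b.crc_deaths
        assert d1 == -d2
        va = compute_objectives(a, b)
        assert va.mortality_reduction_pct > 0
        vb = compute_objectives(b, a)
        assert vb.mortality_reduction_pct < 0

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            compute_objectives(outcomes(n=10), outcomes())

    def test_lyl_includes_complication_deaths(self):
        # complication deaths enter the mortality count
        v = compute_objectives(
            outcomes(crc_deaths=18, complication_deaths=2), outcomes())
        assert v.mortality_reduction_pct == pytest.approx(0.0)


class TestSummaryMetrics:
    def test_arithmetic_fixture(self):
        base = outcomes(lyl_raw=300.0)
        scr = outcomes(lyl_raw=250.0, colonoscopies_screening=1000,
                       colonoscopies_surveillance=0, colonoscopies_diagnostic=0)
        m = summary_metrics(scr, base)
        assert m["lyg_per_1000"] == pytest.approx(50.0)
        assert m["colonoscopies_per_lyg"] == pytest.approx(1000 / 50)

    def test_no_cases_prevented_flagged(self):
        m = summary_metrics(outcomes(), outcomes())
        assert math.isnan(m["colonoscopies_per_case_prevented"])


class TestIcer:
    def test_arithmetic(self):
        b = outcomes()
        a = outcomes(discounted_cost=b.discounted_cost + 100,
                     lyl_disc=b.lyl_disc - 10)
        r = icer(a, b)
        assert r["icer"] == pytest.approx(10.0)
        assert not r["swapped"]

    def test_cost_saving_negative(self):
        b = outcomes()
        a = outcomes(discounted_cost=b.discounted_cost - 500,
                     lyl_disc=b.lyl_disc - 10)
        assert icer(a, b)["icer"] == pytest.approx(-50.0)

    def test_equal_effectiveness_undefined(self):
        r = icer(outcomes(), outcomes())
        assert r["undefined"] and math.isnan(r["icer"])

    def test_swapped_when_b_better(self):
        a = outcomes()
        b = outcomes(discounted_cost=a.discounted_cost + 100,
                     lyl_disc=a.lyl_disc - 10)
        r = icer(a, b)
        assert r["swapped"] and r["icer"] == pytest.approx(10.0)


class TestDiscountedVsRaw:
    def test_rate_zero_equality(self, null_bundle):
        from colosim import presimulate, replay_cohort
        from colosim.params import CostParams, ParamBundle

        d = null_bundle.costs.to_dict()
        d["discount_rate_annual"] = 0.0
        bundle = ParamBundle(natural_history=null_bundle.natural_history,
                             colonoscopy=null_bundle.colonoscopy,
                             costs=CostParams.from_dict(d),
                             life_table=null_bundle.life_table,
                             guideline=null_bundle.guideline)
        cohort = presimulate(5_000, bundle, seed=30)
        rec = replay_cohort(cohort, bundle, (55,))
        o = CohortOutcomes.from_record(rec, cohort, bundle.costs)
        assert o.discounted_life_years == pytest.approx(o.total_life_years)
        assert o.discounted_cost == pytest.approx(o.total_cost)

    @settings(max_examples=20, deadline=None)
    @given(rate=st.floats(0.0, 0.2))
    def test_discounted_never_exceeds_raw(self, rate):
        from colosim.engine import discount_factors

        f = discount_factors(rate, 20.0)
        assert np.all(f <= 1.0 + 1e-12)
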