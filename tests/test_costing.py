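"""Costing engine: DDD arithmetic, micro-costing, avoidance rules, staffing."""

import math

import pytest
from hypothesis import given, strategies as st

from stewardcost import (
    AdeEvent,
    AntimicrobialCourse,
    DDDReference,
    PatientEpisode,
    Route,
    UnitCostTable,
    annual_operational_cost,
    course_ddd,
    episode_avoidance_cost,
    episode_resource_cost,
    period_consumption,
    period_totals,
)
from stewardcost.costing import (
    EmptyCohortError,
    StaffingConfig,
    StaffingRole,
)
from stewardcost.records import DrugLookupError, PricingError, ResourceEvents


def simple_costs(**kwargs) -> UnitCostTable:
    defaults = dict(
        bed_day=1000.0, culture_test=160.0, lab_test=100.0, biopsy=450.0,
        iv_to_oral_switch_event=700.0, cdi_diagnostic_culture=30.0,
        vancomycin_125mg_dose=2.0, cost_per_ddd={"fluconazole": 7.0},
    )
    defaults.update(kwargs)
    return UnitCostTable(**defaults)


def episode(**kwargs) -> PatientEpisode:
    defaults = dict(
        id="x", period="preliminary", age_years=40.0, sex="female",
        los_initial_days=10.0,
    )
    defaults.update(kwargs)
    return PatientEpisode(**defaults)


class TestCourseDDD:
    ref = DDDReference(values={"fluconazole": 0.2, "cefepime": 1.0})

    @pytest.mark.parametrize(
        "dose, days, drug, expected",
        [
            (2.0, 5.0, "cefepime", 10.0),       # 10 g over the course, 1 g per DDD
            (2.0, 0.0, "cefepime", 0.0),        # zero-duration course consumes nothing
            (0.4, 7.0, "fluconazole", 14.0),    # 0.4 x 7 / 0.2
        ],
    )
    def test_grams_over_ddd(self, dose, days, drug, expected):
        c = AntimicrobialCourse(
            drug_name=drug, route=Route.oral, daily_dose_grams=dose, duration_days=days
        )
        assert course_ddd(c, self.ref) == pytest.approx(expected)

    def test_unknown_drug_is_named_in_the_error(self):
        c = AntimicrobialCourse(
            drug_name="metronidazole", route=Route.oral,
            daily_dose_grams=1.0, duration_days=3.0,
        )
        with pytest.raises(DrugLookupError, match="metronidazole"):
            course_ddd(c, self.ref)

    def test_route_override_takes_precedence(self):
        ref = DDDReference(
            values={"ciprofloxacin": 1.0},
            route_overrides={"ciprofloxacin": {Route.injectable: 0.8}},
        )
        oral = AntimicrobialCourse(
            drug_name="ciprofloxacin", route=Route.oral,
            daily_dose_grams=0.8, duration_days=1.0,
        )
        iv = AntimicrobialCourse(
            drug_name="ciprofloxacin", route=Route.injectable,
            daily_dose_grams=0.8, duration_days=1.0,
        )
        assert course_ddd(oral, ref) == pytest.approx(0.8)
        assert course_ddd(iv, ref) == pytest.approx(1.0)


class TestConsumption:
    ref = DDDReference(values={"fluconazole": 0.2})

    def test_empty_cohort_consumes_nothing(self):
        assert period_consumption([], self.ref, simple_costs()) == (0.0, 0.0)

    def test_ddd_times_price(self):
        ep = episode(courses=[AntimicrobialCourse(
            drug_name="fluconazole", route=Route.oral,
            daily_dose_grams=0.4, duration_days=5.0,
        )])
        ddd, cost = period_consumption([ep], self.ref, simple_costs())
        assert ddd == pytest.approx(10.0)
        assert cost == pytest.approx(70.0)

    def test_missing_price_is_named(self):
        ep = episode(courses=[AntimicrobialCourse(
            drug_name="fluconazole", route=Route.oral,
            daily_dose_grams=0.4, duration_days=5.0,
        )])
        costs = simple_costs(cost_per_ddd={})
        with pytest.raises(PricingError, match="fluconazole"):
            period_consumption([ep], self.ref, costs)

    def test_acquisition_mode_sums_recorded_costs(self):
        ep = episode(courses=[AntimicrobialCourse(
            drug_name="fluconazole", route=Route.oral, daily_dose_grams=0.4,
            duration_days=5.0, acquisition_cost=123.5,
        )])
        _, cost = period_consumption([ep], self.ref, simple_costs(), mode="acquisition")
        assert cost == pytest.approx(123.5)


class TestMicroCosting:
    def test_count_times_unit_cost(self):
        ep = episode(resources=ResourceEvents(
            cultures_before=2, labs_after=3, iv_to_oral_switches=1,
        ))
        r = episode_resource_cost(ep, simple_costs())
        assert r.cultures_before == pytest.approx(320.0)
        assert r.labs_after == pytest.approx(300.0)
        assert r.iv_to_oral == pytest.approx(700.0)
        assert r.total == pytest.approx(1320.0)

    def test_zero_counts_give_zero_components(self):
        r = episode_resource_cost(episode(), simple_costs())
        assert r.total == 0.0


class TestAvoidance:
    def test_hospitalization_is_bed_days(self):
        a = episode_avoidance_cost(episode(los_initial_days=10.0), simple_costs())
        assert a.hospitalization == pytest.approx(10_000.0)

    def test_cdi_recipe_forty_doses_plus_culture(self):
        a = episode_avoidance_cost(episode(cdi=True), simple_costs())
        assert a.cdi == pytest.approx(40 * 2.0 + 30.0)

    @pytest.mark.parametrize(
        "events, expected",
        [
            ([AdeEvent(implicated_route=Route.injectable)], 1000.0),
            ([AdeEvent(implicated_route=Route.oral)], 500.0),
            ([], 0.0),
        ],
    )
    def test_ade_extra_stay_by_route(self, events, expected):
        costs = simple_costs(bed_day=500.0)
        a = episode_avoidance_cost(episode(ade_events=events), costs)
        assert a.ade == pytest.approx(expected)

    def test_readmission_bed_days_only_when_readmitted(self):
        a = episode_avoidance_cost(
            episode(readmitted_30d=True, los_readmission_days=4.0), simple_costs()
        )
        assert a.readmission == pytest.approx(4000.0)
        assert episode_avoidance_cost(episode(), simple_costs()).readmission == 0.0


class TestOperationalCost:
    def test_daily_rounds_only(self):
        cfg = StaffingConfig(
            working_days_per_year=260,
            roles=[StaffingRole(name="md", hourly_rate=100.0, rounds_hours_per_day=1.0)],
        )
        assert annual_operational_cost(cfg) == pytest.approx(26_000.0)

    def test_monthly_meetings_only(self):
        cfg = StaffingConfig(roles=[
            StaffingRole(name="a", hourly_rate=100.0, meeting_hours_per_month=5.0),
            StaffingRole(name="b", hourly_rate=100.0, meeting_hours_per_month=5.0),
        ])
        assert annual_operational_cost(cfg) == pytest.approx(12_000.0)

    def test_empty_roster_costs_nothing(self):
        assert annual_operational_cost(StaffingConfig()) == 0.0


def brute_force_totals(cohort, ref: DDDReference, costs: UnitCostTable):
    """Independent accumulation straight off the raw records."""
    ddd = am = resource = avoidance = 0.0
    for ep in cohort:
        for c in ep.courses:
            grams_per_ddd = ref.route_overrides.get(c.drug_name, {}).get(
                c.route, ref.values[c.drug_name]
            )
            d = c.daily_dose_grams * c.duration_days / grams_per_ddd
            ddd += d
            am += d * costs.cost_per_ddd[c.drug_name]
        r = ep.resources
        resource += (
            (r.cultures_before + r.cultures_after) * costs.culture_test
            + (r.labs_before + r.labs_after) * costs.lab_test
            + (r.biopsies_before + r.biopsies_after) * costs.biopsy
            + r.iv_to_oral_switches * costs.iv_to_oral_switch_event
        )
        avoidance += ep.los_initial_days * costs.bed_day
        if ep.readmitted_30d:
            avoidance += ep.los_readmission_days * costs.bed_day
        if ep.cdi:
            avoidance += 40 * costs.vancomycin_125mg_dose + costs.cdi_diagnostic_culture
        for event in ep.ade_events:
            avoidance += (2 if event.implicated_route == Route.injectable else 1) * costs.bed_day
    return ddd, am, resource, avoidance


class TestPeriodTotals:
    def test_empty_cohort_is_an_error(self, cost_tables):
        costs, ref, _ = cost_tables
        with pytest.raises(EmptyCohortError):
            period_totals([], ref, costs, "preliminary")

    def test_published_resource_line_items_sum(self, printed_summaries):
        pre, dev = printed_summaries
        assert pre.ledger.resource_total == pytest.approx(125_245)
        assert dev.ledger.resource_total == pytest.approx(145_956)
        assert pre.ledger.avoidance_total == pytest.approx(17_919_806)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_tiny_cohorts(self, cost_tables, profiles, seed):
        from stewardcost import generate_cohort

        costs, ref, _ = cost_tables
        profile = profiles[seed % 2].model_copy(
            update={"n": 5, "ade_prob_injectable": 0.4, "ade_prob_oral": 0.3}
        )
        cohort = generate_cohort(profile, seed)
        summary = period_totals(cohort, ref, costs, "test")
        ddd, am, resource, avoidance = brute_force_totals(cohort, ref, costs)
        assert summary.ledger.ddd_total == pytest.approx(ddd)
        assert summary.ledger.antimicrobial_ddd_cost == pytest.approx(am)
        assert summary.ledger.resource_total == pytest.approx(resource)
        assert summary.ledger.avoidance_total == pytest.approx(avoidance)

    @given(seed=st.integers(0, 50), k=st.floats(0.1, 10))
    def test_homogeneity_in_unit_costs(self, cost_tables, profiles, seed, k):
        """Scaling every unit cost by k scales money by k; DDDs are invariant."""
        from stewardcost import generate_cohort

        costs, ref, _ = cost_tables
        profile = profiles[0].model_copy(update={"n": 4, "ade_prob_oral": 0.3})
        cohort = generate_cohort(profile, seed)
        scaled = costs.model_copy(update={
            field: getattr(costs, field) * k
            for field in ("bed_day", "culture_test", "lab_test", "biopsy",
                          "iv_to_oral_switch_event", "cdi_diagnostic_culture",
                          "vancomycin_125mg_dose")
        } | {"cost_per_ddd": {d: p * k for d, p in costs.cost_per_ddd.items()}})
        base = period_totals(cohort, ref, costs, "p").ledger
        big = period_totals(cohort, ref, scaled, "p").ledger
        assert big.ddd_total == pytest.approx(base.ddd_total)
        assert big.antimicrobial_ddd_cost == pytest.approx(k * base.antimicrobial_ddd_cost)
        assert big.resource_total == pytest.approx(k * base.resource_total)
        assert big.avoidance_total == pytest.approx(k * base.avoidance_total)

    def test_additivity_over_disjoint_cohorts(self, cost_tables, small_cohorts):
        costs, ref, _ = cost_tables
        pre, _ = small_cohorts
        a, b = pre[:40], pre[40:]
        whole = period_totals(pre, ref, costs, "p").ledger
        parts = period_totals(a, ref, costs, "p").ledger + period_totals(b, ref, costs, "p").ledger
        assert whole.ddd_total == pytest.approx(parts.ddd_total)
        assert whole.antimicrobial_ddd_cost == pytest.approx(parts.antimicrobial_ddd_cost)
        assert whole.resource_total == pytest.approx(parts.resource_total)
        assert whole.avoidance_total == pytest.approx(parts.avoidance_total)

    def test_ledger_conservation_on_random_cohorts(self, cost_tables, profiles):
        from stewardcost import generate_cohort

        costs, ref, _ = cost_tables
        for seed in range(5):
            profile = profiles[seed % 2].model_copy(update={"n": 8, "cdi_prob": 0.5})
            summary = period_totals(generate_cohort(profile, seed), ref, costs, "p")
            summary.ledger.check_conservation()
            led = summary.ledger
            assert math.isclose(
                led.resource_total,
                led.resource.cultures_before + led.resource.labs_before
                + led.resource.biopsies_before + led.resource.cultures_after
                + led.resource.labs_after + led.resource.biopsies_after
                + led.resource.iv_to_oral,
                abs_tol=1e-6,
            )
            assert math.isclose(
                led.avoidance_total,
                led.avoidance.hospitalization + led.avoidance.cdi
                + led.avoidance.readmission + led.avoidance.ade,
                abs_tol=1e-6,
            )
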