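"""Weekly stock-and-flow engine: schedule, access ratio, FIFO consumption."""

import math

import pytest

from oxyaccess import (
    InvalidInputError,
    InventoryState,
    SupplyPlan,
    TemperatureProfile,
    UndefinedRatioError,
    build_schedule,
    minimal_supply,
    simulate_year,
    step_week,
    weekly_access_ratio,
    weekly_demand,
)

from _daily_oracle import daily_simulation


class TestSchedule:
    @pytest.mark.parametrize(
        "annual, n, weeks, per_shipment",
        [
            (26_500, 2, (0, 26), 13_250),  # semiannual CMS restock
            (0, 2, (0, 26), 0),
            (52_000, 4, (0, 13, 26, 39), 13_000),
            (10_000, 1, (0,), 10_000),
        ],
    )
    def test_equal_spacing_and_size(self, annual, n, weeks, per_shipment):
        plan = SupplyPlan(annual_doses=annual, shipments_per_year=n)
        assert build_schedule(plan) == weeks
        assert plan.doses_per_shipment == per_shipment

    def test_invalid_plans_rejected(self):
        with pytest.raises(InvalidInputError):
            SupplyPlan(annual_doses=100, shipments_per_year=0)
        with pytest.raises(InvalidInputError):
            SupplyPlan(annual_doses=-1)


class TestWeeklyAccessRatio:
    @pytest.mark.parametrize(
        "effective, demand, weeks, expected",
        [(1000, 100, 5, 2.0), (500, 100, 5, 1.0), (0, 100, 5, 0.0)],
    )
    def test_ratio_arithmetic(self, effective, demand, weeks, expected):
        assert weekly_access_ratio(effective, demand, weeks) == expected

    def test_zero_demand_undefined(self):
        with pytest.raises(UndefinedRatioError):
            weekly_access_ratio(100, 0.0, 5)


class TestStepWeek:
    def test_empty_inventory_records_zero_ratio(self, bands, kin):
        state = InventoryState()
        plan = SupplyPlan(annual_doses=0)
        record = step_week(
            state, 1, plan, TemperatureProfile.constant(25.0), 100.0, bands, kin
        )
        assert record.effective_doses == 0
        assert record.access_ratio == 0.0
        assert record.shortfall == 100

    def test_cool_cohort_stays_full_strength_for_half_year(self, bands, kin):
        # closed form: exp(-k(25) * 182) = 0.947, comfortably above 0.85
        state = InventoryState()
        plan = SupplyPlan(annual_doses=1000, shipments_per_year=1)
        profile = TemperatureProfile.constant(25.0)
        for week in range(26):
            step_week(state, week, plan, profile, 1.0, bands, kin)
        (cohort,) = state.cohorts
        assert cohort.strength == pytest.approx(0.9472, abs=1e-4)
        assert cohort.strength > bands.full_min

    def test_hot_storage_collapses_before_quarterly_restock(
        self, pop, anchored_model, demand, bands, kin
    ):
        # at constant 45 degC the strength crosses the 33% viability floor in
        # ~9 weeks, so the ratio hits zero before the week-13 shipment and
        # jumps on its arrival
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=26_500, shipments_per_year=4),
            TemperatureProfile.constant(45.0),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        ratios = [r.access_ratio for r in result.records]
        assert min(ratios[9:13]) == 0.0
        assert ratios[13] > ratios[12]
        assert ratios[13] > 0.5


class TestSimulateYear:
    def test_balanced_supply_has_unit_average_ratio(
        self, pop, anchored_model, demand, bands, kin
    ):
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=26_500),
            TemperatureProfile.constant(25.0),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        assert result.average_access_ratio == pytest.approx(1.0, abs=0.02)

    def test_zero_supply_all_ratios_zero(self, pop, anchored_model, demand, bands, kin):
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=0),
            TemperatureProfile.constant(25.0),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        assert all(r.access_ratio == 0.0 for r in result.records)
        assert result.average_access_ratio == 0.0

    def test_doubling_supply_raises_every_ratio(
        self, pop, anchored_model, demand, bands, kin
    ):
        # the first week of a cycle is pre-consumption, so its ratio scales
        # exactly with the order; later weeks carry the consumption history
        # and rise by more
        def run(annual):
            return simulate_year(
                pop, anchored_model, demand,
                SupplyPlan(annual_doses=annual),
                TemperatureProfile.constant(25.0),
                bands=bands, kinetics=kin, p_access=0.5,
            )

        single, double = run(26_500), run(53_000)
        assert double.records[0].access_ratio == pytest.approx(
            2 * single.records[0].access_ratio, rel=1e-9
        )
        for one, two in zip(single.records, double.records):
            assert two.access_ratio >= one.access_ratio

    @pytest.mark.parametrize(
        "annual, shipments, temp",
        [
            (26_500, 2, 25.0),
            (26_500, 2, 40.0),
            (26_500, 4, 45.0),
            (100_000, 2, 25.0),
            (10_000, 1, 35.0),
        ],
    )
    def test_dose_conservation(
        self, pop, anchored_model, demand, bands, kin, annual, shipments, temp
    ):
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=annual, shipments_per_year=shipments),
            TemperatureProfile.constant(temp),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        assert result.doses_supplied == (
            result.doses_consumed
            + result.doses_written_off
            + result.doses_carried_over
        )

    @pytest.mark.parametrize("temp", [25.0, 35.0])
    def test_sawtooth_troughs_immediately_before_shipments(
        self, pop, anchored_model, demand, bands, kin, temp
    ):
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=26_500),
            TemperatureProfile.constant(temp),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        ratios = [r.access_ratio for r in result.records]
        for cycle in (ratios[:26], ratios[26:]):
            assert all(a >= b for a, b in zip(cycle, cycle[1:]))
            assert min(cycle) == cycle[-1]
        # restock at week 26 lifts the ratio off the trough
        assert ratios[26] > ratios[25]

    def test_zero_demand_is_undefined(self, anchored_model, demand, bands, kin):
        from oxyaccess import PopulationState

        with pytest.raises(UndefinedRatioError):
            simulate_year(
                PopulationState(annual_births=0),
                anchored_model,
                demand,
                SupplyPlan(annual_doses=1000),
                TemperatureProfile.constant(25.0),
                bands=bands,
                kinetics=kin,
            )


class TestDailyOracleAgreement:
    @pytest.mark.parametrize("temp", [25.0, 30.0, 35.0, 40.0, 45.0])
    @pytest.mark.parametrize("annual", [26_500, 53_000])
    def test_weekly_engine_matches_day_resolution_oracle(
        self, pop, anchored_model, demand, bands, kin, temp, annual
    ):
        result = simulate_year(
            pop,
            anchored_model,
            demand,
            SupplyPlan(annual_doses=annual),
            TemperatureProfile.constant(temp),
            bands=bands,
            kinetics=kin,
            p_access=0.5,
        )
        oracle_ratios = daily_simulation(annual, 2, temp, weekly_demand(pop, 0.5, demand))
        oracle_avg = sum(oracle_ratios) / len(oracle_ratios)
        assert result.average_access_ratio == pytest.approx(
            oracle_avg, rel=0.02, abs=1e-9
        )


class TestMinimalSupply:
    def test_national_requirement_at_half_access(self, pop, anchored_model, demand):
        assert minimal_supply(1.0, pop, anchored_model, demand, p_access=0.5) == 26_500

    def test_closed_form_cross_check_under_cold_storage(
        self, pop, anchored_model, demand
    ):
        # at <= 25 degC no cohort leaves the full-strength band, so the
        # requirement is the annual served demand rounded to hundreds
        for p in (0.5, 1.0):
            expected = round(52 * weekly_demand(pop, p, demand) / 100) * 100
            assert (
                minimal_supply(1.0, pop, anchored_model, demand, p_access=p) == expected
            )

    def test_monotone_in_target_access_and_temperature(
        self, pop, anchored_model, demand
    ):
        by_target = [
            minimal_supply(t, pop, anchored_model, demand, p_access=0.5)
            for t in (0.5, 1.0, 1.5)
        ]
        assert by_target == sorted(by_target)
        by_access = [
            minimal_supply(1.0, pop, anchored_model, demand, p_access=p)
            for p in (0.25, 0.5, 1.0)
        ]
        assert by_access == sorted(by_access)
        by_temp = [
            minimal_supply(1.0, pop, anchored_model, demand, temp=t, p_access=0.5)
            for t in (25.0, 35.0, 45.0)
        ]
        assert by_temp == sorted(by_temp)
        assert by_temp[0] < by_temp[-1]

    def test_zero_births_raise(self, anchored_model, demand):
        from oxyaccess import PopulationState

        with pytest.raises(UndefinedRatioError):
            minimal_supply(
                1.0, PopulationState(annual_births=0), anchored_model, demand
            )
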