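"""Discounting, QALY and cost accrual rules."""

import numpy as np
import pytest

from tbicea.markov import build_schedule, point_inputs, run_cohort
from tbicea.valuation import (
    AgeUtilityMultiplier,
    DiscountSpec,
    StrategyResult,
    UtilityModel,
    arm_costs,
    bundled_age_multiplier,
    discount_factor,
    life_years,
    qalys,
    value_strategy,
)


class TestDiscountFactor:
    def test_values(self):
        assert discount_factor(DiscountSpec(0.0), 5.0) == 1.0
        assert discount_factor(DiscountSpec(0.035), 1.0) == pytest.approx(0.96618, abs=1e-5)
        assert discount_factor(DiscountSpec(0.06), 0.0) == 1.0

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            DiscountSpec(0.2)


@pytest.fixture(scope="module")
def uk_traces(uk_params, uk_table):
    inputs = point_inputs(uk_params)
    return {
        arm: run_cohort(build_schedule(inputs, uk_table, arm))
        for arm in ("control", "treated")
    }, inputs


class TestLifeYears:
    def test_annuity_closed_form(self, uk_params, uk_table):
        # immortal cohort over a 10-year horizon: discounted life-years are
        # the annuity sum over the annual cycles plus the (almost undiscounted)
        # first year of daily cycles
        inputs = point_inputs(uk_params).replace(
            p28_head=0.0, p28_nonhead=0.0, smr_year1=0.0, smr_later=0.0,
            horizon_years=10.0,
        )
        tr = run_cohort(build_schedule(inputs, uk_table, "control"))
        assert life_years(tr, DiscountSpec(0.0)) == pytest.approx(10.0, rel=1e-12)
        r = 0.035
        daily_part = np.sum((1 + r) ** -(np.arange(365) / 365)) / 365
        annual_part = np.sum((1 + r) ** -(1.0 + np.arange(9)))
        assert life_years(tr, DiscountSpec(r)) == pytest.approx(
            daily_part + annual_part, rel=1e-12
        )

    def test_discounted_never_exceeds_undiscounted(self, uk_traces):
        traces, _ = uk_traces
        for tr in traces.values():
            assert life_years(tr, DiscountSpec(0.035)) <= life_years(tr, DiscountSpec(0.0))

    def test_discount_ordering_across_rates(self, uk_traces):
        traces, _ = uk_traces
        tr = traces["control"]
        ly = [life_years(tr, DiscountSpec(r)) for r in (0.0, 0.035, 0.06)]
        assert ly[0] > ly[1] > ly[2]


class TestQalys:
    def test_utility_one_no_deaths_equals_life_years(self, uk_params, uk_table):
        inputs = point_inputs(uk_params).replace(
            p28_head=0.0, p28_nonhead=0.0, smr_year1=0.0, smr_later=0.0,
            horizon_years=10.0,
        )
        tr = run_cohort(build_schedule(inputs, uk_table, "control"))
        u = UtilityModel(base_utility=1.0, age_multiplier=None)
        assert qalys(tr, u, DiscountSpec(0.0)) == pytest.approx(
            life_years(tr, DiscountSpec(0.0)), rel=1e-12
        )

    def test_zero_utility_gives_zero(self, uk_traces):
        traces, _ = uk_traces
        u = UtilityModel(base_utility=0.0)
        assert qalys(traces["control"], u, DiscountSpec(0.035)) == 0.0

    def test_linearity_in_base_utility(self, uk_traces, age_mult):
        traces, _ = uk_traces
        d = DiscountSpec(0.035)
        full = qalys(traces["control"], UtilityModel(0.75, age_mult), d)
        half = qalys(traces["control"], UtilityModel(0.375, age_mult), d)
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_decedent_rule_reduces_qalys(self, uk_traces, age_mult):
        traces, _ = uk_traces
        d = DiscountSpec(0.035)
        with_rule = qalys(traces["control"], UtilityModel(0.75, age_mult, True), d)
        without = qalys(traces["control"], UtilityModel(0.75, age_mult, False), d)
        assert with_rule < without
        # the adjustment is small: at most the trial deaths over 28 days
        assert without - with_rule < 0.75 * 0.08 * 28 / 365

    def test_qalys_below_life_years_for_subunit_utility(self, uk_traces, age_mult):
        traces, _ = uk_traces
        d = DiscountSpec(0.035)
        q = qalys(traces["control"], UtilityModel(0.75, age_mult), d)
        assert q <= life_years(traces["control"], d)


class TestAgeMultiplier:
    def test_bundled_table_normalised_at_entry_age(self, age_mult):
        assert age_mult(42) == 1.0
        assert age_mult(41) == 1.0
        assert age_mult(43) == pytest.approx(0.996)
        assert np.all(np.diff(age_mult(np.arange(42, 101))) <= 0)

    def test_floor_lookup_and_clamping(self, age_mult):
        assert age_mult(43.9) == age_mult(43)
        assert age_mult(150) == age_mult(100)

    def test_increasing_multiplier_rejected(self):
        with pytest.raises(ValueError):
            AgeUtilityMultiplier([40, 41, 42], [0.9, 1.0, 1.1])


class TestArmCosts:
    def test_pakistan_control_cost_is_hospital_only(self, pk_params, pk_table):
        inputs = point_inputs(pk_params)
        tr = run_cohort(build_schedule(inputs, pk_table, "control"))
        cost = arm_costs(tr, inputs, DiscountSpec(inputs.discount_rate), "control")
        assert cost == pytest.approx(92.0)

    def test_treatment_components_only_in_treated_arm(self, uk_traces):
        traces, inputs = uk_traces
        d = DiscountSpec(inputs.discount_rate)
        # identical trace in both arms isolates the treatment lump exactly
        c = arm_costs(traces["control"], inputs, d, "control")
        t = arm_costs(traces["control"], inputs, d, "treated")
        assert t - c == pytest.approx(inputs.treatment_cost, rel=1e-12)

    def test_equal_los_cancels_in_increment(self, uk_traces):
        traces, inputs = uk_traces
        d = DiscountSpec(inputs.discount_rate)
        base = arm_costs(traces["treated"], inputs, d, "treated") - arm_costs(
            traces["control"], inputs, d, "control"
        )
        doubled = inputs.replace(hospital_cost_per_day=2 * inputs.hospital_cost_per_day)
        more = arm_costs(traces["treated"], doubled, d, "treated") - arm_costs(
            traces["control"], doubled, d, "control"
        )
        assert base == pytest.approx(more, rel=1e-9)

    def test_monitoring_duration_limits(self, uk_traces):
        traces, inputs = uk_traces
        d = DiscountSpec(inputs.discount_rate)
        tr = traces["control"]
        lifetime = arm_costs(tr, inputs, d, "control")
        one_year = arm_costs(tr, inputs.replace(monitoring_duration_years=1.0), d, "control")
        five_years = arm_costs(tr, inputs.replace(monitoring_duration_years=5.0), d, "control")
        assert one_year < five_years < lifetime
        # first-year-only removes all annual monitoring but keeps the daily accrual
        assert one_year > 4741

    def test_incremental_cost_decomposition(self, uk_traces):
        """Treatment components are a small share of UK incremental costs;
        survivor-driven monitoring dominates (printed split 3% / 97%)."""
        traces, inputs = uk_traces
        d = DiscountSpec(inputs.discount_rate)
        d_cost = arm_costs(traces["treated"], inputs, d, "treated") - arm_costs(
            traces["control"], inputs, d, "control"
        )
        share = inputs.treatment_cost / d_cost
        assert share == pytest.approx(0.03, abs=0.03)
        assert 1 - share == pytest.approx(0.97, abs=0.03)


class TestValueStrategy:
    def test_composition(self, uk_traces, age_mult):
        traces, inputs = uk_traces
        d = DiscountSpec(inputs.discount_rate)
        u = UtilityModel(0.747, age_mult)
        res = value_strategy(traces["treated"], u, inputs, d, "treated")
        assert res.total_cost == arm_costs(traces["treated"], inputs, d, "treated")
        assert res.life_years == life_years(traces["treated"], d)
        assert res.qalys == qalys(traces["treated"], u, d)

    def test_non_finite_results_rejected(self):
        with pytest.raises(ValueError):
            StrategyResult(total_cost=float("nan"), life_years=1.0, qalys=1.0)
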