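"""ICER/NMB arithmetic, PSA machinery, CEAC and scenario runs."""

import dataclasses

import numpy as np
import pytest

from tbicea.cea import (
    DEFAULT_DELAY_TABLE,
    DelayEffectTable,
    ceac,
    default_threshold_grid,
    icer,
    nmb,
    one_way_scenarios,
    run_deterministic,
    run_psa,
    time_to_treatment,
    tornado_entries,
)
from tbicea.parameters import FixedSpec, GosUtilitySet
from tbicea.valuation import StrategyResult


def _sr(cost, ly, q):
    return StrategyResult(total_cost=cost, life_years=ly, qalys=q)


class TestIcer:
    def test_direct_ratio(self):
        res = icer(_sr(0, 10, 5), _sr(100, 10.1, 5.05))
        assert res.icer_per_qaly == pytest.approx(2000)
        assert res.dominance_flag == "none"

    def test_published_rounded_table_arithmetic(self):
        """The rounded published cost/QALY columns give 759/0.18 ~ 4217,
        consistent with the exact 4288 given column rounding."""
        res = icer(_sr(55_110, 16.87, 12.10), _sr(55_869, 17.12, 12.28))
        assert res.icer_per_qaly == pytest.approx(759 / 0.18, rel=1e-9)
        assert res.icer_per_qaly == pytest.approx(4288, rel=0.03)
        assert res.icer_per_ly == pytest.approx(3078, rel=0.015)

    def test_dominance_flags(self):
        assert icer(_sr(100, 10, 5), _sr(50, 10.2, 5.1)).dominance_flag == "treated_dominates"
        assert icer(_sr(100, 10, 5), _sr(150, 9.8, 4.9)).dominance_flag == "treated_dominated"
        undef = icer(_sr(100, 10, 5), _sr(150, 10, 5))
        assert undef.dominance_flag == "undefined"
        assert undef.icer_per_qaly is None


class TestNmb:
    def test_arithmetic(self):
        assert nmb(_sr(97, 11.04, 11.04), 0) == -97
        assert nmb(_sr(97, 14.0, 11.04), 158) == pytest.approx(1647.32)

    def test_incremental_nmb_sign_matches_icer_vs_threshold(self):
        res = icer(_sr(0, 10, 5), _sr(100, 10.1, 5.05))  # ICER 2000
        assert res.nmb_incremental(2500) > 0
        assert res.nmb_incremental(1500) < 0


class TestDeterministic:
    def test_null_effect_is_undefined_with_treatment_cost(self, uk_params, uk_table):
        null = uk_params.replace(rr_head=FixedSpec(1.0))
        res = run_deterministic(null, uk_table)
        assert res.delta_qaly == pytest.approx(0.0, abs=1e-12)
        assert res.delta_cost == pytest.approx(
            uk_params.costs.treatment_component_total, rel=1e-6
        )
        assert res.dominance_flag == "undefined"

    def test_deltas_consistent(self, uk_params, uk_table):
        res = run_deterministic(uk_params, uk_table)
        assert res.delta_cost == pytest.approx(
            res.treated.total_cost - res.control.total_cost
        )
        assert res.icer_per_qaly == pytest.approx(res.delta_cost / res.delta_qaly)
        assert res.delta_qaly > 0 and res.delta_ly > res.delta_qaly


def _all_fixed(params):
    """Replace every sampling distribution by its point value."""
    u = params.utilities
    fixed_u = GosUtilitySet(
        utility_good=FixedSpec(u.utility_good.mean),
        utility_moderate=FixedSpec(u.utility_moderate.mean),
        utility_severe=FixedSpec(u.utility_severe.mean),
        utility_vegetative=u.utility_vegetative,
        counts_good=u.counts_good,
        counts_moderate=u.counts_moderate,
        counts_severe=u.counts_severe,
        counts_vegetative=u.counts_vegetative,
    )
    return params.replace(
        p28_head=FixedSpec(params.p28_head.mean),
        p28_nonhead=FixedSpec(params.p28_nonhead.mean),
        rr_head=FixedSpec(params.rr_head.point),
        smr_year1=FixedSpec(params.smr_year1.mean),
        smr_later=FixedSpec(params.smr_later.mean),
        utilities=fixed_u,
        costs=dataclasses.replace(
            params.costs, los_days=FixedSpec(params.costs.los_days_point)
        ),
    )


class TestPsa:
    def test_degenerate_psa_equals_deterministic(self, uk_params, uk_table):
        """With every distribution collapsed to a point, each PSA draw must
        reproduce the deterministic result exactly, for any n_sims."""
        det = run_deterministic(uk_params, uk_table)
        psa = run_psa(_all_fixed(uk_params), uk_table, n_sims=3, seed=5)
        assert np.allclose(psa.delta_cost, det.delta_cost, rtol=1e-12)
        assert np.allclose(psa.delta_qaly, det.delta_qaly, rtol=1e-12)
        assert psa.mean_icer == pytest.approx(det.icer_per_qaly, rel=1e-12)

    def test_seed_reproducibility(self, pk_params, pk_table):
        a = run_psa(pk_params, pk_table, n_sims=40, seed=7)
        b = run_psa(pk_params, pk_table, n_sims=40, seed=7)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_qaly, b.delta_qaly)
        c = run_psa(pk_params, pk_table, n_sims=40, seed=8)
        assert not np.array_equal(a.delta_qaly, c.delta_qaly)

    def test_prob_ce_is_ceac_at_threshold(self, pk_params, pk_table):
        psa = run_psa(pk_params, pk_table, n_sims=60, seed=1)
        curve = ceac(psa, [0.0, pk_params.threshold, 1e9])
        assert psa.prob_ce_at_threshold == curve["probability"].iloc[1]

    def test_ceac_limits_and_monotonicity(self, pk_params, pk_table):
        psa = run_psa(pk_params, pk_table, n_sims=60, seed=2)
        grid = default_threshold_grid(pk_params.threshold)
        curve = ceac(psa, grid)
        assert curve["probability"].iloc[0] == np.mean(psa.delta_cost < 0)
        if np.all(psa.delta_qaly >= 0):
            assert np.all(np.diff(curve["probability"]) >= 0)
        huge = psa.prob_cost_effective(1e12)
        assert huge == np.mean(psa.delta_qaly > 0)


class TestScenarios:
    def test_identity_scenario_reproduces_base_case(self, uk_params, uk_table):
        base = run_deterministic(uk_params, uk_table)
        scen = one_way_scenarios(uk_params, uk_table, names=("base_case",))
        assert scen["base_case"].icer_per_qaly == base.icer_per_qaly

    def test_unknown_scenario_rejected(self, uk_params, uk_table):
        with pytest.raises(KeyError):
            one_way_scenarios(uk_params, uk_table, names=("not_a_scenario",))

    def test_base_unchanged_between_scenarios(self, uk_params, uk_table):
        scen = one_way_scenarios(
            uk_params, uk_table, names=("base_case", "discount_0pct", "base_case")
        )
        assert scen["base_case"].icer_per_qaly == run_deterministic(
            uk_params, uk_table
        ).icer_per_qaly

    def test_tornado_entries_cover_pairs(self, pk_params, pk_table):
        scen = one_way_scenarios(pk_params, pk_table)
        entries = tornado_entries(scen)
        names = {e.scenario_name for e in entries}
        assert "treatment_effect_rr" in names and "discount_rate" in names
        rr = next(e for e in entries if e.scenario_name == "treatment_effect_rr")
        assert rr.icer_low < rr.icer_high


class TestTimeToTreatment:
    def test_lower_rr_monotonically_improves_icer(self, uk_params, uk_table):
        delays = DelayEffectTable(rows=((30.0, 0.62), (120.0, 0.78), (180.0, 0.9)))
        results = time_to_treatment(uk_params, uk_table, delays)
        icers = [r.icer_per_qaly for _, r in results]
        assert icers == sorted(icers)
        d_qalys = [r.delta_qaly for _, r in results]
        assert d_qalys == sorted(d_qalys, reverse=True)

    def test_invalid_delay_table_rejected(self):
        with pytest.raises(ValueError):
            DelayEffectTable(rows=((60.0, 0.62), (30.0, 0.78)))
        with pytest.raises(ValueError):
            DelayEffectTable(rows=((30.0, -0.5),))

    def test_default_table_has_published_30min_point(self):
        assert DEFAULT_DELAY_TABLE.rows == ((30.0, 0.62),)
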