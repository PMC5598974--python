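"""Cohort engine: discounting, accrual arithmetic, conservation, identities."""

import numpy as np
import pytest

from hsamcea import ScenarioSpec, run_cohort, run_pair
from hsamcea.engine import (
    CycleAccruals,
    accrue_cycle_costs,
    accrue_cycle_qalys,
    advance_cycle,
    annualized_fall_dw,
    discount_factor,
    initial_state,
)
from hsamcea.strata import N_AGE

from conftest import make_toy_params, toy_population


def zero_accruals() -> dict[str, np.ndarray]:
    return {
        name: np.zeros((N_AGE, 2, 2))
        for name in (
            "surv_comm",
            "surv_rc",
            "deaths",
            "falls_hosp",
            "falls_nonhosp",
            "falls_surviving",
            "new_high_risk_unmod",
        )
    }


class TestDiscounting:
    def test_reference_value(self):
        assert discount_factor(0.03, 5) == pytest.approx(0.8626087843841639, abs=1e-15)

    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0.03, 0) == 1.0

    def test_zero_rate_is_identity(self):
        assert discount_factor(0.0, 17) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)


class TestAnnualizedDW:
    def test_published_value(self):
        assert annualized_fall_dw(0.30, 4.0) == pytest.approx(0.10, abs=1e-15)

    def test_other_example(self):
        assert annualized_fall_dw(0.39, 4.0) == pytest.approx(0.13, abs=1e-15)

    def test_validation(self):
        with pytest.raises(ValueError):
            annualized_fall_dw(1.2, 4.0)
        with pytest.raises(ValueError):
            annualized_fall_dw(0.3, 0.0)
        with pytest.raises(ValueError):
            annualized_fall_dw(0.3, 13.0)


class TestAccrualArithmetic:
    def test_qalys_survivor_and_death_weighting(self):
        params = make_toy_params(yld=0.10, dw=0.10)
        acc = zero_accruals()
        acc["surv_comm"][0, 0, 0] = 1.0  # one surviving person-year at YLD 0.1
        acc["deaths"][0, 0, 1] = 1.0  # one death: half a cycle at utility 0.9
        acc["falls_surviving"][0, 0, 0] = 1.0  # subtracts the annualized DW
        q = accrue_cycle_qalys(CycleAccruals(**acc), params)
        assert q == pytest.approx(0.9 + 0.5 * 0.9 - 0.10, abs=1e-12)

    def test_fall_cost_reproduces_published_2011_total(self):
        # 1364 hospitalized at $4068 plus 5097 non-hospitalized at $344
        params = make_toy_params(cost_nonhosp=344.0, cost_hosp=4068.0)
        acc = zero_accruals()
        acc["falls_hosp"][0, 0, 0] = 1364.0
        acc["falls_nonhosp"][0, 0, 0] = 5097.0
        costs = accrue_cycle_costs(CycleAccruals(**acc), params)
        assert costs["fall_hosp"] + costs["fall_nonhosp"] == pytest.approx(
            7_302_120.0, abs=1e-6
        )

    def test_background_and_last6mo_costs(self):
        params = make_toy_params(bg_cost=1000.0, bg_cost_last6mo=5000.0)
        acc = zero_accruals()
        acc["surv_comm"][3, 1, 0] = 10.0
        acc["deaths"][3, 1, 0] = 2.0
        costs = accrue_cycle_costs(CycleAccruals(**acc), params)
        assert costs["background"] == pytest.approx(10_000.0, abs=1e-9)
        assert costs["last6mo"] == pytest.approx(10_000.0, abs=1e-9)


class TestStateAndConservation:
    def test_initial_state_mass_and_risk_split(self):
        pop = toy_population(1000.0)
        state = initial_state(pop, high_risk_share=0.10)
        assert state.total_alive() == pytest.approx(1000.0, abs=1e-9)
        high = state.comm[..., 1:].sum()
        assert high == pytest.approx(100.0, abs=1e-9)
        # spread evenly over clocks 1..5
        per_clock = state.comm[:, :, :, :, 1].sum()
        assert per_clock == pytest.approx(20.0, abs=1e-9)

    def test_mass_conserved_every_cycle(self):
        params = make_toy_params()
        state = initial_state(toy_population(1000.0), params.high_risk_share)
        sc = ScenarioSpec("base_case")
        for _ in range(20):
            state, _ = advance_cycle(state, params, sc)
            total = state.total_alive() + float(state.dead.sum())
            assert total == pytest.approx(1000.0, abs=1e-9 * 1000.0)

    def test_default_build_conserves_mass(self, default_params, default_population):
        state = initial_state(
            default_population.by_age, default_params.high_risk_share
        )
        sc = ScenarioSpec("base_case")
        for _ in range(46):
            state, _ = advance_cycle(state, default_params, sc)
        total = state.total_alive() + float(state.dead.sum())
        assert total == pytest.approx(41_736.0, rel=1e-9)

    def test_everyone_dead_by_age_110(self, default_params, default_population):
        result = run_cohort(
            default_params, ScenarioSpec("base_case"), default_population, "baseline"
        )
        # after 46 cycles the youngest 65-year-old has reached age 111
        state = initial_state(default_population.by_age, default_params.high_risk_share)
        for _ in range(46):
            state, _ = advance_cycle(state, default_params, ScenarioSpec("base_case"))
        assert state.total_alive() == pytest.approx(0.0, abs=1e-9)
        assert result.qalys > 0


class TestIdentities:
    def test_null_intervention_zero_increments(self):
        params = make_toy_params(rr_hsam=1.0, cost_hsam=0.0, cost_program=0.0)
        base, interv = run_pair(params, ScenarioSpec("base_case"), toy_population())
        # zero to float precision: 1e-9 relative to the totals being differenced
        assert interv.qalys - base.qalys == pytest.approx(0.0, abs=1e-9 * base.qalys)
        assert interv.total_cost - base.total_cost == pytest.approx(
            0.0, abs=1e-9 * base.total_cost
        )

    def test_null_intervention_on_default_build(self, default_params, default_population):
        params = default_params.copy()
        params.rr_hsam = 1.0
        params.cost_hsam_per_person = 0.0
        params.cost_program_per_person = 0.0
        base, interv = run_pair(params, ScenarioSpec("base_case"), default_population)
        assert interv.qalys - base.qalys == pytest.approx(0.0, abs=1e-6)
        assert interv.total_cost - base.total_cost == pytest.approx(0.0, abs=1e-4)

    def test_zero_discount_equals_undiscounted(self, default_params, default_population):
        sc = ScenarioSpec("nodisc", discount_rate=0.0)
        result = run_cohort(default_params, sc, default_population, "intervention")
        assert result.qalys == pytest.approx(result.qalys_undiscounted, rel=1e-9)

    def test_discounting_reduces_totals(self, default_params, default_population):
        r0 = run_cohort(
            default_params, ScenarioSpec("d0", discount_rate=0.0), default_population
        )
        r3 = run_cohort(
            default_params, ScenarioSpec("d3", discount_rate=0.03), default_population
        )
        assert r3.qalys < r0.qalys


class TestHorizonsAndTrend:
    def test_horizon_monotonicity(self, default_params, default_population):
        qalys = [
            run_cohort(
                default_params,
                ScenarioSpec(f"h{h}", horizon_years=h) if h else ScenarioSpec("life"),
                default_population,
                "baseline",
            ).qalys
            for h in (10, 20, None)
        ]
        assert qalys[0] < qalys[1] < qalys[2]

    def test_mortality_trend_lowers_later_mortality(self):
        from hsamcea.engine import _mortality_this_cycle

        params = make_toy_params()
        params.mortality_decline = {"maori": 0.0225, "non_maori": 0.0175}
        m0 = _mortality_this_cycle(params, 0)
        m2 = _mortality_this_cycle(params, 2)
        assert m2[0, 0, 1] == pytest.approx(m0[0, 0, 1] * (1 - 0.0175) ** 2, rel=1e-12)
        # flat after 2026
        m15 = _mortality_this_cycle(params, 15)
        m20 = _mortality_this_cycle(params, 20)
        assert np.allclose(m15[:-1], m20[:-1], rtol=1e-12)

    def test_age_110_absorbing(self):
        from hsamcea.engine import _mortality_this_cycle

        m = _mortality_this_cycle(make_toy_params(), 0)
        assert np.all(m[-1] == 1.0)


class TestRunResults:
    def test_trace_collected(self, default_params, default_population):
        base, interv = run_pair(
            default_params, ScenarioSpec("base_case"), default_population, collect_trace=True
        )
        frame = interv.trace_frame()
        assert {"cycle", "qalys", "deaths", "cost_background"} <= set(frame.columns)
        assert len(frame) == 46

    def test_unknown_arm_rejected(self, default_params, default_population):
        with pytest.raises(ValueError):
            run_cohort(
                default_params, ScenarioSpec("base_case"), default_population, "placebo"
            )
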