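"""Targeting rules, intervention costs, effectiveness decay and ICERs."""

import pytest

from hsamcea import ScenarioSpec, run_pair
from hsamcea.intervention import (
    COST_SAVING,
    DOMINATED,
    UNDEFINED,
    compute_icer,
    effective_rr,
    eligibility_mask,
    icer_rank_value,
    intervention_cost,
    select_targets,
    table2_scenarios,
)



class TestEligibility:
    def test_all_65plus_covers_everyone(self):
        mask = eligibility_mask("all_65plus")
        assert mask.shape == (46, 6)
        assert mask.all()

    def test_risk_filter_excludes_clock_zero(self):
        mask = eligibility_mask("risk_65plus")
        assert not mask[:, 0].any()
        assert mask[:, 1:].all()

    def test_age_cut(self):
        mask = eligibility_mask("all_75plus")
        assert not mask[:10].any()  # ages 65-74
        assert mask[10:].all()

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            eligibility_mask("all_60plus")


class TestSelectTargets:
    def test_partitions_of_population(self, default_population):
        h = 0.09
        totals = {
            rule: select_targets(default_population, rule, h)["eligible"].sum()
            for rule in ("all_65plus", "risk_65plus", "norisk_65plus")
        }
        assert totals["all_65plus"] == pytest.approx(41_736.0, abs=1e-6)
        assert totals["risk_65plus"] == pytest.approx(0.09 * 41_736.0, abs=1e-6)
        assert totals["risk_65plus"] + totals["norisk_65plus"] == pytest.approx(
            totals["all_65plus"], abs=1e-9
        )

    def test_narrowing_never_increases(self, default_population):
        h = 0.09
        for cut in ("65plus", "75plus"):
            all_n = select_targets(default_population, f"all_{cut}", h)["eligible"].sum()
            for part in ("risk", "norisk"):
                n = select_targets(default_population, f"{part}_{cut}", h)["eligible"].sum()
                assert n <= all_n + 1e-9


class TestEffectiveRR:
    def test_no_decay_full_effect(self):
        assert effective_rr(0.81, 7, None) == pytest.approx(0.81, abs=1e-15)

    def test_linear_decay(self):
        assert effective_rr(0.81, 0, 10) == pytest.approx(0.81, abs=1e-15)
        assert effective_rr(0.81, 5, 10) == pytest.approx(0.905, abs=1e-12)
        assert effective_rr(0.81, 10, 10) == pytest.approx(1.0, abs=1e-15)
        assert effective_rr(0.81, 15, 10) == pytest.approx(1.0, abs=1e-15)

    def test_harmful_draw_accepted(self):
        assert effective_rr(1.05, 0, None) == pytest.approx(1.05, abs=1e-15)

    def test_validation(self):
        with pytest.raises(ValueError):
            effective_rr(0.0, 0, None)
        with pytest.raises(ValueError):
            effective_rr(0.81, -1, None)


class TestInterventionCost:
    def test_program_cost_published_arithmetic(self):
        program, _ = intervention_cost(41_736, 0.89, 0.0, 44.0, 250.0, 1.0)
        assert program == pytest.approx(1_836_384.0, abs=1e-6)

    def test_program_cost_uptake_independent(self):
        p1, _ = intervention_cost(100, 0.1, 0.0, 44.0, 250.0, 1.0)
        p2, _ = intervention_cost(100, 0.9, 0.0, 44.0, 250.0, 1.0)
        assert p1 == p2 == pytest.approx(4400.0)

    def test_cohabitation_halves_marginal_cost(self):
        # everyone cohabiting: expected HSAM cost per participant is $125
        _, hsam = intervention_cost(1000, 1.0, 1.0, 0.0, 250.0, 1.0)
        assert hsam == pytest.approx(125.0 * 1000, abs=1e-9)

    def test_cost_multiplier(self):
        _, full = intervention_cost(1000, 1.0, 0.0, 0.0, 250.0, 1.0)
        _, cut = intervention_cost(1000, 1.0, 0.0, 0.0, 250.0, 2.0 / 3.0)
        assert cut == pytest.approx(full * 2.0 / 3.0, rel=1e-12)
        assert cut / 1000 == pytest.approx(250.0 * 2 / 3, rel=1e-12)


class TestICER:
    def test_ratio(self):
        assert compute_icer(5480.0 * 2800.0, 2800.0) == pytest.approx(5480.0)

    def test_cost_saving(self):
        assert compute_icer(-163_000.0, 281.0) == COST_SAVING

    def test_dominated(self):
        assert compute_icer(1000.0, -5.0) == DOMINATED

    def test_undefined(self):
        assert compute_icer(0.0, 0.0) == UNDEFINED

    def test_rank_value_orders_through_zero(self):
        better = icer_rank_value(-4_360_000.0, 1610.0)
        middle = icer_rank_value(-2_800_000.0, 1123.0)
        worse = icer_rank_value(1_320_000.0, 4187.0)
        none = icer_rank_value(100.0, 0.0)
        assert better < middle < worse < none


class TestScenarios:
    def test_published_grid(self):
        scenarios = table2_scenarios()
        assert len(scenarios) == 12
        assert len({s.name for s in scenarios}) == 12
        base = scenarios[0]
        assert base.name == "base_case"
        assert base.discount_rate == 0.03
        assert base.targeting == "all_65plus"

    def test_validation(self):
        with pytest.raises(ValueError):
            ScenarioSpec("bad", targeting="everyone")
        with pytest.raises(ValueError):
            ScenarioSpec("bad", discount_rate=-0.01)
        with pytest.raises(ValueError):
            ScenarioSpec("bad", horizon_years=0)
        with pytest.raises(ValueError):
            ScenarioSpec("bad", hsam_cost_multiplier=0.0)


class TestTargetingPartition:
    def test_risk_plus_norisk_equals_all(self, default_params, default_population):
        """With prospective delivery off, the risk and no-history arms
        modify disjoint parts of the population that together make up the
        all-comers arm, so gains and outlays add up exactly."""
        results = {}
        for rule in ("all_65plus", "risk_65plus", "norisk_65plus"):
            sc = ScenarioSpec(rule, targeting=rule, prospective_delivery=False)
            base, interv = run_pair(default_params, sc, default_population)
            results[rule] = (
                interv.qalys - base.qalys,
                interv.costs["intervention"],
                interv.total_cost - base.total_cost,
            )
        for i in range(3):
            assert results["risk_65plus"][i] + results["norisk_65plus"][i] == pytest.approx(
                results["all_65plus"][i], rel=1e-6, abs=1e-4
            )
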