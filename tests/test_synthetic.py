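"""Synthetic table generation: exact calibration, determinism, shape."""

import numpy as np
import pytest

from hsamcea.strata import all_strata
from hsamcea.synthetic import (
    BG_COST_ANCHORS,
    FALL_COUNT_2011,
    HOSP_FALL_COUNT_2011,
    POPULATION_65PLUS,
    CalibrationError,
    build_default_parameter_set,
    generate_background_tables,
    generate_case_costs,
    generate_conditional_hosp,
    generate_fall_fatality,
    generate_population,
    generate_stratified_rates,
    mortality_trend_multiplier,
    write_parameter_tables,
)

FALL_TARGET = FALL_COUNT_2011 / POPULATION_65PLUS  # 0.15480640214682767
HOSP_TARGET = HOSP_FALL_COUNT_2011 / POPULATION_65PLUS  # 0.032681617788000765


class TestPopulation:
    def test_total_is_exact(self):
        pop = generate_population()
        assert pop.counts["count"].sum() == POPULATION_65PLUS
        assert pop.by_age.sum() == pytest.approx(POPULATION_65PLUS, abs=1e-6)

    def test_uniform_shares_apportion_within_one(self):
        shares = {st: 1.0 / 20.0 for st in all_strata()}
        pop = generate_population(shares=shares)
        # 41,736 / 20 = 2086.8 -> largest-remainder counts are 2086 or 2087
        assert set(pop.counts["count"]) <= {2086, 2087}
        assert pop.counts["count"].sum() == POPULATION_65PLUS

    def test_band_weights_sum_to_one(self):
        w = generate_population().band_weights()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w.shape == (5, 2, 2)

    def test_bad_shares_rejected(self):
        shares = {st: 0.01 for st in all_strata()}
        with pytest.raises(CalibrationError):
            generate_population(shares=shares)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(CalibrationError):
            generate_population(total=0)


class TestFallRates:
    def test_aggregate_calibration_exact(self):
        pop = generate_population()
        w = pop.band_weights()
        p = generate_stratified_rates(FALL_TARGET, weights=w, seed=0)
        mix = 0.91 * p[..., 0] + 0.09 * p[..., 1]
        assert (w * mix).sum() == pytest.approx(FALL_TARGET, abs=1e-9)

    def test_risk_ratio_holds_everywhere(self):
        p = generate_stratified_rates(FALL_TARGET, risk_ratio_high_vs_low=2.0, seed=0)
        assert np.allclose(p[..., 1], 2.0 * p[..., 0], rtol=1e-12)

    def test_age_gradient_monotone(self):
        p = generate_stratified_rates(FALL_TARGET, seed=0)
        assert np.all(np.diff(p[..., 0], axis=0) >= 0)

    def test_seed_changes_shape_not_aggregate(self):
        pop = generate_population()
        w = pop.band_weights()
        p1 = generate_stratified_rates(FALL_TARGET, weights=w, seed=1)
        p2 = generate_stratified_rates(FALL_TARGET, weights=w, seed=2)
        assert not np.allclose(p1, p2)
        for p in (p1, p2):
            mix = 0.91 * p[..., 0] + 0.09 * p[..., 1]
            assert (w * mix).sum() == pytest.approx(FALL_TARGET, abs=1e-9)

    def test_infeasible_target_raises(self):
        with pytest.raises(CalibrationError):
            generate_stratified_rates(0.9, risk_ratio_high_vs_low=2.0, seed=0)

    def test_decreasing_gradient_rejected(self):
        with pytest.raises(CalibrationError):
            generate_stratified_rates(FALL_TARGET, gradient=(2.0, 1.5, 1.2, 1.1, 1.0))


class TestConditionalHosp:
    def test_joint_calibration_exact(self):
        pop = generate_population()
        w = pop.band_weights()
        p_fall = generate_stratified_rates(FALL_TARGET, weights=w, seed=0)
        h = generate_conditional_hosp(HOSP_TARGET, p_fall, w, seed=0)
        mix = 0.91 * p_fall[..., 0] + 0.09 * p_fall[..., 1]
        assert (w * mix * h).sum() == pytest.approx(HOSP_TARGET, abs=1e-9)
        assert np.all((h > 0) & (h < 1))


class TestFatality:
    def test_peak_is_exact_and_at_maori_men_65_69(self):
        f = generate_fall_fatality(peak=0.05, seed=0)
        assert f.max() == pytest.approx(0.05, abs=1e-15)
        band, sex, eth = np.unravel_index(f.argmax(), f.shape)
        assert (band, sex, eth) == (0, 1, 0)  # 65-69, male, Maori

    def test_all_cells_within_range(self):
        f = generate_fall_fatality(peak=0.05, seed=0)
        assert np.all(f > 0) and np.all(f <= 0.05)


class TestCaseCosts:
    def test_case_weighted_mean_exact(self):
        pop = generate_population()
        w = pop.band_weights()
        p_fall = generate_stratified_rates(FALL_TARGET, weights=w, seed=0)
        c = generate_case_costs(4068.0, p_fall, w, seed=0)
        mix = 0.91 * p_fall[..., 0] + 0.09 * p_fall[..., 1]
        cases = (w * mix).sum(axis=2)
        assert (cases * c).sum() / cases.sum() == pytest.approx(4068.0, rel=1e-9)


class TestBackgroundTables:
    def test_cost_anchors_exact(self):
        t = generate_background_tables(seed=0)
        # annual: women 65-69 and men 85-89 (ages 85-89 are indices 20-24)
        assert np.allclose(t["bg_cost"][0:5, 0], BG_COST_ANCHORS["annual_female_65_69"])
        assert np.allclose(t["bg_cost"][20:25, 1], BG_COST_ANCHORS["annual_male_85_89"])
        # last six months of life: women 65-69 and women 95-99 (indices 30-34)
        assert np.allclose(
            t["bg_cost_last6mo"][0:5, 0], BG_COST_ANCHORS["last6mo_female_65_69"]
        )
        assert np.allclose(
            t["bg_cost_last6mo"][30:35, 0], BG_COST_ANCHORS["last6mo_female_95_99"]
        )

    def test_annual_cost_flat_above_anchor_band(self):
        t = generate_background_tables(seed=0)
        assert np.allclose(t["bg_cost"][25:, :], t["bg_cost"][24, :])

    def test_mortality_rises_with_age_and_is_valid(self):
        t = generate_background_tables(seed=0)
        m = t["bg_mortality"]
        assert np.all((m >= 0) & (m <= 1))
        assert np.all(np.diff(m, axis=0) >= -1e-12)

    def test_trend_multiplier(self):
        assert mortality_trend_multiplier(0.0175, 2011, 2013) == pytest.approx(
            (1 - 0.0175) ** 2, abs=1e-15
        )
        # the decline stops after 2026
        assert mortality_trend_multiplier(0.0175, 2011, 2030) == pytest.approx(
            mortality_trend_multiplier(0.0175, 2011, 2026), abs=1e-15
        )


class TestDefaultBuild:
    def test_deterministic(self):
        p1, pop1 = build_default_parameter_set(seed=0)
        p2, pop2 = build_default_parameter_set(seed=0)
        assert np.array_equal(p1.p_fall, p2.p_fall)
        assert np.array_equal(pop1.by_age, pop2.by_age)

    def test_calibrated_aggregates(self, default_build):
        params, population = default_build
        w = population.band_weights()
        mix = (
            0.91 * params.p_fall[..., 0] + 0.09 * params.p_fall[..., 1]
        )
        assert (w * mix).sum() == pytest.approx(FALL_TARGET, abs=1e-9)
        assert (w * mix * params.p_hosp_given_fall).sum() == pytest.approx(
            HOSP_TARGET, abs=1e-9
        )
        assert params.p_death_given_fall.max() == pytest.approx(0.05, abs=1e-15)

    def test_config_overrides(self):
        cfg = {
            "population": {"total": 10_000},
            "falls": {
                "count": 1500,
                "hospitalized_count": 300,
                "reference_population": 10_000,
            },
            "intervention": {"rr_hsam": 0.75},
            "costs": {"hsam_per_person": 300.0},
        }
        params, population = build_default_parameter_set(seed=0, config=cfg)
        assert population.total == 10_000
        assert params.rr_hsam == 0.75
        assert params.cost_hsam_per_person == 300.0
        w = population.band_weights()
        mix = 0.91 * params.p_fall[..., 0] + 0.09 * params.p_fall[..., 1]
        assert (w * mix).sum() == pytest.approx(0.15, abs=1e-9)


class TestExport:
    def test_tables_written_with_calibration_notes(self, tmp_path, default_build):
        params, population = default_build
        paths = write_parameter_tables(params, population, tmp_path)
        names = {p.name for p in paths}
        assert {"population.csv", "p_fall.csv", "bg_mortality.csv"} <= names
        for p in paths:
            first = p.read_text().splitlines()[0]
            assert first.startswith("# calibration:")
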