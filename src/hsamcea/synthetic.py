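"""Synthetic stratified parameter tables for the district cohort.

The original analysis drew stratified injurious-fall rates, hospitalization
and case-fatality probabilities, background mortality/morbidity and health
system costs from administrative sources (injury-insurer claims, census and
mortality statistics, a national costing database) that are not public.
This module generates stand-in tables with plausible demographic gradients,
**calibrated so that every published aggregate is reproduced exactly**:

* district population 65+ of 41,736 across 20 (age band x sex x ethnicity)
  strata (largest-remainder rounding, so counts always sum exactly);
* overall annual injurious-fall probability 6461/41,736 (15.5%) and
  hospitalized-fall probability 1364/41,736 (3.3%), population-weighted;
* fall case fatality peaking at exactly 5% for Maori men aged 65-69;
* mean treatment costs of $344 (non-hospital) and $4068 (hospitalized) per
  case, case-weighted;
* background annual health-system cost anchors ($3378, women 65-69;
  $6511, men 85-89) and last-six-months-of-life anchors ($20,476, women
  65-69; $6127, women 95-99), hit exactly.

Different seeds jitter the within-range detail of the rate tables (the
demographic shape) but never the calibrated aggregates: tables are re-scaled
to their targets after jittering.  The jitter is applied per (sex,
ethnicity) cell, not per age band, so the monotone age gradients survive it
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterSet, default_uncertainty
from .strata import (
    AGE_BANDS,
    AGE_MIN,
    ETHNICITIES,
    N_AGE,
    N_BAND,
    SEXES,
    Stratum,
    all_strata,
)

# published aggregates used as calibration targets
POPULATION_65PLUS = 41_736
FALL_COUNT_2011 = 6461
HOSP_FALL_COUNT_2011 = 1364


class CalibrationError(ValueError):
    """A generated table cannot hit its calibration target feasibly."""


# --------------------------------------------------------------------------
# population
# --------------------------------------------------------------------------

#: default stratum composition: age-band shares of the 65+ population,
#: female share and Maori share within each band (younger age structure of
#: the Maori population, female predominance growing with age).
DEFAULT_BAND_SHARES = (0.36, 0.26, 0.18, 0.12, 0.08)
DEFAULT_FEMALE_SHARE = (0.52, 0.53, 0.55, 0.58, 0.64)
DEFAULT_MAORI_SHARE = (0.14, 0.11, 0.08, 0.06, 0.04)

# within-band single-year decline of the population (steeper in the open
# 85+ band, which the engine spreads over ages 85-110)
_WITHIN_BAND_DECAY = 0.97
_OPEN_BAND_DECAY = 0.82


@dataclass
class Population:
    """The simulated district population aged 65+.

    ``counts`` holds integer persons per (band, sex, ethnicity) stratum with
    the cohabiting fraction annotation; ``by_age`` spreads each stratum over
    single-year ages for the engine (float counts; stratum sums are exact).
    """

    counts: pd.DataFrame
    by_age: np.ndarray  # (N_AGE, 2, 2)
    share_cohabiting: float

    @property
    def total(self) -> float:
        return float(self.counts["count"].sum())

    def band_weights(self) -> np.ndarray:
        """(band, sex, eth) population shares (sum to 1)."""
        w = np.zeros((N_BAND, 2, 2))
        for band, sex, eth, n in zip(
            self.counts["age_band"],
            self.counts["sex"],
            self.counts["ethnicity"],
            self.counts["count"],
        ):
            w[AGE_BANDS.index(band), SEXES.index(sex), ETHNICITIES.index(eth)] = n
        return w / w.sum()


def default_stratum_shares() -> dict[Stratum, float]:
    shares: dict[Stratum, float] = {}
    for st in all_strata():
        b, s, e = st.indices
        sex_share = DEFAULT_FEMALE_SHARE[b] if s == 0 else 1.0 - DEFAULT_FEMALE_SHARE[b]
        eth_share = DEFAULT_MAORI_SHARE[b] if e == 0 else 1.0 - DEFAULT_MAORI_SHARE[b]
        shares[st] = DEFAULT_BAND_SHARES[b] * sex_share * eth_share
    return shares


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``shares`` (sums exactly)."""
    quotas = shares * total
    counts = np.floor(quotas).astype(int)
    remainder = int(round(total - counts.sum()))
    # ties broken by index order for determinism
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_population(
    total: int = POPULATION_65PLUS,
    shares: dict[Stratum, float] | None = None,
    share_cohabiting: float = 0.5,
    seed: int = 0,
) -> Population:
    """Stratified population with counts summing exactly to ``total``."""
    if total <= 0:
        raise CalibrationError("total population must be positive")
    if shares is None:
        shares = default_stratum_shares()
    strata = list(shares)
    vec = np.array([shares[st] for st in strata], dtype=float)
    if abs(vec.sum() - 1.0) > 1e-9:
        raise CalibrationError(f"stratum shares sum to {vec.sum()}, not 1")
    counts = _largest_remainder(total, vec)
    df = pd.DataFrame(
        {
            "age_band": [st.age_band for st in strata],
            "sex": [st.sex for st in strata],
            "ethnicity": [st.ethnicity for st in strata],
            "count": counts,
            "share_cohabiting": share_cohabiting,
        }
    )
    by_age = np.zeros((N_AGE, 2, 2))
    for st, n in zip(strata, counts):
        b, s, e = st.indices
        if b < N_BAND - 1:
            ages = np.arange(b * 5, b * 5 + 5)
            w = _WITHIN_BAND_DECAY ** np.arange(5)
        else:
            ages = np.arange(20, N_AGE)  # 85..110
            w = _OPEN_BAND_DECAY ** np.arange(N_AGE - 20)
        by_age[ages, s, e] += n * w / w.sum()
    return Population(counts=df, by_age=by_age, share_cohabiting=share_cohabiting)


# --------------------------------------------------------------------------
# stratified rate tables
# --------------------------------------------------------------------------

DEFAULT_FALL_GRADIENT = (1.0, 1.19, 1.41, 1.68, 2.0)  # doubles 65-69 -> 85+
DEFAULT_HOSP_GRADIENT = (1.0, 1.3, 1.7, 2.2, 2.8)  # severity rises with age


def _jitter(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Per-(sex, ethnicity) multiplicative noise; preserves age monotonicity."""
    if sd <= 0:
        return np.ones((2, 2))
    return np.exp(rng.normal(0.0, sd, size=(2, 2)))


def generate_stratified_rates(
    aggregate_target: float,
    gradient: tuple[float, ...] = DEFAULT_FALL_GRADIENT,
    risk_ratio_high_vs_low: float = 2.0,
    weights: np.ndarray | None = None,
    seed: int = 0,
    high_risk_share: float = 0.09,
    sex_mult: tuple[float, float] = (1.05, 1.0),
    eth_mult: tuple[float, float] = (1.10, 1.0),
    jitter_sd: float = 0.03,
) -> np.ndarray:
    """Per-stratum, per-risk-group annual probabilities.

    The population-weighted mean over strata and risk groups (mixed at
    ``high_risk_share``) equals ``aggregate_target`` exactly; the high-risk
    probability is ``risk_ratio_high_vs_low`` times the low-risk one in
    every stratum.  Returns an array of shape (band, sex, eth, risk).
    """
    grad = np.asarray(gradient, dtype=float)
    if not 0.0 < aggregate_target < 1.0:
        raise CalibrationError("aggregate target must lie in (0, 1)")
    if grad.shape != (N_BAND,) or np.any(grad <= 0) or np.any(np.diff(grad) < 0):
        raise CalibrationError("gradient must be positive and non-decreasing with age")
    if risk_ratio_high_vs_low < 1.0:
        raise CalibrationError("high/low risk ratio must be >= 1")
    if weights is None:
        weights = generate_population(seed=seed).band_weights()
    rng = np.random.default_rng(seed)
    shape = (
        grad[:, None, None]
        * np.asarray(sex_mult)[None, :, None]
        * np.asarray(eth_mult)[None, None, :]
        * _jitter(rng, jitter_sd)[None, :, :]
    )
    mix = (1.0 - high_risk_share) + high_risk_share * risk_ratio_high_vs_low
    scale = aggregate_target / float((weights * shape).sum() * mix)
    p_low = scale * shape
    p_high = risk_ratio_high_vs_low * p_low
    if np.any(p_high > 1.0):
        raise CalibrationError(
            "calibration infeasible: an implied probability exceeds 1"
        )
    return np.stack([p_low, p_high], axis=-1)


def generate_conditional_hosp(
    joint_target: float,
    p_fall: np.ndarray,
    weights: np.ndarray,
    gradient: tuple[float, ...] = DEFAULT_HOSP_GRADIENT,
    high_risk_share: float = 0.09,
    seed: int = 0,
    jitter_sd: float = 0.03,
) -> np.ndarray:
    """Conditional P(hospitalization | injurious fall) by stratum.

    Calibrated so the population probability of a hospitalized fall,
    sum_s w_s * p_fall_s * h_s (fall risk mixed over risk groups), equals
    ``joint_target`` exactly.
    """
    grad = np.asarray(gradient, dtype=float)
    if grad.shape != (N_BAND,) or np.any(grad <= 0) or np.any(np.diff(grad) < 0):
        raise CalibrationError("gradient must be positive and non-decreasing with age")
    rng = np.random.default_rng(seed + 1)
    fall_mix = (
        (1.0 - high_risk_share) * p_fall[..., 0] + high_risk_share * p_fall[..., 1]
    )
    shape = grad[:, None, None] * _jitter(rng, jitter_sd)[None, :, :]
    scale = joint_target / float((weights * fall_mix * shape).sum())
    h = scale * shape
    if np.any(h > 1.0):
        raise CalibrationError("calibration infeasible: conditional probability > 1")
    return h


DEFAULT_FATALITY_AGE_MULT = (1.1, 1.05, 1.0, 0.95, 0.9)


def generate_fall_fatality(
    peak: float = 0.05,
    age_mult: tuple[float, ...] = DEFAULT_FATALITY_AGE_MULT,
    sex_mult: tuple[float, float] = (1.0, 1.25),
    eth_mult: tuple[float, float] = (1.3, 1.0),
    seed: int = 0,
    jitter_sd: float = 0.03,
) -> np.ndarray:
    """Probability of death after an injurious fall, by stratum.

    Anchored so the highest cell — Maori men aged 65-69, as published —
    equals ``peak`` exactly; everything else scales within [0, peak].
    """
    rng = np.random.default_rng(seed + 2)
    shape = (
        np.asarray(age_mult)[:, None, None]
        * np.asarray(sex_mult)[None, :, None]
        * np.asarray(eth_mult)[None, None, :]
        * _jitter(rng, jitter_sd)[None, :, :]
    )
    return peak * shape / shape.max()


def generate_case_costs(
    mean_per_case: float,
    p_fall: np.ndarray,
    weights: np.ndarray,
    high_risk_share: float = 0.09,
    gradient: tuple[float, ...] = (0.8, 0.9, 1.0, 1.15, 1.3),
    sex_mult: tuple[float, float] = (1.0, 1.1),
    seed: int = 0,
    jitter_sd: float = 0.03,
) -> np.ndarray:
    """Per-case treatment cost by (band, sex), case-weighted mean exact."""
    rng = np.random.default_rng(seed + 3)
    fall_mix = (
        (1.0 - high_risk_share) * p_fall[..., 0] + high_risk_share * p_fall[..., 1]
    )
    cases = (weights * fall_mix).sum(axis=2)  # (band, sex)
    jit = np.exp(rng.normal(0.0, jitter_sd, size=2)) if jitter_sd > 0 else np.ones(2)
    shape = np.asarray(gradient)[:, None] * (np.asarray(sex_mult) * jit)[None, :]
    scale = mean_per_case * cases.sum() / float((cases * shape).sum())
    return scale * shape


# --------------------------------------------------------------------------
# background mortality, morbidity and costs
# --------------------------------------------------------------------------

BG_COST_ANCHORS = {
    "annual_female_65_69": 3378.0,
    "annual_male_85_89": 6511.0,
    "last6mo_female_65_69": 20_476.0,
    "last6mo_female_95_99": 6127.0,
}

MORTALITY_DECLINE = {"maori": 0.0225, "non_maori": 0.0175}

_EXT_BAND_OF_AGE = np.minimum((np.arange(N_AGE)) // 5, 9)  # 65-69 ... 110


def generate_background_tables(
    cost_anchors: dict[str, float] | None = None,
    mortality_level: float = 0.0105,
    mortality_slope: float = 0.101,
    mortality_sex_mult: tuple[float, float] = (1.0, 1.6),
    mortality_eth_mult: tuple[float, float] = (1.9, 1.0),
    male_cost_ratio: float = 1.12,
    seed: int = 0,
    jitter_sd: float = 0.02,
) -> dict[str, np.ndarray]:
    """Background cost, end-of-life cost, mortality and YLD tables.

    Annual health-system costs step up by five-year age band between the
    two published anchors (women 65-69 = $3378; men 85-89 = $6511) and are
    held flat above 85-89, keeping the table inside the published range.
    Last-six-months-of-life costs *decline* with age between their anchors
    (women 65-69 = $20,476; women 95-99 = $6127) and are held flat beyond.
    Background mortality follows a Gompertz curve in age (2011 level) with
    sex and ethnicity multipliers; YLD per capita rises with age and is
    higher for Maori.
    """
    a = dict(BG_COST_ANCHORS)
    if cost_anchors:
        a.update(cost_anchors)
    rng = np.random.default_rng(seed + 4)

    # annual background cost (age, sex); exponential growth between anchors
    lo = a["annual_female_65_69"]
    hi = a["annual_male_85_89"]
    g = np.log(hi / (male_cost_ratio * lo)) / 20.0  # per year of age, 67 -> 87
    eb = np.minimum(_EXT_BAND_OF_AGE, 4)  # flat above 85-89
    female = lo * np.exp(g * 5.0 * eb)
    bg_cost = np.stack([female, male_cost_ratio * female], axis=1)

    # last-6-months-of-life cost (age, sex); declines with age, flat past 95-99
    top = a["last6mo_female_65_69"]
    bottom = a["last6mo_female_95_99"]
    d = np.log(top / bottom) / 30.0
    eb6 = np.minimum(_EXT_BAND_OF_AGE, 6)
    l6 = top * np.exp(-d * 5.0 * eb6)
    bg_cost_last6mo = np.stack([l6, l6], axis=1)

    # Gompertz background mortality, 2011 level
    ages = np.arange(N_AGE, dtype=float)
    jit = np.exp(rng.normal(0.0, jitter_sd, size=(2, 2))) if jitter_sd > 0 else np.ones((2, 2))
    bg_mortality = (
        mortality_level
        * np.exp(mortality_slope * ages)[:, None, None]
        * np.asarray(mortality_sex_mult)[None, :, None]
        * np.asarray(mortality_eth_mult)[None, None, :]
        * jit[None, :, :]
    )
    np.clip(bg_mortality, 0.0, 1.0, out=bg_mortality)

    # per-capita YLD (band, sex, eth): rising with age, higher for Maori
    yld_band = np.array([0.09, 0.11, 0.13, 0.16, 0.21])
    yld = (
        yld_band[:, None, None]
        * np.array([1.0, 0.92])[None, :, None]  # men slightly lower
        * np.array([1.25, 1.0])[None, None, :]  # Maori higher
    )
    return {
        "bg_cost": bg_cost,
        "bg_cost_last6mo": bg_cost_last6mo,
        "bg_mortality": bg_mortality,
        "yld_per_capita": yld,
    }


def mortality_trend_multiplier(
    decline: float, start_year: int, year: int, end_year: int = 2026
) -> float:
    """Compounded mortality decline from ``start_year``; flat after 2026."""
    years = max(0, min(year, end_year) - start_year)
    return (1.0 - decline) ** years


# --------------------------------------------------------------------------
# assembled default parameter set
# --------------------------------------------------------------------------

DEFAULT_TRANSITIONS = {
    # annual residential-care entry by age band (published range 0-2%)
    "p_residential_care": (0.001, 0.003, 0.006, 0.012, 0.02),
    # annual probability of moving house by age band (published range 2-5%)
    "p_move_house": (0.05, 0.04, 0.03, 0.025, 0.02),
}


def build_default_parameter_set(
    seed: int = 0, config: dict | None = None
) -> tuple[ParameterSet, Population]:
    """The packaged synthetic parameter set, calibrated to all published
    aggregates, together with its population.

    ``config`` may override any generator default; see
    :mod:`hsamcea.reporting` for the file-based configuration surface.
    """
    cfg = config or {}
    popc = cfg.get("population", {})
    fallc = cfg.get("falls", {})
    costc = cfg.get("costs", {})
    intc = cfg.get("intervention", {})
    trc = cfg.get("transitions", {})
    jitter_sd = float(cfg.get("jitter_sd", 0.03))

    population = generate_population(
        total=int(popc.get("total", POPULATION_65PLUS)),
        share_cohabiting=float(popc.get("share_cohabiting", 0.5)),
        seed=seed,
    )
    weights = population.band_weights()
    high_risk_share = float(fallc.get("high_risk_share", 0.09))
    risk_ratio = float(fallc.get("risk_ratio_high_vs_low", 2.0))
    ref_pop = float(fallc.get("reference_population", POPULATION_65PLUS))
    fall_target = float(
        fallc.get("aggregate", float(fallc.get("count", FALL_COUNT_2011)) / ref_pop)
    )
    hosp_target = float(
        fallc.get(
            "hospitalized_aggregate",
            float(fallc.get("hospitalized_count", HOSP_FALL_COUNT_2011)) / ref_pop,
        )
    )

    p_fall = generate_stratified_rates(
        aggregate_target=fall_target,
        risk_ratio_high_vs_low=risk_ratio,
        weights=weights,
        seed=seed,
        high_risk_share=high_risk_share,
        jitter_sd=jitter_sd,
    )
    p_hosp = generate_conditional_hosp(
        joint_target=hosp_target,
        p_fall=p_fall,
        weights=weights,
        high_risk_share=high_risk_share,
        seed=seed,
        jitter_sd=jitter_sd,
    )
    p_death = generate_fall_fatality(
        peak=float(fallc.get("fatality_peak", 0.05)), seed=seed, jitter_sd=jitter_sd
    )
    background = generate_background_tables(seed=seed, jitter_sd=jitter_sd)
    cost_nonhosp = generate_case_costs(
        float(costc.get("fall_nonhosp_mean", 344.0)),
        p_fall,
        weights,
        high_risk_share,
        seed=seed,
        jitter_sd=jitter_sd,
    )
    cost_hosp = generate_case_costs(
        float(costc.get("fall_hosp_mean", 4068.0)),
        p_fall,
        weights,
        high_risk_share,
        seed=seed + 7,
        jitter_sd=jitter_sd,
    )

    # uncertainty distributions fitted from the same configuration numbers
    from .distributions import (
        beta_spec,
        fit_lognormal_from_ci,
        gamma_relsd,
    )

    uncertainty = default_uncertainty()
    if "rr_ci" in intc:
        uncertainty["rr_hsam"] = fit_lognormal_from_ci(*intc["rr_ci"])
    if "uptake_beta" in intc:
        uncertainty["uptake"] = beta_spec(*intc["uptake_beta"])
    if "dw_ci" in intc:
        uncertainty["dw_fall_annualized"] = fit_lognormal_from_ci(*intc["dw_ci"])
    if "hsam_ci" in costc:
        uncertainty["cost_hsam_per_person"] = fit_lognormal_from_ci(*costc["hsam_ci"])
    if "program_rel_sd" in costc:
        uncertainty["cost_program_per_person"] = gamma_relsd(
            float(costc.get("program_per_person", 44.0)),
            float(costc["program_rel_sd"]),
        )

    params = ParameterSet(
        p_fall=p_fall,
        p_hosp_given_fall=p_hosp,
        p_death_given_fall=p_death,
        p_residential_care=np.asarray(
            trc.get("p_residential_care", DEFAULT_TRANSITIONS["p_residential_care"]),
            dtype=float,
        ),
        p_move_house=np.asarray(
            trc.get("p_move_house", DEFAULT_TRANSITIONS["p_move_house"]), dtype=float
        ),
        bg_mortality=background["bg_mortality"],
        mortality_decline=dict(cfg.get("mortality_decline", MORTALITY_DECLINE)),
        yld_per_capita=background["yld_per_capita"],
        rr_hsam=float(intc.get("rr_hsam", 0.81)),
        uptake=float(intc.get("uptake", 0.890)),
        dw_fall_annualized=float(intc.get("dw_fall_annualized", 0.10)),
        high_risk_share=high_risk_share,
        share_cohabiting=population.share_cohabiting,
        cost_hsam_per_person=float(costc.get("hsam_per_person", 250.0)),
        cost_program_per_person=float(costc.get("program_per_person", 44.0)),
        cost_fall_nonhosp=cost_nonhosp,
        cost_fall_hosp=cost_hosp,
        bg_cost=background["bg_cost"],
        bg_cost_last6mo=background["bg_cost_last6mo"],
        start_year=int(cfg.get("start_year", 2011)),
        uncertainty=uncertainty,
    )
    params.validate()
    return params, population


# --------------------------------------------------------------------------
# CSV export
# --------------------------------------------------------------------------

def _band_table_frame(arr: np.ndarray, value: str) -> pd.DataFrame:
    rows = []
    for b, band in enumerate(AGE_BANDS):
        for s, sex in enumerate(SEXES):
            if arr.ndim == 2:
                rows.append({"age_band": band, "sex": sex, value: arr[b, s]})
                continue
            for e, eth in enumerate(ETHNICITIES):
                if arr.ndim == 3:
                    rows.append(
                        {"age_band": band, "sex": sex, "ethnicity": eth, value: arr[b, s, e]}
                    )
                else:
                    for r, risk in enumerate(("low", "high")):
                        rows.append(
                            {
                                "age_band": band,
                                "sex": sex,
                                "ethnicity": eth,
                                "risk_group": risk,
                                value: arr[b, s, e, r],
                            }
                        )
    return pd.DataFrame(rows)


def write_parameter_tables(
    params: ParameterSet, population: Population, outdir: str | Path
) -> list[Path]:
    """Write the generated tables as CSV, one calibration note per file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weights = population.band_weights()
    mix = (1 - params.high_risk_share) * params.p_fall[..., 0] + (
        params.high_risk_share
    ) * params.p_fall[..., 1]
    tables: list[tuple[str, pd.DataFrame, str]] = [
        (
            "population",
            population.counts,
            f"total={population.total:.0f}",
        ),
        (
            "p_fall",
            _band_table_frame(params.p_fall, "annual_probability"),
            f"population_weighted_mean={(weights * mix).sum():.9f}",
        ),
        (
            "p_hosp_given_fall",
            _band_table_frame(params.p_hosp_given_fall, "conditional_probability"),
            f"population_hospitalized_fall_probability="
            f"{(weights * mix * params.p_hosp_given_fall).sum():.9f}",
        ),
        (
            "p_death_given_fall",
            _band_table_frame(params.p_death_given_fall, "conditional_probability"),
            f"peak={params.p_death_given_fall.max():.9f}",
        ),
        (
            "cost_fall_nonhosp",
            _band_table_frame(params.cost_fall_nonhosp, "nzd_per_case"),
            "case_weighted_mean=344",
        ),
        (
            "cost_fall_hosp",
            _band_table_frame(params.cost_fall_hosp, "nzd_per_case"),
            "case_weighted_mean=4068",
        ),
    ]
    age_frames = {
        "bg_cost": ("nzd_per_person_year", params.bg_cost),
        "bg_cost_last6mo": ("nzd_per_death", params.bg_cost_last6mo),
    }
    for name, (value, arr) in age_frames.items():
        rows = [
            {"age": AGE_MIN + a, "sex": sex, value: arr[a, s]}
            for a in range(N_AGE)
            for s, sex in enumerate(SEXES)
        ]
        tables.append((name, pd.DataFrame(rows), "anchors held exactly"))
    mort_rows = [
        {
            "age": AGE_MIN + a,
            "sex": sex,
            "ethnicity": eth,
            "annual_probability_2011": params.bg_mortality[a, s, e],
        }
        for a in range(N_AGE)
        for s, sex in enumerate(SEXES)
        for e, eth in enumerate(ETHNICITIES)
    ]
    tables.append(("bg_mortality", pd.DataFrame(mort_rows), "2011 level, Gompertz"))
    tables.append(
        ("yld_per_capita", _band_table_frame(params.yld_per_capita, "yld"), "constant")
    )

    written = []
    for name, frame, note in tables:
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# calibration: {note}\n")
            frame.to_csv(fh, index=False)
        written.append(path)
    return written
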