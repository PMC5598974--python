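"""The HSAM intervention: targeting rules, costs, effectiveness and ICERs.

A home safety assessment and modification (HSAM) program invites eligible
community-dwelling older people (a $44 letter-and-phone invitation per
eligible person, uptake-independent), and modifies the homes of those who
accept (uptake 89%, $250 labor and materials per participant, halved on a
per-participant basis where two eligible people share a dwelling).  Modified
homes experience injurious falls at ``rr_hsam`` (0.81) times the stratum
rate.

Targeting rules cross two age cuts (65+, 75+) with fall-history filters
(everyone / only people with a treated injurious fall in the preceding five
years / only people without one).  Risk-targeted arms can be delivered
*prospectively*: a person is invited in the cycle they enter the high-risk
state, with invitation and modification costs discounted at that cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .strata import AGE_MIN, N_AGE

COST_SAVING = "cost saving"
DOMINATED = "dominated"
UNDEFINED = "undefined"

#: targeting rule -> (age cut, fall-history filter)
TARGETING_RULES: dict[str, tuple[int, str]] = {
    "all_65plus": (65, "all"),
    "risk_65plus": (65, "risk"),
    "norisk_65plus": (65, "norisk"),
    "all_75plus": (75, "all"),
    "risk_75plus": (75, "risk"),
    "norisk_75plus": (75, "norisk"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One analysis scenario: targeting, discounting, horizon, decay, costs."""

    name: str
    targeting: str = "all_65plus"
    discount_rate: float = 0.03
    horizon_years: int | None = None  # None = lifetime (to death or age 110)
    decay_years: int | None = None  # linear decay of effectiveness to nil
    hsam_cost_multiplier: float = 1.0
    prospective_delivery: bool = False

    def __post_init__(self) -> None:
        if self.targeting not in TARGETING_RULES:
            raise ValueError(f"unknown targeting rule {self.targeting!r}")
        if self.hsam_cost_multiplier <= 0:
            raise ValueError("hsam_cost_multiplier must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")
        if self.decay_years is not None and self.decay_years <= 0:
            raise ValueError("decay_years must be positive")

    @property
    def age_cut(self) -> int:
        return TARGETING_RULES[self.targeting][0]

    @property
    def risk_filter(self) -> str:
        return TARGETING_RULES[self.targeting][1]


def table2_scenarios() -> list[ScenarioSpec]:
    """The published scenario grid: base case, six targeting arms, 0%/6%
    discounting, 10-year effectiveness decay, one-third HSAM cost reduction,
    and 10/20-year horizons."""
    base = ScenarioSpec("base_case")
    return [
        base,
        ScenarioSpec("risk_65plus", targeting="risk_65plus", prospective_delivery=True),
        ScenarioSpec("norisk_65plus", targeting="norisk_65plus"),
        ScenarioSpec("all_75plus", targeting="all_75plus"),
        ScenarioSpec("risk_75plus", targeting="risk_75plus", prospective_delivery=True),
        ScenarioSpec("norisk_75plus", targeting="norisk_75plus"),
        replace(base, name="discount_0pct", discount_rate=0.0),
        replace(base, name="discount_6pct", discount_rate=0.06),
        replace(base, name="decay_10y", decay_years=10),
        replace(base, name="hsam_cost_two_thirds", hsam_cost_multiplier=2.0 / 3.0),
        replace(base, name="horizon_10y", horizon_years=10),
        replace(base, name="horizon_20y", horizon_years=20),
    ]


# --------------------------------------------------------------------------
# eligibility
# --------------------------------------------------------------------------

def eligibility_mask(rule: str) -> np.ndarray:
    """(age, risk-clock) boolean eligibility for a targeting rule.

    Clock 0 means no treated injurious fall in the preceding five years
    (low risk); clocks 1-5 count years since the last one (high risk).
    """
    if rule not in TARGETING_RULES:
        raise ValueError(f"unknown targeting rule {rule!r}")
    age_cut, risk = TARGETING_RULES[rule]
    ages_ok = (np.arange(N_AGE) + AGE_MIN) >= age_cut
    if risk == "all":
        clocks_ok = np.ones(6, dtype=bool)
    elif risk == "risk":
        clocks_ok = np.array([False] + [True] * 5)
    else:  # norisk
        clocks_ok = np.array([True] + [False] * 5)
    return ages_ok[:, None] & clocks_ok[None, :]


def select_targets(population, rule: str, high_risk_share: float) -> pd.DataFrame:
    """Eligible person-counts per stratum and risk group at program start."""
    if rule not in TARGETING_RULES:
        raise ValueError(f"unknown targeting rule {rule!r}")
    age_cut, risk = TARGETING_RULES[rule]
    rows = []
    for band, sex, eth, n in zip(
        population.counts["age_band"],
        population.counts["sex"],
        population.counts["ethnicity"],
        population.counts["count"],
    ):
        band_lo = 85 if band == "85+" else int(band.split("-")[0])
        in_age = band_lo >= age_cut
        for risk_group, share in (("low", 1 - high_risk_share), ("high", high_risk_share)):
            eligible = in_age and (
                risk == "all"
                or (risk == "risk" and risk_group == "high")
                or (risk == "norisk" and risk_group == "low")
            )
            rows.append(
                {
                    "age_band": band,
                    "sex": sex,
                    "ethnicity": eth,
                    "risk_group": risk_group,
                    "eligible": n * share if eligible else 0.0,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# effectiveness and costs
# --------------------------------------------------------------------------

def effective_rr(
    base_rr: float, years_since_modification: int, decay_years: int | None = None
) -> float:
    """Risk ratio in force ``years_since_modification`` years after HSAM.

    Without decay the full effect persists; with decay over ``d`` years the
    rate reduction (1 - rr) shrinks linearly to nil:
    rr(t) = 1 - (1 - base_rr) * max(0, 1 - t/d).

    ``base_rr`` above 1 is accepted (a harmful draw from the upper tail of
    the effectiveness distribution, whose excess decays the same way).
    """
    if not base_rr > 0.0 or not np.isfinite(base_rr):
        raise ValueError("base_rr must be a positive finite risk ratio")
    if years_since_modification < 0:
        raise ValueError("years_since_modification must be >= 0")
    if decay_years is None:
        return base_rr
    frac = max(0.0, 1.0 - years_since_modification / decay_years)
    return 1.0 - (1.0 - base_rr) * frac


def intervention_cost(
    eligible: float,
    uptake: float,
    share_cohabiting: float,
    cost_program_pp: float,
    cost_hsam_pp: float,
    multiplier: float = 1.0,
) -> tuple[float, float]:
    """(program cost, HSAM cost) for a batch of eligible persons.

    The invitation (program) cost applies to every eligible person
    regardless of uptake; the HSAM materials/labor cost only to takers, with
    the expected-cost cohabitation factor (1 - share/2) reflecting the
    per-participant halving for eligible pairs sharing a dwelling.
    """
    if not (0 <= uptake <= 1 and 0 <= share_cohabiting <= 1):
        raise ValueError("uptake and share_cohabiting must lie in [0, 1]")
    if min(eligible, cost_program_pp, cost_hsam_pp) < 0 or multiplier <= 0:
        raise ValueError("counts and costs must be non-negative, multiplier positive")
    program = cost_program_pp * eligible
    hsam = cost_hsam_pp * multiplier * uptake * eligible * (1.0 - share_cohabiting / 2.0)
    return program, hsam


def compute_icer(
    delta_cost: float, delta_qalys: float, tol: float = 1e-9
) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance label.

    Positive health gain with positive cost gives the ratio; gain with net
    savings is "cost saving" (dominant); health loss with positive cost is
    "dominated"; a ~zero/zero comparison is flagged "undefined" rather than
    returning a number.
    """
    if abs(delta_cost) < tol and abs(delta_qalys) < tol:
        return UNDEFINED
    if delta_qalys > tol:
        return COST_SAVING if delta_cost < 0 else delta_cost / delta_qalys
    if delta_cost > 0:
        return DOMINATED
    # health loss with cost savings: report the ratio (cost saved per QALY lost)
    return delta_cost / delta_qalys if abs(delta_qalys) > tol else UNDEFINED


def icer_rank_value(delta_cost: float, delta_qalys: float, tol: float = 1e-9) -> float:
    """Numeric key ordering strategies from most to least cost-effective.

    Among QALY-gaining strategies the signed cost-per-QALY ratio is the
    standard figure of merit — it extends the ICER continuously through
    zero, so a cost-saving strategy ranks by how much it saves per QALY
    (more negative = better).  Strategies that gain no health rank worst
    (+inf).  Use this for comparisons; use :func:`compute_icer` for
    reporting, which renders dominance as a label the way published
    cost-effectiveness tables do.
    """
    if delta_qalys > tol:
        return delta_cost / delta_qalys
    return np.inf
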