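"""Annual-cycle cohort Markov engine for the falls-prevention model.

A closed cohort of community-dwelling people aged 65+ in 2011 is propagated
deterministically (state-occupancy fractions, not individuals) through
annual cycles until death or age 110.  The state space per single-year age,
sex and ethnicity is:

* community, in an unmodified or modified home (modified states additionally
  track years since modification when the effectiveness-decay scenario is
  active);
* residential aged care (no home flag; the HSAM benefit ceases on entry,
  but stratum fall risk continues);
* dead (absorbing).

Each living state carries a risk clock: 0 means no treated injurious fall
in the preceding five years (low risk), 1-5 count years since the last one
(high risk).  A new treated fall resets the clock to 1; after five fall-free
years it expires back to 0.

Within a cycle events apply in a fixed order: injurious falls (hospital /
non-hospital split, fall case fatality), background mortality on fall
survivors, residential-care entry, house moves (modified -> unmodified),
then ageing and clock update.  Deaths accrue half a cycle of utility;
surviving states are valued at end of cycle.  Costs and QALYs of cycle k
(the year ``start_year + k``) are discounted by (1 + r)^-k, so the cycle-0
intervention outlay is undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervention import ScenarioSpec, effective_rr, eligibility_mask, intervention_cost
from .params import MORTALITY_TREND_END_YEAR, ParameterSet
from .strata import BAND_OF_AGE, N_AGE

N_CLOCK = 6  # 0 = low risk; 1..5 = years since last treated injurious fall

COST_COMPONENTS = ("intervention", "fall_nonhosp", "fall_hosp", "background", "last6mo")


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor (1 + rate)^-cycle; cycle 0 is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return (1.0 + rate) ** (-cycle)


def annualized_fall_dw(episode_dw: float, duration_months: float) -> float:
    """Per-cycle QALY decrement of an injury episode within a one-year cycle.

    A fracture-type disability weight applied for a fraction of the year:
    e.g. 0.30 held for four months contributes 0.10 QALYs lost.
    """
    if not 0.0 <= episode_dw <= 1.0:
        raise ValueError("episode_dw must lie in [0, 1]")
    if not 0.0 < duration_months <= 12.0:
        raise ValueError("duration_months must lie in (0, 12]")
    return episode_dw * duration_months / 12.0


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------

@dataclass
class CohortState:
    """Person-counts by (age, sex, ethnicity, home status, risk clock).

    ``comm`` has a home axis of length M: index 0 is an unmodified home;
    index j >= 1 is a modified home with j-1 years since modification (the
    last index absorbs).  ``rc`` is residential care (no home axis).
    """

    comm: np.ndarray  # (N_AGE, 2, 2, M, N_CLOCK)
    rc: np.ndarray  # (N_AGE, 2, 2, N_CLOCK)
    dead: np.ndarray  # (2, 2)
    cycle: int
    initial_total: float

    @property
    def n_mod_states(self) -> int:
        return self.comm.shape[3]

    def total_alive(self) -> float:
        return float(self.comm.sum() + self.rc.sum())

    def check(self, tol: float = 1e-9) -> None:
        if np.any(self.comm < -1e-12) or np.any(self.rc < -1e-12):
            raise ValueError("negative state occupancy")
        total = self.total_alive() + float(self.dead.sum())
        if abs(total - self.initial_total) > tol * max(1.0, self.initial_total):
            raise ValueError(
                f"cohort mass not conserved: {total} vs {self.initial_total}"
            )


def initial_state(
    pop_by_age: np.ndarray, high_risk_share: float, n_mod_states: int = 2
) -> CohortState:
    """Everyone community-dwelling and unmodified; the high-risk stock is
    spread evenly over risk clocks 1-5."""
    comm = np.zeros((N_AGE, 2, 2, n_mod_states, N_CLOCK))
    comm[:, :, :, 0, 0] = pop_by_age * (1.0 - high_risk_share)
    for k in range(1, N_CLOCK):
        comm[:, :, :, 0, k] = pop_by_age * high_risk_share / 5.0
    return CohortState(
        comm=comm,
        rc=np.zeros((N_AGE, 2, 2, N_CLOCK)),
        dead=np.zeros((2, 2)),
        cycle=0,
        initial_total=float(pop_by_age.sum()),
    )


@dataclass
class CycleAccruals:
    """Event counts and person-years accrued during one cycle (undiscounted)."""

    surv_comm: np.ndarray  # (N_AGE, 2, 2) surviving community person-years
    surv_rc: np.ndarray  # (N_AGE, 2, 2) surviving residential-care person-years
    deaths: np.ndarray  # (N_AGE, 2, 2) fall + background deaths
    falls_hosp: np.ndarray  # (N_AGE, 2, 2) hospitalized injurious falls
    falls_nonhosp: np.ndarray  # (N_AGE, 2, 2)
    falls_surviving: np.ndarray  # (N_AGE, 2, 2) fallers alive at cycle end
    new_high_risk_unmod: np.ndarray  # (N_AGE, 2, 2) low->high entrants, unmodified

    @property
    def surv_py(self) -> np.ndarray:
        return self.surv_comm + self.surv_rc


# --------------------------------------------------------------------------
# one cycle
# --------------------------------------------------------------------------

def _expand_band(arr: np.ndarray) -> np.ndarray:
    """Band-indexed table -> single-year-age-indexed table."""
    return arr[BAND_OF_AGE]


def _mortality_this_cycle(params: ParameterSet, cycle: int) -> np.ndarray:
    """Background mortality (age, sex, eth) for the given cycle, applying the
    published ethnic annual declines through 2026 and 0% thereafter; age 110
    is absorbing (probability 1)."""
    year = params.start_year + cycle
    years_of_decline = max(0, min(year, MORTALITY_TREND_END_YEAR) - params.start_year)
    factors = np.array(
        [
            (1.0 - params.mortality_decline["maori"]) ** years_of_decline,
            (1.0 - params.mortality_decline["non_maori"]) ** years_of_decline,
        ]
    )
    m = np.clip(params.bg_mortality * factors[None, None, :], 0.0, 1.0)
    m[-1] = 1.0  # the model follows people to death or age 110
    return m


def advance_cycle(
    state: CohortState, params: ParameterSet, scenario: ScenarioSpec
) -> tuple[CohortState, CycleAccruals]:
    """Apply one annual cycle and return the new state plus its accruals."""
    M = state.n_mod_states
    comm, rc = state.comm, state.rc

    # --- lookups for this cycle
    pf = _expand_band(params.p_fall)  # (age, sex, eth, risk)
    q = np.empty((N_AGE, 2, 2, N_CLOCK))
    q[..., 0] = pf[..., 0]
    q[..., 1:] = pf[..., 1][..., None]
    rr_by_mod = np.array(
        [1.0]
        + [
            effective_rr(params.rr_hsam, j, scenario.decay_years)
            for j in range(M - 1)
        ]
    )
    q_comm = np.clip(q[:, :, :, None, :] * rr_by_mod[None, None, None, :, None], 0, 1)
    h = _expand_band(params.p_hosp_given_fall)  # (age, sex, eth)
    f = _expand_band(params.p_death_given_fall)
    r = _expand_band(params.p_residential_care)  # (age,)
    v = _expand_band(params.p_move_house)
    m = _mortality_this_cycle(params, state.cycle)

    # --- community: falls, fall deaths, background mortality
    falls_c = comm * q_comm
    fdeaths_c = falls_c * f[..., None, None]
    bgdeaths_c = (comm - fdeaths_c) * m[..., None, None]
    surv_fall_c = (falls_c - fdeaths_c) * (1.0 - m[..., None, None])
    surv_non_c = (comm - falls_c) * (1.0 - m[..., None, None])

    # --- residential care: same event structure, no HSAM benefit, no entry/move
    falls_r = rc * q
    fdeaths_r = falls_r * f[..., None]
    bgdeaths_r = (rc - fdeaths_r) * m[..., None]
    surv_fall_r = (falls_r - fdeaths_r) * (1.0 - m[..., None])
    surv_non_r = (rc - falls_r) * (1.0 - m[..., None])

    # --- residential-care entry from the community
    rcol = r[:, None, None, None, None]
    to_rc_fall = surv_fall_c * rcol
    to_rc_non = surv_non_c * rcol
    surv_fall_c = surv_fall_c - to_rc_fall
    surv_non_c = surv_non_c - to_rc_non

    # low->high entrants still unmodified, counted before movers join mod 0
    entrants_unmod = surv_fall_c[:, :, :, 0, 0].copy()

    # --- house moves: modified homes vacated into unmodified ones
    if M > 1:
        vcol = v[:, None, None, None, None]
        movers_fall = surv_fall_c[:, :, :, 1:, :] * vcol
        movers_non = surv_non_c[:, :, :, 1:, :] * vcol
        surv_fall_c[:, :, :, 1:, :] -= movers_fall
        surv_non_c[:, :, :, 1:, :] -= movers_non
        surv_fall_c[:, :, :, 0, :] += movers_fall.sum(axis=3)
        surv_non_c[:, :, :, 0, :] += movers_non.sum(axis=3)

    # --- accruals (indexed by age during the cycle)
    falls_total = falls_c.sum(axis=(3, 4)) + falls_r.sum(axis=3)
    accruals = CycleAccruals(
        surv_comm=surv_fall_c.sum(axis=(3, 4)) + surv_non_c.sum(axis=(3, 4)),
        surv_rc=(surv_fall_r + surv_non_r + to_rc_fall.sum(axis=3) + to_rc_non.sum(axis=3)).sum(
            axis=3
        ),
        deaths=(fdeaths_c + bgdeaths_c).sum(axis=(3, 4)) + (fdeaths_r + bgdeaths_r).sum(axis=3),
        falls_hosp=falls_total * h,
        falls_nonhosp=falls_total * (1.0 - h),
        falls_surviving=surv_fall_c.sum(axis=(3, 4))
        + surv_fall_r.sum(axis=3)
        + to_rc_fall.sum(axis=(3, 4)),
        new_high_risk_unmod=entrants_unmod,
    )

    # --- clock update and ageing
    mod_next = np.array([0] + [min(j + 1, M - 1) for j in range(1, M)])
    new_comm = np.zeros_like(comm)
    for j in range(M):
        jn = mod_next[j]
        new_comm[:, :, :, jn, 1] += surv_fall_c[:, :, :, j, :].sum(axis=-1)
        new_comm[:, :, :, jn, 0] += surv_non_c[:, :, :, j, 0] + surv_non_c[:, :, :, j, 5]
        new_comm[:, :, :, jn, 2:6] += surv_non_c[:, :, :, j, 1:5]
    new_rc = np.zeros_like(rc)
    rc_fall = surv_fall_r + to_rc_fall.sum(axis=3)
    rc_non = surv_non_r + to_rc_non.sum(axis=3)
    new_rc[:, :, :, 1] += rc_fall.sum(axis=-1)
    new_rc[:, :, :, 0] += rc_non[:, :, :, 0] + rc_non[:, :, :, 5]
    new_rc[:, :, :, 2:6] += rc_non[:, :, :, 1:5]

    aged_comm = np.zeros_like(new_comm)
    aged_comm[1:] = new_comm[:-1]
    aged_rc = np.zeros_like(new_rc)
    aged_rc[1:] = new_rc[:-1]

    out = CohortState(
        comm=aged_comm,
        rc=aged_rc,
        dead=state.dead + accruals.deaths.sum(axis=0),
        cycle=state.cycle + 1,
        initial_total=state.initial_total,
    )
    out.check()
    return out, accruals


# --------------------------------------------------------------------------
# accrual valuation
# --------------------------------------------------------------------------

def accrue_cycle_qalys(accruals: CycleAccruals, params: ParameterSet) -> float:
    """Undiscounted QALYs accrued in one cycle.

    Survivors contribute 1 - YLD per person-year; each surviving injurious
    fall subtracts the annualized disability weight; people dying during the
    cycle contribute half a cycle at their background utility.
    """
    util = 1.0 - _expand_band(params.yld_per_capita)
    q = float((accruals.surv_py * util).sum())
    q += 0.5 * float((accruals.deaths * util).sum())
    q -= params.dw_fall_annualized * float(accruals.falls_surviving.sum())
    return q


def accrue_cycle_costs(accruals: CycleAccruals, params: ParameterSet) -> dict[str, float]:
    """Undiscounted health-system cost components for one cycle (NZ$)."""
    cn = _expand_band(params.cost_fall_nonhosp)  # (age, sex)
    ch = _expand_band(params.cost_fall_hosp)
    surv_agesex = accruals.surv_py.sum(axis=2)
    deaths_agesex = accruals.deaths.sum(axis=2)
    return {
        "fall_nonhosp": float((accruals.falls_nonhosp.sum(axis=2) * cn).sum()),
        "fall_hosp": float((accruals.falls_hosp.sum(axis=2) * ch).sum()),
        "background": float((surv_agesex * params.bg_cost).sum()),
        "last6mo": float((deaths_agesex * params.bg_cost_last6mo).sum()),
    }


# --------------------------------------------------------------------------
# full runs
# --------------------------------------------------------------------------

@dataclass
class RunResult:
    """Discounted totals (and per-cycle trace) of one deterministic run."""

    scenario: str
    arm: str
    qalys: float
    qalys_undiscounted: float
    costs: dict[str, float]
    n_invited_initial: float
    n_invited_prospective: float
    population: float
    trace: list[dict] = field(default_factory=list, repr=False)

    @property
    def total_cost(self) -> float:
        return float(sum(self.costs.values()))

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def _apply_initial_intervention(
    state: CohortState, params: ParameterSet, scenario: ScenarioSpec
) -> tuple[float, float]:
    """Invite the cycle-0 eligible set; movers of the uptake share into the
    just-modified state.  Returns (persons invited, cost)."""
    mask = eligibility_mask(scenario.targeting)  # (age, clock)
    invited = state.comm[:, :, :, 0, :] * mask[:, None, None, :]
    n_invited = float(invited.sum())
    takers = params.uptake * invited
    state.comm[:, :, :, 0, :] -= takers
    state.comm[:, :, :, 1, :] += takers
    program, hsam = intervention_cost(
        n_invited,
        params.uptake,
        params.share_cohabiting,
        params.cost_program_per_person,
        params.cost_hsam_per_person,
        scenario.hsam_cost_multiplier,
    )
    return n_invited, program + hsam


def _apply_prospective_invitation(
    state: CohortState,
    entrants_prev_age: np.ndarray,
    params: ParameterSet,
    scenario: ScenarioSpec,
) -> tuple[float, float]:
    """Invite new high-risk entrants at the cycle they enter the state."""
    age_cut_idx = scenario.age_cut - 65
    ent = np.zeros((N_AGE, 2, 2))
    ent[1:] = entrants_prev_age[:-1]  # entrants have aged one year
    ent[:age_cut_idx] = 0.0
    n_invited = float(ent.sum())
    if n_invited <= 0:
        return 0.0, 0.0
    takers = params.uptake * ent
    state.comm[:, :, :, 0, 1] -= takers
    state.comm[:, :, :, 1, 1] += takers
    program, hsam = intervention_cost(
        n_invited,
        params.uptake,
        params.share_cohabiting,
        params.cost_program_per_person,
        params.cost_hsam_per_person,
        scenario.hsam_cost_multiplier,
    )
    return n_invited, program + hsam


def run_cohort(
    params: ParameterSet,
    scenario: ScenarioSpec,
    population,
    arm: str = "intervention",
    collect_trace: bool = False,
) -> RunResult:
    """Run the cohort from 2011 to extinction, age 110 or the scenario horizon.

    ``arm`` is "intervention" (HSAM delivered per the scenario) or
    "baseline" (no program).  ``population`` is a
    :class:`~hsamcea.synthetic.Population` or a raw (46, 2, 2) count array.
    """
    if arm not in ("baseline", "intervention"):
        raise ValueError(f"unknown arm {arm!r}")
    pop_by_age = population if isinstance(population, np.ndarray) else population.by_age
    n_mod = 2 if scenario.decay_years is None else scenario.decay_years + 2
    state = initial_state(pop_by_age, params.high_risk_share, n_mod)
    state.check()

    rate = scenario.discount_rate
    costs = {c: 0.0 for c in COST_COMPONENTS}
    qalys = 0.0
    qalys_undisc = 0.0
    n_init = n_prosp = 0.0
    trace: list[dict] = []

    if arm == "intervention":
        n_init, cost0 = _apply_initial_intervention(state, params, scenario)
        costs["intervention"] += cost0  # cycle 0, undiscounted
    prospective = (
        arm == "intervention"
        and scenario.prospective_delivery
        and scenario.risk_filter == "risk"
    )

    n_cycles = N_AGE if scenario.horizon_years is None else min(scenario.horizon_years, N_AGE)
    for t in range(n_cycles):
        state, acc = advance_cycle(state, params, scenario)
        df = discount_factor(rate, t)
        q = accrue_cycle_qalys(acc, params)
        c = accrue_cycle_costs(acc, params)
        qalys += df * q
        qalys_undisc += q
        for k, val in c.items():
            costs[k] += df * val
        if prospective and t + 1 < n_cycles:
            n_new, cost_new = _apply_prospective_invitation(
                state, acc.new_high_risk_unmod, params, scenario
            )
            n_prosp += n_new
            costs["intervention"] += discount_factor(rate, t + 1) * cost_new
        if collect_trace:
            trace.append(
                {
                    "cycle": t,
                    "year": params.start_year + t,
                    "alive_community": float(acc.surv_comm.sum()),
                    "alive_residential_care": float(acc.surv_rc.sum()),
                    "dead_cumulative": float(state.dead.sum()),
                    "falls_hosp": float(acc.falls_hosp.sum()),
                    "falls_nonhosp": float(acc.falls_nonhosp.sum()),
                    "deaths": float(acc.deaths.sum()),
                    "qalys": q,
                    **{f"cost_{k}": val for k, val in c.items()},
                }
            )
        if state.total_alive() < 1e-12:
            break

    return RunResult(
        scenario=scenario.name,
        arm=arm,
        qalys=qalys,
        qalys_undiscounted=qalys_undisc,
        costs=costs,
        n_invited_initial=n_init,
        n_invited_prospective=n_prosp,
        population=float(pop_by_age.sum()),
        trace=trace,
    )


def run_pair(
    params: ParameterSet,
    scenario: ScenarioSpec,
    population,
    collect_trace: bool = False,
) -> tuple[RunResult, RunResult]:
    """(baseline, intervention) runs sharing one parameter draw."""
    base = run_cohort(params, scenario, population, "baseline", collect_trace)
    interv = run_cohort(params, scenario, population, "intervention", collect_trace)
    return base, interv
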