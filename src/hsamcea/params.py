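"""The model parameter container and PSA sampling machinery.

:class:`ParameterSet` holds every input the cohort engine consumes: annual
injurious-fall probabilities by stratum and risk group, conditional
hospitalization and case-fatality probabilities, residential-care entry and
house-move probabilities, background mortality (2011 level plus ethnic trend),
per-capita background morbidity (YLD), the intervention effect (risk ratio),
uptake, disability-weight decrement per injurious fall, and all unit costs in
2011 NZ$.

For probabilistic sensitivity analysis each uncertain input is tied to a
:class:`~hsamcea.distributions.DistributionSpec`.  Parameters whose printed
uncertainty is "0.5 to 1.5 of the point estimate" are sampled as a single
multiplicative scalar applied to the whole stratified table (one scalar per
table, matching the one-bar-per-parameter tornado convention); the risk
ratio, uptake, disability weight and the two intervention unit costs are
sampled on their natural scales.  Sampled probabilities are truncated into
[0, 1].
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np

from .distributions import (
    DistributionSpec,
    beta_spec,
    fit_lognormal_from_ci,
    fit_lognormal_scalar,
    gamma_relsd,
)
from .strata import N_AGE, N_BAND

MORTALITY_TREND_END_YEAR = 2026  # annual declines apply through this year


@dataclass
class ParameterSet:
    """Every input of the district falls-prevention model.

    Array axes are (age band 5, sex 2, ethnicity 2) unless noted; background
    mortality and the two background-cost tables are indexed by single-year
    age (65..110 -> axis length 46).
    """

    # epidemiology -------------------------------------------------------
    p_fall: np.ndarray  # (band, sex, eth, risk) annual injurious-fall probability
    p_hosp_given_fall: np.ndarray  # (band, sex, eth) conditional on a fall
    p_death_given_fall: np.ndarray  # (band, sex, eth) fall case fatality
    p_residential_care: np.ndarray  # (band,) annual entry probability
    p_move_house: np.ndarray  # (band,) annual probability of moving house
    bg_mortality: np.ndarray  # (age, sex, eth) annual probability in 2011
    mortality_decline: dict[str, float]  # per-annum decline by ethnicity, to 2026
    yld_per_capita: np.ndarray  # (band, sex, eth) morbidity decrement /person-year

    # intervention -------------------------------------------------------
    rr_hsam: float  # risk ratio on the injurious-fall rate in modified homes
    uptake: float  # proportion of invited persons accepting HSAM
    dw_fall_annualized: float  # QALY decrement per injurious fall (one cycle)
    high_risk_share: float  # initial prevalence of a treated fall in prior 5y
    share_cohabiting: float  # eligible persons sharing a dwelling with another

    # costs (NZ$, 2011) --------------------------------------------------
    cost_hsam_per_person: float
    cost_program_per_person: float
    cost_fall_nonhosp: np.ndarray  # (band, sex) per case
    cost_fall_hosp: np.ndarray  # (band, sex) per case
    bg_cost: np.ndarray  # (age, sex) per surviving person-year
    bg_cost_last6mo: np.ndarray  # (age, sex) per death

    start_year: int = 2011
    uncertainty: dict[str, DistributionSpec] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def copy(self) -> "ParameterSet":
        new = copy.copy(self)
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                setattr(new, f.name, v.copy())
            elif isinstance(v, dict):
                setattr(new, f.name, dict(v))
        return new

    def validate(self) -> None:
        """Raise ValueError naming the offending field on any invariant breach."""
        shapes = {
            "p_fall": (N_BAND, 2, 2, 2),
            "p_hosp_given_fall": (N_BAND, 2, 2),
            "p_death_given_fall": (N_BAND, 2, 2),
            "p_residential_care": (N_BAND,),
            "p_move_house": (N_BAND,),
            "bg_mortality": (N_AGE, 2, 2),
            "yld_per_capita": (N_BAND, 2, 2),
            "cost_fall_nonhosp": (N_BAND, 2),
            "cost_fall_hosp": (N_BAND, 2),
            "bg_cost": (N_AGE, 2),
            "bg_cost_last6mo": (N_AGE, 2),
        }
        for name, shape in shapes.items():
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
        for name in (
            "p_fall",
            "p_hosp_given_fall",
            "p_death_given_fall",
            "p_residential_care",
            "p_move_house",
            "bg_mortality",
            "yld_per_capita",
        ):
            arr = np.asarray(getattr(self, name))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name}: probabilities/rates must lie in [0, 1]")
        if np.any(self.p_fall[..., 1] < self.p_fall[..., 0] - 1e-12):
            raise ValueError("p_fall: high-risk probability below low-risk")
        for name in ("cost_fall_nonhosp", "cost_fall_hosp", "bg_cost", "bg_cost_last6mo"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name}: costs must be non-negative")
        for name in ("cost_hsam_per_person", "cost_program_per_person"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: costs must be non-negative")
        if not self.rr_hsam > 0:
            raise ValueError("rr_hsam: must be positive")
        for name in ("uptake", "dw_fall_annualized", "high_risk_share", "share_cohabiting"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must lie in [0, 1]")
        for eth in ("maori", "non_maori"):
            if eth not in self.mortality_decline:
                raise ValueError(f"mortality_decline: missing entry for {eth!r}")


# which ParameterSet field(s) each uncertain parameter perturbs, and how:
# "mult" scales the named table(s) by one sampled scalar; "value" replaces it.
# Background annual and last-6-months-of-life costs are one health-system-cost
# parameter and share a single scalar.
UNCERTAINTY_TARGETS: dict[str, tuple[str, tuple[str, ...]]] = {
    "p_fall_scalar": ("mult", ("p_fall",)),
    "p_hosp_scalar": ("mult", ("p_hosp_given_fall",)),
    "p_death_given_fall_scalar": ("mult", ("p_death_given_fall",)),
    "p_residential_care_scalar": ("mult", ("p_residential_care",)),
    "p_move_house_scalar": ("mult", ("p_move_house",)),
    "cost_fall_nonhosp_scalar": ("mult", ("cost_fall_nonhosp",)),
    "cost_fall_hosp_scalar": ("mult", ("cost_fall_hosp",)),
    "bg_cost_scalar": ("mult", ("bg_cost", "bg_cost_last6mo")),
    "rr_hsam": ("value", ("rr_hsam",)),
    "uptake": ("value", ("uptake",)),
    "dw_fall_annualized": ("value", ("dw_fall_annualized",)),
    "cost_hsam_per_person": ("value", ("cost_hsam_per_person",)),
    "cost_program_per_person": ("value", ("cost_program_per_person",)),
}

_PROBABILITY_FIELDS = {
    "p_fall",
    "p_hosp_given_fall",
    "p_death_given_fall",
    "p_residential_care",
    "p_move_house",
    "rr_hsam",  # a ratio, not truncated
}

_TRUNCATE_01 = {
    "p_fall",
    "p_hosp_given_fall",
    "p_death_given_fall",
    "p_residential_care",
    "p_move_house",
    "uptake",
    "dw_fall_annualized",
}


def default_uncertainty() -> dict[str, DistributionSpec]:
    """Distribution specs for every uncertain input, on their stated scales.

    Table-scaling parameters use a log-normal whose 95% interval is 0.5x to
    1.5x; the risk ratio (0.68-0.97), HSAM unit cost ($165-$355) and the
    fall disability weight (0.06-0.15) use log-normals fitted to their
    printed 95% intervals; uptake is Beta(10.03, 1.24); the $44 program cost
    is gamma with SD 10% of the mean.  Background mortality and YLD carry no
    uncertainty.
    """
    scalar = fit_lognormal_scalar(1.0, 0.5, 1.5)
    return {
        "p_fall_scalar": scalar,
        "p_hosp_scalar": scalar,
        "p_death_given_fall_scalar": scalar,
        "p_residential_care_scalar": scalar,
        "p_move_house_scalar": scalar,
        "cost_fall_nonhosp_scalar": scalar,
        "cost_fall_hosp_scalar": scalar,
        "bg_cost_scalar": scalar,
        "rr_hsam": fit_lognormal_from_ci(0.68, 0.97),
        "uptake": beta_spec(10.03, 1.24),
        "dw_fall_annualized": fit_lognormal_from_ci(0.06, 0.15),
        "cost_hsam_per_person": fit_lognormal_from_ci(165.0, 355.0),
        "cost_program_per_person": gamma_relsd(44.0, 0.10),
    }


def sample_parameter_set(
    base: ParameterSet,
    specs: dict[str, DistributionSpec] | None = None,
    seed: int | np.random.Generator = 0,
) -> ParameterSet:
    """Draw one ParameterSet from the joint (independent) uncertainty.

    Parameters without a spec pass through unchanged; a given seed yields a
    bit-identical draw.  Probabilities are truncated into [0, 1] after any
    scaling.
    """
    if specs is None:
        specs = base.uncertainty
    unknown = set(specs) - set(UNCERTAINTY_TARGETS)
    if unknown:
        raise KeyError(f"unknown uncertain parameter(s): {sorted(unknown)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = base.copy()
    for name in sorted(specs):  # fixed order => reproducible draws
        draw = float(specs[name].rvs(rng))
        apply_draw(out, name, draw)
    return out


def apply_draw(pset: ParameterSet, name: str, draw: float) -> None:
    """Apply one sampled value for the named uncertain parameter in place."""
    mode, attrs = UNCERTAINTY_TARGETS[name]
    for attr in attrs:
        if mode == "mult":
            setattr(pset, attr, getattr(pset, attr) * draw)
        else:
            setattr(pset, attr, draw)
        if attr in _TRUNCATE_01:
            v = getattr(pset, attr)
            if isinstance(v, np.ndarray):
                np.clip(v, 0.0, 1.0, out=v)
            else:
                setattr(pset, attr, min(max(v, 0.0), 1.0))
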