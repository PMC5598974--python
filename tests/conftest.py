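"""Shared fixtures: the packaged default build and a small flat-rate toy
parameter set for engine-level unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from hsamcea import ScenarioSpec, build_default_parameter_set
from hsamcea.params import ParameterSet
from hsamcea.strata import N_AGE, N_BAND


@pytest.fixture(scope="session")
def default_build():
    """(params, population) generated once per session at seed 0."""
    return build_default_parameter_set(seed=0)


@pytest.fixture(scope="session")
def default_params(default_build):
    return default_build[0]


@pytest.fixture(scope="session")
def default_population(default_build):
    return default_build[1]


@pytest.fixture
def base_scenario():
    return ScenarioSpec("base_case")


def make_toy_params(
    p_fall_low: float = 0.10,
    risk_ratio: float = 2.0,
    p_hosp: float = 0.20,
    p_death_given_fall: float = 0.02,
    p_rc: float = 0.01,
    p_move: float = 0.03,
    bg_mortality: float = 0.05,
    yld: float = 0.10,
    rr_hsam: float = 0.81,
    uptake: float = 0.89,
    dw: float = 0.10,
    high_risk_share: float = 0.10,
    share_cohabiting: float = 0.0,
    cost_hsam: float = 250.0,
    cost_program: float = 44.0,
    cost_nonhosp: float = 344.0,
    cost_hosp: float = 4068.0,
    bg_cost: float = 1000.0,
    bg_cost_last6mo: float = 5000.0,
) -> ParameterSet:
    """A ParameterSet with flat (stratum-independent) rates, handy for
    hand-computable engine checks and the micro-simulation oracle."""
    params = ParameterSet(
        p_fall=np.stack(
            [
                np.full((N_BAND, 2, 2), p_fall_low),
                np.full((N_BAND, 2, 2), p_fall_low * risk_ratio),
            ],
            axis=-1,
        ),
        p_hosp_given_fall=np.full((N_BAND, 2, 2), p_hosp),
        p_death_given_fall=np.full((N_BAND, 2, 2), p_death_given_fall),
        p_residential_care=np.full(N_BAND, p_rc),
        p_move_house=np.full(N_BAND, p_move),
        bg_mortality=np.full((N_AGE, 2, 2), bg_mortality),
        mortality_decline={"maori": 0.0, "non_maori": 0.0},
        yld_per_capita=np.full((N_BAND, 2, 2), yld),
        rr_hsam=rr_hsam,
        uptake=uptake,
        dw_fall_annualized=dw,
        high_risk_share=high_risk_share,
        share_cohabiting=share_cohabiting,
        cost_hsam_per_person=cost_hsam,
        cost_program_per_person=cost_program,
        cost_fall_nonhosp=np.full((N_BAND, 2), cost_nonhosp),
        cost_fall_hosp=np.full((N_BAND, 2), cost_hosp),
        bg_cost=np.full((N_AGE, 2), bg_cost),
        bg_cost_last6mo=np.full((N_AGE, 2), bg_cost_last6mo),
    )
    params.validate()
    return params


def toy_population(n: float = 1000.0, age: int = 70) -> np.ndarray:
    """(46, 2, 2) population with everyone at one age, split 50/50 by sex,
    all non-Maori (two strata)."""
    pop = np.zeros((N_AGE, 2, 2))
    pop[age - 65, 0, 1] = n / 2.0
    pop[age - 65, 1, 1] = n / 2.0
    return pop
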