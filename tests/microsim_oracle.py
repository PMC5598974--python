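"""Independent individual-level micro-simulation oracle.

Re-implements the model's annual event cycle (falls -> fall deaths ->
background mortality on survivors -> residential-care entry -> house moves ->
risk-clock update) by Bernoulli simulation of individuals, sharing nothing
with the cohort engine but the parameter values.  Used to check that the
deterministic cohort occupancy equals the micro-simulated occupancy within
Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np


def run_microsim(
    params,
    n_people: int,
    age: int,
    n_cycles: int,
    record_cycles: tuple[int, ...],
    seed: int = 0,
    intervention: bool = True,
) -> dict[int, dict[str, float]]:
    """Simulate ``n_people`` individuals of one age (split 50/50 by sex, all
    in the second ethnicity group) and return occupancy fractions
    {cycle: {"community", "residential_care", "dead", "modified"}}.

    Rates are read from ``params`` assuming stratum-flat tables (the toy
    parameter sets used in tests), so band lookups reduce to scalars.
    """
    rng = np.random.default_rng(seed)
    band = min((age - 65) // 5, 4)
    p_low = float(params.p_fall[band, 0, 1, 0])
    p_high = float(params.p_fall[band, 0, 1, 1])
    f = float(params.p_death_given_fall[band, 0, 1])
    r = float(params.p_residential_care[band])
    v = float(params.p_move_house[band])
    m = float(params.bg_mortality[age - 65, 0, 1])
    rr = float(params.rr_hsam)
    h = float(params.high_risk_share)
    u = float(params.uptake)

    alive = np.ones(n_people, dtype=bool)
    in_rc = np.zeros(n_people, dtype=bool)
    high = rng.random(n_people) < h
    clock = np.where(high, rng.integers(1, 6, size=n_people), 0)
    modified = np.zeros(n_people, dtype=bool)
    if intervention:
        modified = rng.random(n_people) < u  # everyone eligible and unmodified

    out: dict[int, dict[str, float]] = {}
    for t in range(1, n_cycles + 1):
        q = np.where(clock > 0, p_high, p_low)
        q = np.where(alive & ~in_rc & modified, q * rr, q)
        fall = alive & (rng.random(n_people) < q)
        fall_death = fall & (rng.random(n_people) < f)
        bg_death = alive & ~fall_death & (rng.random(n_people) < m)
        died = fall_death | bg_death
        alive &= ~died

        enter_rc = alive & ~in_rc & (rng.random(n_people) < r)
        in_rc |= enter_rc
        modified &= ~enter_rc

        move = alive & ~in_rc & modified & (rng.random(n_people) < v)
        modified &= ~move

        survivor_fell = alive & fall
        clock = np.where(survivor_fell, 1, np.where(clock >= 5, 0, clock + (clock > 0)))
        clock = np.where(alive, clock, 0)

        if t in record_cycles:
            out[t] = {
                "community": float((alive & ~in_rc).mean()),
                "residential_care": float((alive & in_rc).mean()),
                "dead": float((~alive).mean()),
                "modified": float((alive & ~in_rc & modified).mean()),
            }
    return out
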