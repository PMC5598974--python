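"""Equity counterfactuals and subgroup analyses.

Standard cost-utility analysis 'penalises' health gain for groups with
higher background mortality and morbidity (their envelope of attainable
life-years is smaller).  The equity counterfactual removes that penalty by
replacing the disadvantaged group's background mortality and per-capita YLD
with the advantaged group's (non-Maori rates applied to Maori; women's rates
applied to men), leaving every fall-specific parameter untouched, and
re-running the subgroup model.

Because the cohort engine is linear in person-counts, subgroup runs add up
exactly to the whole-population run under fixed parameters.
"""

from __future__ import annotations

import numpy as np

from .engine import run_pair
from .intervention import ScenarioSpec, compute_icer
from .params import ParameterSet
from .strata import ETHNICITIES, SEXES


def _group_index(group: dict[str, str]) -> tuple[str, int]:
    if len(group) != 1:
        raise ValueError("a group selects exactly one of {'sex', 'ethnicity'}")
    ((dim, value),) = group.items()
    if dim == "sex":
        return dim, SEXES.index(value)
    if dim == "ethnicity":
        return dim, ETHNICITIES.index(value)
    raise ValueError(f"unknown group dimension {dim!r}")


def apply_equity_counterfactual(
    params: ParameterSet, target_group: dict[str, str], donor_group: dict[str, str]
) -> ParameterSet:
    """Give the target group the donor group's background mortality and YLD.

    Target and donor must differ on exactly one stratifier (sex or
    ethnicity); all other parameters, including fall rates and costs, are
    untouched, and the donor group's own results are unaffected.
    """
    tdim, tidx = _group_index(target_group)
    ddim, didx = _group_index(donor_group)
    if tdim != ddim:
        raise ValueError("target and donor must be groups of the same stratifier")
    if tidx == didx:
        raise ValueError("target and donor groups are identical")
    out = params.copy()
    axis_mort = 1 if tdim == "sex" else 2  # bg_mortality axes: (age, sex, eth)
    mort = out.bg_mortality.copy()
    yld = out.yld_per_capita.copy()
    idx_t = [slice(None)] * 3
    idx_d = [slice(None)] * 3
    idx_t[axis_mort] = tidx
    idx_d[axis_mort] = didx
    mort[tuple(idx_t)] = mort[tuple(idx_d)]
    yld[tuple(idx_t)] = yld[tuple(idx_d)]  # same (band, sex, eth) axis order
    out.bg_mortality = mort
    out.yld_per_capita = yld
    return out


def subgroup_population(population, group_filter: dict[str, str] | None) -> np.ndarray:
    """Population slice (46, 2, 2) restricted to the given subgroup."""
    pop = population if isinstance(population, np.ndarray) else population.by_age
    if not group_filter:
        return pop
    out = np.zeros_like(pop)
    dim, idx = _group_index(group_filter)
    sl = [slice(None)] * 3
    sl[1 if dim == "sex" else 2] = idx
    out[tuple(sl)] = pop[tuple(sl)]
    return out


def subgroup_run(
    params: ParameterSet,
    scenario: ScenarioSpec,
    population,
    group_filter: dict[str, str] | None = None,
) -> dict:
    """Baseline/intervention runs restricted to one subgroup.

    Returns the two :class:`RunResult` objects plus per-capita baseline QALY
    expectancy and per-capita QALY gain for the subgroup.
    """
    pop = subgroup_population(population, group_filter)
    n = float(pop.sum())
    if n <= 0:
        raise ValueError(f"empty subgroup: {group_filter}")
    baseline, interv = run_pair(params, scenario, pop)
    dq = interv.qalys - baseline.qalys
    dc = interv.total_cost - baseline.total_cost
    return {
        "group": group_filter or {},
        "population": n,
        "baseline": baseline,
        "intervention": interv,
        "baseline_qalys_per_capita": baseline.qalys / n,
        "delta_qalys": dq,
        "delta_cost": dc,
        "delta_qalys_per_capita": dq / n,
        "icer": compute_icer(dc, dq),
    }


def equity_analysis_rows(
    params: ParameterSet, scenario: ScenarioSpec, population
) -> list[dict]:
    """The seven-row subgroup/equity table: total, Maori, Maori under the
    equity counterfactual, non-Maori, men, men under the counterfactual,
    women."""
    rows = []
    specs: list[tuple[str, dict | None, ParameterSet]] = [
        ("total", None, params),
        ("maori", {"ethnicity": "maori"}, params),
        (
            "maori_equity",
            {"ethnicity": "maori"},
            apply_equity_counterfactual(
                params, {"ethnicity": "maori"}, {"ethnicity": "non_maori"}
            ),
        ),
        ("non_maori", {"ethnicity": "non_maori"}, params),
        ("men", {"sex": "male"}, params),
        (
            "men_equity",
            {"sex": "male"},
            apply_equity_counterfactual(params, {"sex": "male"}, {"sex": "female"}),
        ),
        ("women", {"sex": "female"}, params),
    ]
    for label, group, pset in specs:
        res = subgroup_run(pset, scenario, population, group)
        rows.append(
            {
                "group": label,
                "population": res["population"],
                "baseline_qalys": res["baseline"].qalys,
                "baseline_cost": res["baseline"].total_cost,
                "baseline_qalys_per_capita": res["baseline_qalys_per_capita"],
                "delta_qalys": res["delta_qalys"],
                "delta_cost": res["delta_cost"],
                "delta_qalys_per_capita": res["delta_qalys_per_capita"],
                "icer": res["icer"],
            }
        )
    return rows
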