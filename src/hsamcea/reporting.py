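"""Configuration handling, full-suite runs and table/figure emission.

`run_suite` ties the pipeline together: it generates the calibrated
synthetic parameter tables, runs every analysis scenario deterministically
and probabilistically, produces the scenario summary table (mean, median,
95% uncertainty interval per output), the subgroup/equity table, the
intervention-cost decomposition by targeting rule, and the tornado CSVs,
and logs the seed, configuration hash and package versions so every emitted
number is reproducible.

Rendered tables round to three significant figures; the raw CSVs keep full
precision.
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import run_pair
from .equity import equity_analysis_rows
from .intervention import ScenarioSpec, compute_icer, table2_scenarios
from .psa import PSAResult, run_psa
from .synthetic import build_default_parameter_set, write_parameter_tables
from .tornado import bars_to_frame, one_way_analysis

_KNOWN_BLOCKS = {
    "start_year",
    "jitter_sd",
    "population",
    "falls",
    "transitions",
    "mortality_decline",
    "intervention",
    "costs",
    "analysis",
}
_REQUIRED_BLOCKS = ("population", "falls", "intervention", "costs")


class ConfigError(ValueError):
    pass


def default_config() -> dict:
    """The packaged default configuration (the published parameter values)."""
    text = resources.files("hsamcea").joinpath("data/default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    """Load and validate a YAML/JSON configuration file."""
    if path is None:
        cfg = default_config()
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown configuration block(s): {sorted(unknown)}")
    missing = [b for b in _REQUIRED_BLOCKS if b not in cfg]
    if missing:
        raise ConfigError(f"missing required configuration block(s): {missing}")
    for block in _REQUIRED_BLOCKS:
        if not isinstance(cfg[block], dict):
            raise ConfigError(f"configuration block {block!r} must be a mapping")


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (rendered tables only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))


def _render(value) -> object:
    return round_sig(value) if isinstance(value, (int, float)) else value


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def scenario_summary_frame(results: dict[str, PSAResult]) -> pd.DataFrame:
    """Scenario table in the published layout: one block of rows per
    scenario with mean, median and 95% UI for net cost, QALYs gained and
    the ICER."""
    rows = []
    for name, psa in results.items():
        s = psa.summary()
        for output, key in (
            ("net_cost", "delta_cost"),
            ("qalys_gained", "delta_qalys"),
        ):
            rows.append(
                {
                    "scenario": name,
                    "output": output,
                    "mean": _render(s[key]["mean"]),
                    "median": _render(s[key]["median"]),
                    "ui_lo": _render(s[key]["lo"]),
                    "ui_hi": _render(s[key]["hi"]),
                }
            )
        icer = s["icer"]
        rows.append(
            {
                "scenario": name,
                "output": "icer",
                "mean": _render(icer["mean"]),
                "median": _render(icer["median"]),
                "ui_lo": _render(icer["lo"]),
                "ui_hi": _render(icer["hi"]),
            }
        )
    return pd.DataFrame(rows)


def render_cost_table(results: dict[str, PSAResult]) -> pd.DataFrame:
    """Intervention-cost decomposition by targeting rule (mean and 95% UI
    of the upfront program + HSAM outlay)."""
    rows = []
    for name, psa in results.items():
        mean, _, lo, hi = (
            float(psa.intervention_cost.mean()),
            float(np.percentile(psa.intervention_cost, 50)),
            float(np.percentile(psa.intervention_cost, 2.5)),
            float(np.percentile(psa.intervention_cost, 97.5)),
        )
        rows.append(
            {
                "scenario": name,
                "intervention_cost_mean": _render(mean),
                "ui_lo": _render(lo),
                "ui_hi": _render(hi),
            }
        )
    return pd.DataFrame(rows)


def run_suite(
    config: dict | str | Path | None = None,
    outdir: str | Path = "results",
    seed: int = 0,
    n_psa: int = 500,
    scenarios: list[ScenarioSpec] | None = None,
    make_plots: bool = False,
) -> dict[str, Path]:
    """Run the full analysis pipeline and write its artifacts.

    Returns a mapping from artifact name to path.  Re-running with the same
    seed and configuration is byte-identical.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params, population = build_default_parameter_set(seed=seed, config=cfg)
    artifacts: dict[str, Path] = {}

    # 1. generated parameter tables
    for path in write_parameter_tables(params, population, outdir / "params"):
        artifacts[f"params/{path.name}"] = path

    if scenarios is None:
        scenarios = table2_scenarios()

    # 2. deterministic scenario runs
    det_rows = []
    for sc in scenarios:
        baseline, interv = run_pair(params, sc, population)
        dq = interv.qalys - baseline.qalys
        dc = interv.total_cost - baseline.total_cost
        det_rows.append(
            {
                "scenario": sc.name,
                "baseline_qalys": baseline.qalys,
                "baseline_cost": baseline.total_cost,
                "delta_qalys": dq,
                "delta_cost": dc,
                "intervention_cost": interv.costs["intervention"],
                "icer": compute_icer(dc, dq),
                "n_invited_initial": interv.n_invited_initial,
                "n_invited_prospective": interv.n_invited_prospective,
            }
        )
    det_path = outdir / "scenarios_deterministic.csv"
    pd.DataFrame(det_rows).to_csv(det_path, index=False)
    artifacts["scenarios_deterministic"] = det_path

    # 3. probabilistic scenario runs
    psa_results: dict[str, PSAResult] = {}
    for i, sc in enumerate(scenarios):
        psa_results[sc.name] = run_psa(
            params, sc, population, n_iter=n_psa, seed=seed + 1000 + i
        )
    summary_path = outdir / "scenarios_psa_summary.csv"
    scenario_summary_frame(psa_results).to_csv(summary_path, index=False)
    artifacts["scenarios_psa_summary"] = summary_path

    cost_path = outdir / "intervention_costs.csv"
    targeting = {n: r for n, r in psa_results.items() if n in (
        "base_case", "risk_65plus", "norisk_65plus",
        "all_75plus", "risk_75plus", "norisk_75plus")}
    render_cost_table(targeting or psa_results).to_csv(cost_path, index=False)
    artifacts["intervention_costs"] = cost_path

    base_psa = psa_results.get("base_case") or next(iter(psa_results.values()))
    iter_path = outdir / "psa_iterations_base_case.csv"
    base_psa.to_frame().to_csv(iter_path, index=False)
    artifacts["psa_iterations_base_case"] = iter_path

    # 4. subgroup and equity analyses (deterministic, base-case scenario)
    base_sc = next((s for s in scenarios if s.name == "base_case"), scenarios[0])
    eq_path = outdir / "equity_table.csv"
    pd.DataFrame(equity_analysis_rows(params, base_sc, population)).to_csv(
        eq_path, index=False
    )
    artifacts["equity_table"] = eq_path

    # 5. one-way (tornado) analysis
    bars = one_way_analysis(params, base_sc, population)
    for output, blist in bars.items():
        path = outdir / f"tornado_{output}.csv"
        bars_to_frame(blist).to_csv(path, index=False)
        artifacts[f"tornado_{output}"] = path
        if make_plots:
            from .tornado import plot_tornado

            plot_path = outdir / f"tornado_{output}.png"
            plot_tornado(blist, f"One-way sensitivity: {output}", plot_path)
            artifacts[f"tornado_{output}_plot"] = plot_path

    # 6. reproducibility log
    log = {
        "seed": seed,
        "config_sha256": config_hash(cfg),
        "n_psa_iterations": n_psa,
        "scenarios": [s.name for s in scenarios],
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    artifacts["run_log"] = log_path
    return artifacts
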