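"""Probabilistic sensitivity analysis.

Each Monte-Carlo iteration draws one parameter set from the joint
(independent) input uncertainty and runs the baseline and intervention arms
with that same draw, so the incremental comparison is paired on parameters.
Summaries report the mean, median and 2.5th/97.5th percentiles of the
incremental cost, incremental QALYs and the per-iteration ICER.

ICER central tendency is taken over per-iteration ratios, not as the ratio
of means (the published tables report a mean and a distinct median, which
only per-iteration ratios produce).  Dominant (cost-saving) iterations are
excluded from the arithmetic mean ICER and reported as a separate fraction;
for interval bounds they rank below every finite ratio, and a bound that
lands on one is rendered "cost saving".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_pair
from .intervention import COST_SAVING, DOMINATED, ScenarioSpec, compute_icer
from .params import ParameterSet, sample_parameter_set


def summarize(samples: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, median, 2.5th pct, 97.5th pct) with linear interpolation."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    return (
        float(arr.mean()),
        float(np.percentile(arr, 50.0)),
        float(np.percentile(arr, 2.5)),
        float(np.percentile(arr, 97.5)),
    )


def _percentile_ranked(vals: np.ndarray, pct: float) -> float:
    """Linear-interpolation percentile over a ranking that may contain
    +/-inf sentinels (cost saving / dominated); a bound whose interpolation
    touches a sentinel takes the sentinel's value instead of NaN."""
    ranked = np.sort(np.asarray(vals, dtype=float))
    h = (ranked.size - 1) * pct / 100.0
    a, b = ranked[int(np.floor(h))], ranked[int(np.ceil(h))]
    if np.isfinite(a) and np.isfinite(b):
        return float(a + (b - a) * (h - np.floor(h)))
    return float(a) if not np.isfinite(a) else float(b)


@dataclass
class PSAResult:
    """Per-iteration PSA outputs and their summaries."""

    scenario: str
    n_iterations: int
    seed: int
    baseline_qalys: np.ndarray
    baseline_cost: np.ndarray
    delta_qalys: np.ndarray
    delta_cost: np.ndarray
    intervention_cost: np.ndarray  # upfront program + HSAM outlay per iteration
    icer_values: np.ndarray  # -inf = cost saving, +inf = dominated
    icer_labels: list[str | None] = field(repr=False, default_factory=list)

    def summary(self) -> dict[str, dict[str, float | str]]:
        out: dict[str, dict[str, float | str]] = {}
        for name in ("baseline_qalys", "baseline_cost", "delta_qalys", "delta_cost",
                     "intervention_cost"):
            mean, med, lo, hi = summarize(getattr(self, name))
            out[name] = {"mean": mean, "median": med, "lo": lo, "hi": hi}
        out["icer"] = self.icer_summary()
        return out

    def icer_summary(self) -> dict[str, float | str]:
        """Mean over finite ratios; quantiles over the dominance-aware ranking."""
        vals = self.icer_values
        finite = vals[np.isfinite(vals)]
        med, lo, hi = (_percentile_ranked(vals, p) for p in (50.0, 2.5, 97.5))

        def render(x: float) -> float | str:
            if np.isneginf(x):
                return COST_SAVING
            if np.isposinf(x):
                return DOMINATED
            return float(x)

        return {
            "mean": float(finite.mean()) if finite.size else COST_SAVING,
            "median": render(med),
            "lo": render(lo),
            "hi": render(hi),
            "fraction_cost_saving": float(np.isneginf(vals).mean()),
            "fraction_dominated": float(np.isposinf(vals).mean()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "baseline_qalys": self.baseline_qalys,
                "baseline_cost": self.baseline_cost,
                "delta_qalys": self.delta_qalys,
                "delta_cost": self.delta_cost,
                "intervention_cost": self.intervention_cost,
                "icer": [
                    lab if lab is not None else val
                    for val, lab in zip(self.icer_values, self.icer_labels)
                ],
            }
        )


def run_psa(
    base: ParameterSet,
    scenario: ScenarioSpec,
    population,
    n_iter: int = 2000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo PSA with paired baseline/intervention runs per draw."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    bq = np.empty(n_iter)
    bc = np.empty(n_iter)
    dq = np.empty(n_iter)
    dc = np.empty(n_iter)
    ic = np.empty(n_iter)
    icer_vals = np.empty(n_iter)
    icer_labels: list[str | None] = []
    for i in range(n_iter):
        try:
            draw = sample_parameter_set(base, base.uncertainty, rng)
            baseline, interv = run_pair(draw, scenario, population)
        except Exception as exc:  # annotate which iteration broke a contract
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        bq[i] = baseline.qalys
        bc[i] = baseline.total_cost
        dq[i] = interv.qalys - baseline.qalys
        dc[i] = interv.total_cost - baseline.total_cost
        ic[i] = interv.costs["intervention"]
        icer = compute_icer(dc[i], dq[i])
        if icer == COST_SAVING:
            icer_vals[i] = -np.inf
            icer_labels.append(COST_SAVING)
        elif isinstance(icer, str):
            icer_vals[i] = np.inf
            icer_labels.append(icer)
        else:
            icer_vals[i] = icer
            icer_labels.append(None)
    return PSAResult(
        scenario=scenario.name,
        n_iterations=n_iter,
        seed=seed,
        baseline_qalys=bq,
        baseline_cost=bc,
        delta_qalys=dq,
        delta_cost=dc,
        intervention_cost=ic,
        icer_values=icer_vals,
        icer_labels=icer_labels,
    )
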