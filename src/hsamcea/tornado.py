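"""One-way (tornado) uncertainty analysis.

For each uncertain parameter in turn, the deterministic model is re-run with
that parameter at the 2.5th and then the 97.5th percentile of its sampling
distribution, all other inputs held at their base values; the output swing
|high - low| ranks the bars.  Outputs covered: incremental QALYs,
incremental net cost, and the ICER.

An ICER bar whose extreme lands in dominance carries the "cost saving"
sentinel; for ranking, that endpoint sits at 0 NZ$/QALY on the ICER axis
(a cost-saving result is at least as good as a free one at any positive
willingness-to-pay), which is also where tornado figures conventionally
clip such bars.  A bar whose extreme is dominated or undefined has no
usable position on the ICER axis at all; that bar falls back to ranking on
its net-cost swing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_pair
from .intervention import COST_SAVING, ScenarioSpec, compute_icer
from .params import ParameterSet, apply_draw

OUTPUTS = ("delta_qalys", "delta_cost", "icer")


@dataclass
class TornadoBar:
    parameter: str
    output_low: float | str  # model output with the parameter at its 2.5th pct
    output_high: float | str  # ... at its 97.5th pct
    swing: float


def _outputs_at(params: ParameterSet, scenario: ScenarioSpec, population) -> dict:
    baseline, interv = run_pair(params, scenario, population)
    dq = interv.qalys - baseline.qalys
    dc = interv.total_cost - baseline.total_cost
    return {"delta_qalys": dq, "delta_cost": dc, "icer": compute_icer(dc, dq)}


def one_way_analysis(
    base: ParameterSet,
    scenario: ScenarioSpec,
    population,
    specs: dict | None = None,
) -> dict[str, list[TornadoBar]]:
    """Ranked tornado bars for each output; deterministic given inputs."""
    if specs is None:
        specs = base.uncertainty
    ends: dict[str, tuple[dict, dict]] = {}
    for name in sorted(specs):
        spec = specs[name]
        if spec.is_fixed:
            out = _outputs_at(base, scenario, population)
            ends[name] = (out, out)
            continue
        lo_val, hi_val = spec.ppf(0.025), spec.ppf(0.975)
        if not (np.isfinite(lo_val) and np.isfinite(hi_val)):
            raise ValueError(f"parameter {name!r} has no invertible quantiles")
        runs = []
        for value in (lo_val, hi_val):
            p = base.copy()
            apply_draw(p, name, float(value))
            runs.append(_outputs_at(p, scenario, population))
        ends[name] = (runs[0], runs[1])

    result: dict[str, list[TornadoBar]] = {}
    for output in OUTPUTS:
        bars = []
        for name, (lo, hi) in ends.items():
            a, b = lo[output], hi[output]
            if isinstance(a, str) or isinstance(b, str):
                pos = []
                for end in (a, b):
                    if not isinstance(end, str):
                        pos.append(end)
                    elif end == COST_SAVING:
                        pos.append(0.0)  # clipped to the ICER-axis origin
                    else:
                        pos = None
                        break
                if pos is None:
                    # no position on the ICER axis: rank on net-cost swing
                    swing = abs(hi["delta_cost"] - lo["delta_cost"])
                else:
                    swing = abs(pos[1] - pos[0])
            else:
                swing = abs(b - a)
            bars.append(TornadoBar(name, a, b, float(swing)))
        bars.sort(key=lambda bar: (-bar.swing, bar.parameter))
        result[output] = bars
    return result


def bars_to_frame(bars: list[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [b.parameter for b in bars],
            "output_low": [b.output_low for b in bars],
            "output_high": [b.output_high for b in bars],
            "swing": [b.swing for b in bars],
        }
    )


def plot_tornado(bars: list[TornadoBar], title: str, path) -> None:
    """Horizontal-bar tornado plot (PNG/SVG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    numeric = [b for b in bars if not isinstance(b.output_low, str)
               and not isinstance(b.output_high, str)]
    numeric = numeric[::-1]  # widest bar on top
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(4, len(numeric))))
    y = np.arange(len(numeric))
    lows = np.array([min(b.output_low, b.output_high) for b in numeric])
    highs = np.array([max(b.output_low, b.output_high) for b in numeric])
    ax.barh(y, highs - lows, left=lows, color="#4878a8")
    ax.set_yticks(y)
    ax.set_yticklabels([b.parameter for b in numeric])
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
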