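#!/usr/bin/env python
"""Run the deterministic base case (HSAM offered to everyone 65+, 3%
discounting, lifetime horizon) and print the headline results."""

import argparse
import json
from pathlib import Path

from hsamcea import ScenarioSpec, compute_icer, run_pair
from hsamcea.synthetic import build_default_parameter_set


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/base_case.json"))
    args = parser.parse_args()

    params, population = build_default_parameter_set(seed=args.seed)
    baseline, interv = run_pair(params, ScenarioSpec("base_case"), population)
    dq = interv.qalys - baseline.qalys
    dc = interv.total_cost - baseline.total_cost
    out = {
        "population": baseline.population,
        "baseline_qalys": baseline.qalys,
        "baseline_qalys_per_capita": baseline.qalys / baseline.population,
        "baseline_cost": baseline.total_cost,
        "delta_qalys": dq,
        "delta_cost": dc,
        "intervention_cost": interv.costs["intervention"],
        "icer": compute_icer(dc, dq),
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
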