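#!/usr/bin/env python
"""One-way (tornado) sensitivity analysis: each uncertain parameter is set
in turn to the 2.5th and 97.5th percentile of its distribution and the
swing in QALYs gained, net cost and the ICER is ranked."""

import argparse
from pathlib import Path

from hsamcea import ScenarioSpec, one_way_analysis
from hsamcea.synthetic import build_default_parameter_set
from hsamcea.tornado import bars_to_frame, plot_tornado


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/tornado"))
    parser.add_argument("--plots", action="store_true", help="also write PNG plots")
    args = parser.parse_args()

    params, population = build_default_parameter_set(seed=args.seed)
    bars = one_way_analysis(params, ScenarioSpec("base_case"), population)
    args.out.mkdir(parents=True, exist_ok=True)
    for output, blist in bars.items():
        frame = bars_to_frame(blist)
        frame.to_csv(args.out / f"{output}.csv", index=False)
        if args.plots:
            plot_tornado(blist, f"One-way sensitivity: {output}",
                         args.out / f"{output}.png")
        print(f"\n== {output} ==")
        print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
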