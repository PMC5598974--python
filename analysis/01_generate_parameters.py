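#!/usr/bin/env python
"""Generate the calibrated synthetic parameter tables and write them as CSV.

The tables are stratified by five-year age band, sex and ethnicity and are
calibrated exactly to the district aggregates (41,736 people 65+, 6461
treated injurious falls, 1364 hospitalized falls in 2011).
"""

import argparse
from pathlib import Path

from hsamcea.synthetic import build_default_parameter_set, write_parameter_tables


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/params"))
    args = parser.parse_args()

    params, population = build_default_parameter_set(seed=args.seed)
    paths = write_parameter_tables(params, population, args.out)
    for path in paths:
        print(path)


if __name__ == "__main__":
    main()
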