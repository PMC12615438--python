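#!/usr/bin/env python
"""Generate the synthetic model inputs and write them out for audit.

The model needs two inputs that were never published: an age/sex life table
and the control arm's short-term NYHA transition matrices. This script
writes the bundled synthetic stand-ins (a calibrated Gompertz–Makeham life
table; placeholder control matrices with improvement only before week 18)
to results/inputs/ so they can be inspected or replaced via config.
"""

import argparse
from pathlib import Path

from ohcm.mortality import annual_life_expectancy
from ohcm.parameters import default_params
from ohcm.synthetic_data import synthetic_control_matrices, synthetic_life_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    ap.add_argument("--seed", type=int, default=default_params().seed)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lt = synthetic_life_table()
    lt.to_csv(args.out / "synthetic_life_table.csv")
    print(f"life table -> {args.out/'synthetic_life_table.csv'}")
    print(f"  e0 female {annual_life_expectancy(lt, 0, 0.0):.1f} y, "
          f"male {annual_life_expectancy(lt, 0, 1.0):.1f} y")

    for e in synthetic_control_matrices(seed=args.seed):
        path = args.out / f"synthetic_control_week{e.start_week:02d}_{e.end_week:02d}.csv"
        e.matrix.to_csv(path)
    print(f"10 SYNTHETIC control-arm matrices (seed {args.seed}) -> {args.out}/")


if __name__ == "__main__":
    main()
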