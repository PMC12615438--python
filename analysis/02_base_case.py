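#!/usr/bin/env python
"""Deterministic base case: LYs and QALYs per arm, overall and by NYHA class.

Runs both arms of the cohort model at the published parameter set (5%/yr
discounting, lifetime horizon from age 42) and writes the outcome table.
With the synthetic stand-ins for the unpublished inputs, the treatment arm
lands near 15 discounted LYs and both increments are positive, driven by the
treatment arm's much larger time in NYHA I.
"""

import argparse
from pathlib import Path

from ohcm.parameters import default_params, load_config
from ohcm.pathway_engine import compare_arms, run_trace


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params = load_config(args.config) if args.config else default_params()
    out = compare_arms(params)
    df = out.to_frame()
    print(df.round(2).to_string())
    print(f"\nincremental: {out.incremental_ly:+.2f} LYs, {out.incremental_qaly:+.2f} QALYs "
          "(discounted; control arm uses SYNTHETIC trial matrices)")
    df.round(6).to_csv(args.out / "base_case_outcomes.csv")

    for arm in ("treatment", "control"):
        run_trace(params, arm).to_frame().to_csv(args.out / f"trace_{arm}.csv", index=False)
    print(f"outcome table and per-cycle traces -> {args.out}/")


if __name__ == "__main__":
    main()
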