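#!/usr/bin/env python
"""Test-retest reliability of trainee confidence ratings (real-data hook).

The deposited trainee dataset (https://data.mendeley.com/datasets/dxn9rhh9tf/2)
is not redistributed here; download it and point this script at a CSV export.
Because the deposit's schema is not standardised, you supply the column
mapping: one column of initial-test confidence ratings and one of retest
ratings, paired per trainee-session.

    python scripts/trainee_reliability.py ratings.csv \
        --initial-col confidence_initial --retest-col confidence_retest

Prints Spearman's rho with a Fisher-z confidence interval (the CI method is
tagged; intervals computed by other methods, e.g. bootstrap, are not directly
comparable).  On the deposited dataset the test-retest reliability of the
confidence ratings is expected to be very high (rho around 0.98).
"""

from __future__ import annotations

import argparse
import json
import sys

import pandas as pd

from cliviplan.stats import spearman_rho_ci


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__,
                                     formatter_class=argparse.RawDescriptionHelpFormatter)
    parser.add_argument("csv", help="CSV export of the trainee dataset")
    parser.add_argument("--initial-col", required=True,
                        help="column with initial-test confidence ratings")
    parser.add_argument("--retest-col", required=True,
                        help="column with retest confidence ratings")
    parser.add_argument("--level", type=float, default=0.95)
    args = parser.parse_args()

    df = pd.read_csv(args.csv)
    for col in (args.initial_col, args.retest_col):
        if col not in df.columns:
            print(f"error: column {col!r} not in {sorted(df.columns)}", file=sys.stderr)
            return 1
    pairs = df[[args.initial_col, args.retest_col]].dropna()
    res = spearman_rho_ci(pairs[args.initial_col].to_numpy(),
                          pairs[args.retest_col].to_numpy(), level=args.level)
    print(json.dumps({
        "rho": round(res.rho, 3),
        "n": res.n,
        "ci_low": round(res.ci_low, 3),
        "ci_high": round(res.ci_high, 3),
        "ci_level": res.ci_level,
        "ci_method": res.ci_method,
    }))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
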