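"""Univariable pre-selection of covariates at the 10% significance level.

Each candidate enters a single-covariate survey-weighted logit model; a
candidate is kept for the multivariable model when any non-reference level is
significant at the 10% level (robust Wald test).
"""

import argparse
import pathlib

import pandas as pd

import geociaf as g

CANDIDATES = ["sex", "residence", "wealth", "year",
              "age_months", "maternal_bmi", "aridity"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--alpha", type=float, default=0.10)
    ap.add_argument("--out-dir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()

    children = pd.read_csv(args.out_dir / "children_ciaf.csv")
    included, table = g.screen_univariable(children, CANDIDATES,
                                           alpha=args.alpha, full=True)
    table.to_csv(args.out_dir / "screening.csv", index=False)
    print(table.to_string(index=False))
    print(f"retained at the {args.alpha:.0%} level: {', '.join(included)}")


if __name__ == "__main__":
    main()
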