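"""Hyperprior sensitivity of the spatial variance components.

Refits the geo-additive model under the four standard inverse-Gamma settings
IG(0.001, 0.001), IG(0.01, 0.01), IG(0.5, 0.0005) and IG(1, 0.026) and
tabulates the posterior mean (SD), 95% CrI of the structured and unstructured
spatial variances and the DIC per setting.
"""

import argparse
import pathlib

import pandas as pd

import geociaf as g

SETTINGS = [(0.001, 0.001), (0.01, 0.01), (0.5, 0.0005), (1.0, 0.026)]
FIXED = [("sex", "male"), ("residence", "rural"),
         ("wealth", "poorest"), ("year", "2000")]
SMOOTHS = [("age_months", 60), ("maternal_bmi", 20)]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()

    children = pd.read_csv(args.out_dir / "children_ciaf.csv")
    graph = g.build_adjacency(str(args.out_dir / "zone_edges.csv"))
    design = g.build_design(children, g.ModelSpec.ggamm(FIXED, SMOOTHS), graph)

    table = g.sensitivity_analysis(design, SETTINGS, seed=args.seed)
    table.to_csv(args.out_dir / "sensitivity.csv", index=False)
    print(table.round(4).to_string(index=False))

    means = table["var_str_mean"]
    spread = means.max() / means.min()
    print(f"structured-variance posterior means span a factor of "
          f"{spread:.2f} across the four priors "
          f"({'robust' if spread <= 1.25 else 'prior-sensitive'} "
          f"at the 25% yardstick)")


if __name__ == "__main__":
    main()
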