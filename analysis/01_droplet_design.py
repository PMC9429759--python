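#!/usr/bin/env python
"""Poisson single-cell loading design for picolitre droplet cultivation.

Works out the published design point — 30 um (~14 pL) droplets loaded at
lambda = 0.3 from a 2e7 CFU/mL suspension — and a dilution table showing
the suspension density each droplet size needs to stay at that lambda.
At lambda = 0.3 roughly 22% of droplets carry exactly one cell while
fewer than 5% carry two or more, which is the operating point that makes
droplet contents effectively clonal.
"""

from pathlib import Path

import pandas as pd

from picodrop import design_report, droplet_volume, expected_counts, required_density
from picodrop.io import write_table

OUT = Path("results/design")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    report = design_report(30.0, target_lambda=0.3)
    write_table(pd.DataFrame([report]), OUT / "design_point.tsv")
    print("Design point (30 um droplets, lambda = 0.3):")
    print(f"  volume            {report['volume_pL']:8.2f} pL")
    print(f"  P(single cell)    {report['p_single']:8.1%}")
    print(f"  P(>= 2 cells)     {report['p_multi']:8.1%}")
    print(f"  required density  {report['required_density_cfu_per_ml']:,.0f} CFU/mL")

    empty, single, multi = expected_counts(2e8, 0.3)
    print(f"\nPer 2e8-droplet sample: {single:.3g} single-cell droplets "
          f"({empty:.3g} empty, {multi:.3g} multi-cell).")

    rows = [
        {
            "diameter_um": d,
            "volume_pL": droplet_volume(d),
            "required_density_cfu_per_ml": required_density(0.3, droplet_volume(d)),
        }
        for d in (10, 20, 30, 40, 50, 80)
    ]
    dilution = pd.DataFrame(rows)
    write_table(dilution, OUT / "dilution_table.tsv")
    print(f"\nDilution table for lambda = 0.3 written to {OUT}/dilution_table.tsv:")
    print(dilution.to_string(index=False, float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
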