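#!/usr/bin/env python
"""Simulated cultivation experiment: droplets versus bulk.

Runs the full demo pipeline (5 species x 3 strains with rare members,
1e5 droplets per replicate, three replicates in each of BHI and MRS,
plus competitive bulk cultures and the uncultured community) and then
quantifies the mechanism of interest: how much better rare strains fare
when cultivated in isolation than in a shared vessel.

All downstream profiling tables land in results/pipeline/ and are reused
by the later analysis scripts.
"""

from pathlib import Path

import pandas as pd

from picodrop.io import load_config, read_table, write_table
from picodrop.pipeline import run_pipeline

SEED = 42
OUT = Path("results/pipeline")


def main() -> None:
    config = load_config(overrides={"seed": SEED, "outdir": str(OUT)})
    run_pipeline(config)
    print(f"Pipeline artifacts written to {OUT} (seed {SEED}).")

    truth = read_table(OUT / "community_truth.tsv")
    comp = read_table(OUT / "pooled_compositions.tsv").set_index("strain_id")
    truth = truth.set_index("strain_id").loc[comp.index]

    rare = truth["abundance"] < 1e-4
    droplet_cols = [c for c in comp.columns if c.startswith(("BHI", "MRS"))]
    bulk_cols = [c for c in comp.columns if c.startswith("BULK")]
    summary = pd.DataFrame({
        "strain_id": comp.index,
        "input_abundance": truth["abundance"].to_numpy(),
        "droplet_mean_share": comp[droplet_cols].mean(axis=1).to_numpy(),
        "bulk_mean_share": comp[bulk_cols].mean(axis=1).to_numpy(),
    })
    summary["rare"] = rare.to_numpy()
    write_table(summary, OUT / "enrichment_summary.tsv", sort_by=["strain_id"])

    rare_sum = summary[summary["rare"]]
    print(f"\n{len(rare_sum)} rare strains (< 0.01% input abundance):")
    for _, row in rare_sum.iterrows():
        d, b = row["droplet_mean_share"], row["bulk_mean_share"]
        note = f"({d / b:.1f}x the bulk share)" if b > 0 else "(extinct in bulk)"
        print(f"  {row['strain_id']}: input {row['input_abundance']:.2e}, "
              f"droplet share {d:.2e}, bulk share {b:.2e} {note}")
    n_better = (rare_sum["droplet_mean_share"]
                >= rare_sum["bulk_mean_share"]).sum()
    print(f"\nFinding: {n_better}/{len(rare_sum)} rare strains end with a "
          "higher pooled share after droplet cultivation than after bulk "
          "culture — compartmentalisation removes the competition that "
          "starves slow growers in a shared vessel.")


if __name__ == "__main__":
    main()
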