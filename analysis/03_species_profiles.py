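#!/usr/bin/env python
"""Species-level community shifts after simulated droplet cultivation.

Reads the marker-gene counts produced by 02_cultivation_experiment.py,
re-estimates relative abundances, and contrasts alpha diversity before
and after cultivation.  Media support only a subset of strains, so
cultivation reshapes the community — diversity drops where a medium
starves many members — and samples separate by medium in the
Bray-Curtis PCoA.
"""

from pathlib import Path

import pandas as pd

from picodrop import alpha_diversity, beta_diversity, pcoa, relative_abundance
from picodrop.io import read_counts, write_table

PIPE = Path("results/pipeline")
OUT = Path("results/species")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_counts(PIPE / "marker_counts.tsv")
    abundance = relative_abundance(counts)

    alpha = pd.DataFrame({
        "shannon": alpha_diversity(abundance, "shannon"),
        "simpson": alpha_diversity(abundance, "simpson"),
    }).rename_axis("sample").reset_index()
    write_table(alpha, OUT / "alpha_diversity.tsv", sort_by=["sample"])

    gut = alpha.loc[alpha["sample"] == "GUT", "shannon"].iloc[0]
    cultured = alpha[alpha["sample"].str.startswith(("BHI", "MRS"))]
    print("Shannon diversity, uncultured vs droplet-cultivated:")
    print(f"  GUT                 {gut:.3f}")
    for _, row in cultured.iterrows():
        print(f"  {row['sample']:<19} {row['shannon']:.3f}")
    n_below = (cultured["shannon"] < gut).sum()
    print(f"Finding: {n_below}/{len(cultured)} cultivated samples are less "
          "diverse than the gut community.")

    dm = beta_diversity(abundance, "bray_curtis")
    emb = pcoa(dm, n_axes=2)
    coords = emb.samples.rename_axis("sample").reset_index()
    write_table(coords, OUT / "pcoa_bray_curtis.tsv", sort_by=["sample"])
    print(f"\nBray-Curtis PCoA (axis 1 explains "
          f"{emb.proportion_explained[0]:.0%} of positive inertia) written "
          f"to {OUT}/pcoa_bray_curtis.tsv.")


if __name__ == "__main__":
    main()
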