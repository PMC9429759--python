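"""Sequencing of a pooled culture into allele-count pileups and marker counts.

Rather than simulating reads and mapping them, allele counts are sampled
directly per genomic site, which preserves exactly the statistical
structure the strain profiler assumes: per-site depth is Poisson with mean
proportional to the species' share of the pool, each counted base is drawn
from the within-species strain mixture at that site, and a per-base error
flips a read to one of the other three bases uniformly.

The pileup dialect produced here is the strain profiler's sole input: one
row per (species, contig, 1-based position, sample) with counts for
A/C/G/T and a coding flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import BASES, SpeciesGenome, StrainCommunity, _child_rng
from .culture import CultureOutcome
from .errors import ConfigError

PILEUP_COLUMNS = [
    "species", "contig", "pos", "ref", "sample",
    "count_A", "count_C", "count_G", "count_T", "coding",
]

MARKER_COLUMNS = ["sample", "species", "gene", "count", "gene_length"]


def sequence_to_pileup(
    outcome: CultureOutcome,
    community: StrainCommunity,
    genomes: dict[str, SpeciesGenome],
    sample_id: str,
    mean_coverage: float = 50.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample one sample's per-site nucleotide counts for every species.

    Depth at each site of species s is Poisson(mean_coverage * p_s *
    n_species), where p_s is the species' relative abundance in the pooled
    culture — an equal-abundance species is covered at ``mean_coverage``.
    Sites with depth 0 are retained as uncovered rows.
    """
    if not mean_coverage > 0:
        raise ConfigError("mean_coverage must be positive")
    if not 0 <= error_rate < 0.25:
        raise ConfigError("error_rate must be in [0, 0.25)")

    comp = outcome.composition()
    strain_species = community.strains.set_index("strain_id")["species_id"]
    sp_share = comp.groupby(strain_species).sum()
    n_species = len(genomes)
    rng = _child_rng(seed, 4)

    frames = []
    for species, genome in genomes.items():
        p_s = float(sp_share.get(species, 0.0))
        lam = mean_coverage * p_s * n_species
        strains = [s for s in comp.index if strain_species[s] == species]
        w = comp[strains].to_numpy(float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(strains), 1 / len(strains))

        for contig, seq in genome.contigs.items():
            L = len(seq)
            ref = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            ref_code = np.searchsorted(BASES, ref)
            depth = rng.poisson(lam, size=L)

            # per-strain allele codes at each site: reference, overwritten
            # at that strain's planted variants
            allele = np.tile(ref_code, (len(strains), 1))
            for k, strain in enumerate(strains):
                var = genome.variants[strain]
                var = var[var["contig"] == contig]
                allele[k, var["pos"].to_numpy(int)] = np.searchsorted(
                    BASES, var["alt"].to_numpy()
                )

            counts = np.zeros((L, 4), dtype=int)
            variant_sites = np.nonzero((allele != ref_code).any(axis=0))[0]
            mono = np.ones(L, dtype=bool)
            mono[variant_sites] = False
            counts[mono, ref_code[mono]] = depth[mono]
            for site in variant_sites:
                per_strain = rng.multinomial(depth[site], w)
                counts[site] = np.bincount(
                    allele[:, site], weights=per_strain, minlength=4
                )

            if error_rate > 0:
                errs = rng.binomial(counts, error_rate)
                counts -= errs
                for b in range(4):
                    others = [o for o in range(4) if o != b]
                    redist = rng.multinomial(errs[:, b], [1 / 3] * 3)
                    for j, o in enumerate(others):
                        counts[:, o] += redist[:, j]

            mask = genome.coding_mask(contig)
            frames.append(pd.DataFrame({
                "species": species,
                "contig": contig,
                "pos": np.arange(1, L + 1),
                "ref": ref,
                "sample": sample_id,
                "count_A": counts[:, 0],
                "count_C": counts[:, 1],
                "count_G": counts[:, 2],
                "count_T": counts[:, 3],
                "coding": mask,
            }))
    return pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]


def make_marker_genes(
    community: StrainCommunity,
    n_markers: int = 10,
    length_range: tuple[int, int] = (500, 1500),
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed per-species marker-gene panel (gene id, length in bp)."""
    rng = _child_rng(seed, 5)
    rows = [
        (sp, f"{sp}.m{j + 1:02d}", int(rng.integers(*length_range)))
        for sp in community.species_ids
        for j in range(n_markers)
    ]
    return pd.DataFrame(rows, columns=["species", "gene", "gene_length"])


def simulate_marker_counts(
    outcome: CultureOutcome,
    community: StrainCommunity,
    markers: pd.DataFrame,
    sample_id: str,
    marker_depth: float = 100.0,
    read_length: int = 150,
    seed: int = 0,
) -> pd.DataFrame:
    """Mapped-read counts per marker gene for one sample.

    The expected read count of a marker is chosen so that its
    length-normalised coverage (count * read_length / gene_length) is
    proportional to the species' relative abundance in the pool, with
    ``marker_depth`` the coverage of a species at abundance 1.
    """
    comp = outcome.composition()
    strain_species = community.strains.set_index("strain_id")["species_id"]
    sp_share = comp.groupby(strain_species).sum()
    rng = _child_rng(seed, 6)
    lam = (
        marker_depth
        * markers["species"].map(sp_share).fillna(0.0).to_numpy()
        * markers["gene_length"].to_numpy()
        / read_length
    )
    out = markers.copy()
    out.insert(0, "sample", sample_id)
    out["count"] = rng.poisson(lam)
    return out[MARKER_COLUMNS]
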