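"""End-to-end demo pipeline: simulate -> profile species -> profile strains
-> compare genomes.

Every stage writes its tables under one output directory together with a
manifest (seed, configuration hash, package versions) sufficient to
reproduce the run bitwise.  Sample naming: ``GUT`` is the uncultured
community, ``<MEDIUM><r>`` the r-th droplet-cultivated replicate in that
medium, ``BULK-<MEDIUM>`` the competitive bulk culture.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import pandas as pd

from . import __version__, community as comm, culture, droplet, io as pio, sequencing
from . import genomes as gen, species as sp, strains as st
from .errors import PicodropError


def _log(stage: str, t0: float) -> None:
    print(f"[picodrop] {stage} done in {time.perf_counter() - t0:.1f}s", file=sys.stderr)


def simulate_samples(config: dict) -> dict:
    """Run the synthetic-community stages and return in-memory artifacts."""
    seed = int(config["seed"])
    cc, gc, cult, seq = (
        config["community"], config["genomes"], config["cultivation"],
        config["sequencing"],
    )
    com = comm.make_community(
        n_species=cc["n_species"],
        strains_per_species=cc["strains_per_species"],
        lognormal_sigma=cc["lognormal_sigma"],
        dirichlet_alpha=cc["dirichlet_alpha"],
        rare_strain_fraction=cc["rare_strain_fraction"],
        rare_abundance=cc["rare_abundance"],
        media=tuple(cc["media"]),
        growth_rate_range=tuple(cc["growth_rate_range"]),
        zero_rate_fraction=cc["zero_rate_fraction"],
        seed=seed,
    )
    genomes = comm.make_strain_genomes(
        com,
        genome_length=gc["genome_length"],
        n_contigs=gc["n_contigs"],
        coding_fraction=gc["coding_fraction"],
        divergence_rate=gc["divergence_rate"],
        seed=seed,
    )
    markers = sequencing.make_marker_genes(com, n_markers=seq["n_markers"], seed=seed)

    lam = config["design"]["target_lambda"]
    outcomes: dict[str, culture.CultureOutcome] = {
        "GUT": culture.uncultured_outcome(com, inoculum_size=cult["inoculum_size"])
    }
    for mi, medium in enumerate(cc["media"]):
        for rep in range(1, cult["replicates"] + 1):
            ens = culture.encapsulate(
                com, n_droplets=int(cult["n_droplets"]), lam=lam,
                seed=seed + 1000 * (mi + 1) + rep,
            )
            outcomes[f"{medium}{rep}"] = culture.grow_droplets(
                ens, com, medium, hours=cult["hours"],
                droplet_capacity=cult["droplet_capacity"],
            )
        outcomes[f"BULK-{medium}"] = culture.grow_bulk(
            com, medium, hours=cult["hours"],
            bulk_capacity=cult["bulk_capacity"],
            inoculum_size=cult["inoculum_size"],
        )

    counts, pileups = [], []
    for i, (sample, outcome) in enumerate(outcomes.items()):
        counts.append(sequencing.simulate_marker_counts(
            outcome, com, markers, sample,
            marker_depth=seq["marker_depth"], read_length=seq["read_length"],
            seed=seed + 7000 + i,
        ))
        pileups.append(sequencing.sequence_to_pileup(
            outcome, com, genomes, sample,
            mean_coverage=seq["mean_coverage"], error_rate=seq["error_rate"],
            seed=seed + 8000 + i,
        ))
    return {
        "community": com,
        "genomes": genomes,
        "markers": markers,
        "outcomes": outcomes,
        "marker_counts": pd.concat(counts, ignore_index=True),
        "pileup": pd.concat(pileups, ignore_index=True),
    }


def run_pipeline(config: dict, outdir: str | Path | None = None) -> Path:
    """Execute the full workflow and write all artifact tables.

    Returns the output directory.  Any stage failure aborts with the
    stage's name in the error message.
    """
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # -- design ---------------------------------------------------
        stage, t0 = "design", time.perf_counter()
        report = droplet.design_report(
            config["design"]["diameter_um"],
            target_lambda=config["design"]["target_lambda"],
        )
        pio.write_table(pd.DataFrame([report]), out / "design.tsv")
        _log(stage, t0)

        # -- simulate -------------------------------------------------
        stage, t0 = "simulate", time.perf_counter()
        sim = simulate_samples(config)
        com: comm.StrainCommunity = sim["community"]
        truth = com.strains.merge(
            com.growth_rates, left_on="strain_id", right_index=True
        )
        pio.write_table(truth, out / "community_truth.tsv", sort_by=["strain_id"])

        refs, beds, variants = {}, [], []
        for species, g in sim["genomes"].items():
            for contig, seqstr in g.contigs.items():
                refs[contig] = seqstr
            beds.append(g.coding)
            for strain, var in g.variants.items():
                variants.append(var.assign(species=species, strain=strain))
        pio.write_fasta(refs, out / "references.fasta")
        pio.write_bed(pd.concat(beds, ignore_index=True), out / "coding.bed")
        pio.write_table(
            pd.concat(variants, ignore_index=True)
            [["species", "strain", "contig", "pos", "ref", "alt"]],
            out / "truth_variants.tsv", sort_by=["species", "strain", "contig", "pos"],
        )
        compositions = pd.DataFrame(
            {s: o.composition() for s, o in sim["outcomes"].items()}
        ).rename_axis("strain_id").reset_index()
        pio.write_table(compositions, out / "pooled_compositions.tsv",
                        sort_by=["strain_id"])
        pio.write_counts(sim["marker_counts"], out / "marker_counts.tsv")
        pio.write_pileup(sim["pileup"], out / "pileup.tsv")
        _log(stage, t0)

        # -- profile species ------------------------------------------
        stage, t0 = "profile-species", time.perf_counter()
        abundance = sp.relative_abundance(
            sim["marker_counts"], read_length=config["sequencing"]["read_length"]
        )
        pio.write_table(abundance.rename_axis("sample").reset_index(),
                        out / "species_abundance.tsv", sort_by=["sample"])
        alpha = pd.DataFrame({
            "shannon": sp.alpha_diversity(abundance, "shannon"),
            "simpson": sp.alpha_diversity(abundance, "simpson"),
        }).rename_axis("sample").reset_index()
        pio.write_table(alpha, out / "alpha_diversity.tsv", sort_by=["sample"])
        for metric in ("bray_curtis", "jaccard"):
            dm = sp.beta_diversity(abundance, metric)
            pio.write_distance_matrix(dm, out / f"beta_{metric}.tsv")
            emb = sp.pcoa(dm, n_axes=2)
            pio.write_table(emb.samples.rename_axis("sample").reset_index(),
                            out / f"pcoa_{metric}.tsv", sort_by=["sample"])
        _log(stage, t0)

        # -- profile strains ------------------------------------------
        stage, t0 = "profile-strains", time.perf_counter()
        prof = config["profiling"]
        calls = st.call_sites(
            sim["pileup"], min_depth=prof["min_depth"], min_maf=prof["min_maf"],
            min_minor_count=prof["min_minor_count"],
        )
        catalog = st.build_catalog(calls, prof["prevalence_threshold"])
        pio.write_table(catalog.sites, out / "snv_catalog.tsv",
                        sort_by=["species", "contig", "pos"])
        frac = st.snv_fraction(catalog, calls, min_depth=prof["min_depth"])
        pio.write_table(frac.reset_index(), out / "snv_fraction.tsv",
                        sort_by=["species"])
        for species in com.species_ids:
            sub_calls = calls[calls["species"] == species]
            if not sub_calls["polymorphic"].any():
                continue
            sub = st.build_catalog(sub_calls, prof["prevalence_threshold"])
            if len(sub) == 0:
                continue
            dm = st.shared_snv_jaccard(sub)
            pio.write_distance_matrix(dm, out / f"snv_jaccard_{species}.tsv")
            emb = sp.pcoa(dm, n_axes=2)
            pio.write_table(emb.samples.rename_axis("sample").reset_index(),
                            out / f"snv_pcoa_{species}.tsv", sort_by=["sample"])
        _log(stage, t0)

        # -- compare genomes (first species' strains) -----------------
        stage, t0 = "compare", time.perf_counter()
        species = com.species_ids[0]
        g = sim["genomes"][species]
        strain_records = {
            strain: gen.GenomeRecord(
                genome_id=strain,
                contigs={c: g.strain_sequence(strain, c) for c in g.contigs},
            )
            for strain in g.variants
        }
        ids = sorted(strain_records)
        rows = []
        for a in ids:
            for b in ids:
                ani, frac_aln = gen.anib(strain_records[a], strain_records[b])
                rows.append((a, b, ani, frac_aln))
        pio.write_table(
            pd.DataFrame(rows, columns=["query", "reference", "ani_percent",
                                        "aligned_fraction"]),
            out / f"anib_{species}.tsv", sort_by=["query", "reference"],
        )
        sigs = {s: gen.tetra_zscores(r) for s, r in strain_records.items()}
        trows = [
            (a, b, gen.tetra_correlation(sigs[a], sigs[b]))
            for a in ids for b in ids
        ]
        pio.write_table(
            pd.DataFrame(trows, columns=["genome_a", "genome_b", "tetra_r"]),
            out / f"tetra_{species}.tsv", sort_by=["genome_a", "genome_b"],
        )
        _log(stage, t0)

        # -- manifest --------------------------------------------------
        blob = json.dumps(config, sort_keys=True).encode()
        manifest = {
            "package": "picodrop",
            "version": __version__,
            "seed": config["seed"],
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "config": config,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except PicodropError as exc:
        raise PicodropError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
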