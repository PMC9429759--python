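"""Readers and writers for the package's on-disk formats.

All tables share one flat TSV dialect: a single header line prefixed with
``#`` naming tab-separated columns, then typed rows, written in a
deterministic (key-sorted) order so that reruns diff cleanly.  Sequences
are FASTA, coding intervals are BED (0-based, half-open), trees are
Newick, configuration is JSON.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError, ParseError
from .genomes import GenomeRecord
from .species import DistanceMatrix

IUPAC_NT = set("ACGTRYSWKMBDHVN")


# ---------------------------------------------------------------------------
# flat TSV dialect

def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a DataFrame in the '#'-headed TSV dialect, key-sorted."""
    df = df.copy()
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str | Path, dtypes: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a '#'-headed TSV table, applying the given column dtypes."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ParseError(f"{path}: line 1: expected '#'-prefixed header")
        columns = header[1:].split("\t")
        body = fh.read()
    if body.strip():
        df = pd.read_csv(_io.StringIO(body), sep="\t", header=None, names=columns)
    else:
        df = pd.DataFrame(columns=columns)
    if dtypes:
        missing = set(dtypes) - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        try:
            df = df.astype(dtypes)
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: bad column type: {exc}") from exc
    return df


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """id -> uppercased sequence; duplicate ids and non-IUPAC letters error."""
    path = Path(path)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT - set("EFILPQZ*X-")  # tolerate amino acids
        if bad:
            raise ParseError(f"{path}: illegal characters {sorted(bad)} in {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_genome(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    contigs = read_fasta(path)
    return GenomeRecord(genome_id=genome_id or Path(path).stem, contigs=contigs)


# ---------------------------------------------------------------------------
# BED (0-based half-open)

def read_bed(path: str | Path) -> pd.DataFrame:
    """Coding intervals: columns (contig, start, end), 0-based half-open."""
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: need >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise ParseError(f"{path}: line {lineno}: bad interval {start}-{end}")
            rows.append((parts[0], start, end))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals = intervals.sort_values(["contig", "start"], kind="mergesort")
    with Path(path).open("w") as fh:
        for _, row in intervals.iterrows():
            fh.write(f"{row['contig']}\t{int(row['start'])}\t{int(row['end'])}\n")


# ---------------------------------------------------------------------------
# typed table wrappers

PILEUP_DTYPES = {
    "species": str, "contig": str, "pos": int, "ref": str, "sample": str,
    "count_A": int, "count_C": int, "count_G": int, "count_T": int,
    "coding": bool,
}

COUNT_DTYPES = {
    "sample": str, "species": str, "gene": str, "count": int, "gene_length": int,
}


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtypes=PILEUP_DTYPES)
    if (df["pos"] < 1).any():
        raise ParseError(f"{path}: pileup positions are 1-based (found < 1)")
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path, sort_by=["species", "contig", "pos", "sample"])


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtypes=COUNT_DTYPES)
    if (df["count"] < 0).any() or (df["gene_length"] <= 0).any():
        raise ParseError(f"{path}: counts must be >= 0 and gene lengths > 0")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path, sort_by=["sample", "species", "gene"])


# ---------------------------------------------------------------------------
# distance matrices & trees

def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#id\t" + "\t".join(dm.ids) + "\n")
        for i, rid in enumerate(dm.ids):
            row = "\t".join(repr(float(x)) for x in dm.values[i])
            fh.write(f"{rid}\t{row}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#id\t"):
            raise ParseError(f"{path}: line 1: expected '#id' header")
        ids = header.split("\t")[1:]
        rows = []
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ids) + 1:
                raise ParseError(f"{path}: line {lineno}: wrong field count")
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids=ids, values=np.array(rows))


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def read_newick(path: str | Path) -> str:
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise ParseError(f"{path}: Newick tree must end with ';'")
    return text


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results/pipeline",
    "design": {"diameter_um": 30.0, "target_lambda": 0.3},
    "community": {
        "n_species": 5,
        "strains_per_species": 3,
        "lognormal_sigma": 1.5,
        "dirichlet_alpha": 2.0,
        "rare_strain_fraction": 0.2,
        "rare_abundance": 5e-5,
        "media": ["BHI", "MRS"],
        "growth_rate_range": [0.05, 1.0],
        "zero_rate_fraction": 0.15,
    },
    "genomes": {
        "genome_length": 5000,
        "n_contigs": 1,
        "coding_fraction": 0.85,
        "divergence_rate": 0.01,
    },
    "cultivation": {
        "n_droplets": 100000,
        "replicates": 3,
        "hours": 120.0,
        "droplet_capacity": 1e4,
        "bulk_capacity": 1e9,
        "inoculum_size": 1e6,
    },
    "sequencing": {
        "mean_coverage": 50.0,
        "error_rate": 0.001,
        "marker_depth": 100.0,
        "read_length": 150,
        "n_markers": 10,
    },
    "profiling": {
        "min_depth": 5,
        "min_maf": 0.05,
        "min_minor_count": 2,
        "prevalence_threshold": 0.05,
    },
}


def _merge_config(defaults: dict, overrides: dict, path: str = "") -> dict:
    merged = dict(defaults)
    for key, value in overrides.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"configuration key {path + key!r} must be a table")
            merged[key] = _merge_config(defaults[key], value, path + key + ".")
        else:
            merged[key] = value
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Full run configuration: JSON file over package defaults.

    Unknown keys are rejected so that typos fail loudly.
    """
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        try:
            user = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        config = _merge_config(config, user)
    if overrides:
        config = _merge_config(config, overrides)
    return config
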