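"""Ground-truth strain-structured communities and planted-variant genomes.

The simulator's starting point is a multi-species community with nested
strain structure: species relative abundances are drawn log-normally
(skewed, as in real gut communities where a handful of phylotypes dominate
and some members sit below 0.01% relative abundance), each species'
abundance is partitioned among its strains by a symmetric Dirichlet, and a
designated fraction of strains is forced below a configurable "rare"
threshold.  Each strain also carries a per-medium exponential growth rate,
which is what the cultivation models consume.

Strain genomes are generated per species: one random reference sequence,
non-overlapping coding intervals covering a target fraction of the genome,
and per-strain planted substitutions at a fixed divergence rate.  The
planted variant lists are retained as ground truth so that downstream SNV
recovery can be checked site-for-site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

BASES = np.array(["A", "C", "G", "T"])

#: default relative-abundance threshold below which a strain counts as rare
RARE_THRESHOLD = 1e-4

#: default media labels (common rich media for bee-gut bacteria)
DEFAULT_MEDIA = ("BHI", "MRS")


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child stream: root seed plus a fixed per-operation key.

    All stochastic operations in the simulator derive their generator this
    way, so reproducibility survives reordering of calls.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class StrainCommunity:
    """Species -> strains with global relative abundances and growth rates.

    ``strains`` has one row per strain: strain_id, species_id, abundance
    (global, all rows sum to 1).  ``growth_rates`` is indexed by strain_id
    with one column per medium (per-hour exponential rates >= 0).
    ``references`` maps species_id -> reference genome id.
    """

    strains: pd.DataFrame
    growth_rates: pd.DataFrame
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ab = self.strains["abundance"].to_numpy()
        if (ab < 0).any():
            raise ConfigError("strain abundances must be >= 0")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ConfigError(f"strain abundances must sum to 1, got {ab.sum()!r}")
        if self.strains["strain_id"].duplicated().any():
            raise ConfigError("strain ids must be unique")

    @property
    def strain_ids(self) -> list[str]:
        return self.strains["strain_id"].tolist()

    @property
    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self.strains["species_id"]))

    @property
    def abundances(self) -> np.ndarray:
        return self.strains["abundance"].to_numpy()

    def species_of(self, strain_id: str) -> str:
        row = self.strains.loc[self.strains["strain_id"] == strain_id]
        return str(row["species_id"].iloc[0])

    def media(self) -> list[str]:
        return list(self.growth_rates.columns)

    def rates_for(self, medium: str) -> np.ndarray:
        """Growth rates (per hour) for every strain, in strain table order."""
        if medium not in self.growth_rates.columns:
            raise ConfigError(f"unknown medium {medium!r}; have {self.media()}")
        return self.growth_rates.loc[self.strain_ids, medium].to_numpy(float)


def make_community(
    n_species: int = 5,
    strains_per_species: int = 3,
    lognormal_sigma: float = 1.5,
    dirichlet_alpha: float = 2.0,
    rare_strain_fraction: float = 0.2,
    rare_abundance: float = 5e-5,
    media: tuple[str, ...] = DEFAULT_MEDIA,
    growth_rate_range: tuple[float, float] = (0.05, 1.0),
    zero_rate_fraction: float = 0.15,
    seed: int = 0,
) -> StrainCommunity:
    """Sample a strain-structured community.

    Species abundances are log-normal with shape ``lognormal_sigma``
    (normalised), split among strains by a symmetric
    Dirichlet(``dirichlet_alpha``).  A ``rare_strain_fraction`` of all
    strains (at least one when the fraction is positive) is then pinned to
    ``rare_abundance`` — below the 1e-4 rare threshold — and the remainder
    renormalised.  Each strain draws a per-medium growth rate uniformly
    from ``growth_rate_range``; a ``zero_rate_fraction`` of (strain,
    medium) pairs gets rate 0, emulating strains that a medium simply does
    not support.
    """
    if n_species < 1 or strains_per_species < 1:
        raise ConfigError("need at least one species and one strain per species")
    if not 0 <= rare_strain_fraction < 1:
        raise ConfigError("rare_strain_fraction must be in [0, 1)")
    if lognormal_sigma < 0 or dirichlet_alpha <= 0:
        raise ConfigError("invalid abundance distribution parameters")
    if not 0 < rare_abundance < RARE_THRESHOLD:
        raise ConfigError(
            f"rare_abundance must be in (0, {RARE_THRESHOLD}) to be rare"
        )

    rng = _child_rng(seed, 1)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]
    sp_ab = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_species)
    sp_ab /= sp_ab.sum()

    rows = []
    for s, p in zip(species, sp_ab):
        w = rng.dirichlet([dirichlet_alpha] * strains_per_species)
        for j in range(strains_per_species):
            rows.append((f"{s}.st{j + 1}", s, p * w[j]))
    strains = pd.DataFrame(rows, columns=["strain_id", "species_id", "abundance"])

    n_strains = len(strains)
    n_rare = int(round(rare_strain_fraction * n_strains))
    if rare_strain_fraction > 0:
        n_rare = max(n_rare, 1)
    if n_rare >= n_strains:
        raise ConfigError("cannot make every strain rare")
    if n_rare:
        rare_idx = rng.choice(n_strains, size=n_rare, replace=False)
        ab = strains["abundance"].to_numpy().copy()
        keep = np.setdiff1d(np.arange(n_strains), rare_idx)
        ab[rare_idx] = rare_abundance
        ab[keep] *= (1.0 - n_rare * rare_abundance) / ab[keep].sum()
        strains["abundance"] = ab

    lo, hi = growth_rate_range
    rates = rng.uniform(lo, hi, size=(n_strains, len(media)))
    zero_mask = rng.random((n_strains, len(media))) < zero_rate_fraction
    rates[zero_mask] = 0.0
    growth = pd.DataFrame(rates, index=strains["strain_id"], columns=list(media))

    references = {s: f"{s}.ref" for s in species}
    return StrainCommunity(strains=strains, growth_rates=growth, references=references)


def markov_sequence(
    length: int, seed: int, concentration: float = 1.0
) -> str:
    """Random nucleotide sequence from a first-order Markov chain with
    Dirichlet-random transition probabilities.

    Real genomes carry compositional bias (GC skew, codon usage) that
    uniform-random sequence lacks; a biased chain gives synthetic genomes
    a genuine oligonucleotide signature, which alignment-free relatedness
    measures rely on.  Smaller ``concentration`` means stronger bias.
    """
    if length < 2:
        raise ConfigError("length must be >= 2")
    rng = _child_rng(seed, 7)
    trans = rng.dirichlet([concentration] * 4, size=4)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = rng.integers(4)
    for i in range(1, length):
        out[i] = np.searchsorted(cum[out[i - 1]], u[i])
    return "".join(BASES[out])


def mutate_sequence(sequence: str, divergence_rate: float, seed: int) -> str:
    """Plant uniform substitutions at the given per-base rate (each to a
    uniformly chosen non-reference base); returns the mutated sequence."""
    if not 0 <= divergence_rate < 1:
        raise ConfigError("divergence_rate must be in [0, 1)")
    rng = _child_rng(seed, 8)
    arr = np.array(list(sequence))
    n = rng.binomial(len(arr), divergence_rate)
    pos = rng.choice(len(arr), size=n, replace=False)
    codes = np.searchsorted(BASES, arr[pos])
    arr[pos] = BASES[(codes + rng.integers(1, 4, size=n)) % 4]
    return "".join(arr)


@dataclass
class SpeciesGenome:
    """Reference sequence, coding intervals, and planted strain variants
    for one species.

    ``contigs`` maps contig id -> ACGT string.  ``coding`` has columns
    (contig, start, end), 0-based half-open.  ``variants`` maps strain id
    -> DataFrame (contig, pos, ref, alt) with 0-based positions.
    """

    species_id: str
    contigs: dict[str, str]
    coding: pd.DataFrame
    variants: dict[str, pd.DataFrame]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def coding_mask(self, contig: str) -> np.ndarray:
        mask = np.zeros(len(self.contigs[contig]), dtype=bool)
        for _, row in self.coding[self.coding["contig"] == contig].iterrows():
            mask[int(row["start"]) : int(row["end"])] = True
        return mask

    def strain_sequence(self, strain_id: str, contig: str) -> str:
        """Reference sequence with the strain's planted substitutions applied."""
        seq = np.array(list(self.contigs[contig]))
        var = self.variants[strain_id]
        var = var[var["contig"] == contig]
        seq[var["pos"].to_numpy(int)] = var["alt"].to_numpy()
        return "".join(seq)


def make_strain_genomes(
    community: StrainCommunity,
    genome_length: int = 5000,
    n_contigs: int = 1,
    coding_fraction: float = 0.85,
    divergence_rate: float = 0.01,
    seed: int = 0,
) -> dict[str, SpeciesGenome]:
    """Plant one random reference genome per species and per-strain variants.

    Each strain carries Binomial(genome_length, divergence_rate)
    substitutions at uniformly chosen positions, each to a uniformly
    chosen non-reference base.  Coding intervals are non-overlapping
    blocks alternating with short intergenic gaps so that roughly
    ``coding_fraction`` of every contig is coding.
    """
    if genome_length < 1000:
        raise ConfigError("genome_length must be >= 1000")
    if not 0 < coding_fraction <= 1:
        raise ConfigError("coding_fraction must be in (0, 1]")
    if not 0 <= divergence_rate < 0.1:
        raise ConfigError("divergence_rate must be in [0, 0.1)")
    if n_contigs < 1 or n_contigs > genome_length // 1000:
        raise ConfigError("n_contigs must be >= 1 and leave >= 1 kb per contig")

    genomes: dict[str, SpeciesGenome] = {}
    for si, species in enumerate(community.species_ids):
        rng = _child_rng(seed, 2, si)
        per = genome_length // n_contigs
        lengths = [per] * (n_contigs - 1) + [genome_length - per * (n_contigs - 1)]
        contigs = {
            f"{species}.c{ci + 1}": "".join(rng.choice(BASES, size=L))
            for ci, L in enumerate(lengths)
        }
        coding_rows = []
        for cid, L in zip(contigs, lengths):
            # alternate gene blocks with intergenic gaps sized so coding
            # coverage ~= coding_fraction
            gene, pos = 600, 0
            gap = max(1, int(round(gene * (1 - coding_fraction) / coding_fraction)))
            while pos < L:
                end = min(pos + gene, L)
                coding_rows.append((cid, pos, end))
                pos = end + gap
        coding = pd.DataFrame(coding_rows, columns=["contig", "start", "end"])

        strain_ids = community.strains.loc[
            community.strains["species_id"] == species, "strain_id"
        ]
        offsets = np.cumsum([0] + lengths[:-1])
        variants: dict[str, pd.DataFrame] = {}
        for strain in strain_ids:
            n_var = rng.binomial(genome_length, divergence_rate)
            pos = rng.choice(genome_length, size=n_var, replace=False)
            pos.sort()
            cidx = np.searchsorted(offsets, pos, side="right") - 1
            local = pos - offsets[cidx]
            cids = np.array(list(contigs))[cidx]
            refs = np.array(
                [contigs[c][p] for c, p in zip(cids, local)], dtype="<U1"
            )
            # shift each ref base by 1..3 in fixed base order: always != ref
            ref_codes = np.searchsorted(BASES, refs)
            alts = BASES[(ref_codes + rng.integers(1, 4, size=n_var)) % 4]
            variants[strain] = pd.DataFrame(
                {"contig": cids, "pos": local, "ref": refs, "alt": alts}
            )
        genomes[species] = SpeciesGenome(
            species_id=species, contigs=contigs, coding=coding, variants=variants
        )
    return genomes
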