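"""Strain-level SNV profiling from per-site allele-count pileups.

The procedure, per species:

1. **Site calling** — at every (site, sample) with depth >= ``min_depth``,
   the two most frequent alleles are the major/minor pair (ties broken in
   fixed A<C<G<T order); the site is polymorphic in that sample when the
   minor-allele frequency and minor count clear their thresholds.
2. **Catalog** — alleles are pooled across samples; sites with exactly
   two observed alleles (bi-allelic) whose prevalence — the fraction of
   *covered* samples in which they are polymorphic — strictly exceeds the
   prevalence threshold (default 5%) enter the SNV catalog.
3. **SNV fraction** — per sample, the number of polymorphic catalog sites
   inside protein-coding regions divided by the coding length covered at
   ``min_depth``; the per-sample strain-diversity statistic.
4. **Shared-SNV Jaccard** — between two samples, one minus the ratio of
   catalog sites polymorphic in both to sites polymorphic in either,
   restricted to sites covered in both; PCoA of this matrix visualises
   which culture conditions enriched which strains.

Everything here is deterministic: no RNG enters this module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ParseError
from .species import DistanceMatrix

BASE_ORDER = ["A", "C", "G", "T"]
COUNT_COLS = ["count_A", "count_C", "count_G", "count_T"]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MIN_MAF = 0.05
DEFAULT_MIN_MINOR_COUNT = 2
DEFAULT_PREVALENCE = 0.05


@dataclass
class SNVCatalog:
    """Bi-allelic polymorphic sites surviving the prevalence filter.

    ``sites`` has one row per catalog site: species, contig, pos, the
    allele pair, prevalence, and the coding flag.  ``presence`` /
    ``covered`` are site-by-sample boolean matrices (index aligned with
    ``sites``) recording where each site is polymorphic / covered.
    """

    sites: pd.DataFrame
    presence: pd.DataFrame
    covered: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    def __len__(self) -> int:
        return len(self.sites)


def _validate_pileup(pileup: pd.DataFrame) -> pd.DataFrame:
    required = {"species", "contig", "pos", "ref", "sample", *COUNT_COLS, "coding"}
    missing = required - set(pileup.columns)
    if missing:
        raise ParseError(f"pileup missing columns {sorted(missing)}")
    counts = pileup[COUNT_COLS].to_numpy()
    if (counts < 0).any():
        bad = int(np.nonzero((counts < 0).any(axis=1))[0][0])
        raise ParseError(f"negative allele count at pileup row {bad}")
    if not pileup["ref"].isin(BASE_ORDER).all():
        bad = pileup.index[~pileup["ref"].isin(BASE_ORDER)][0]
        raise ParseError(f"invalid reference base at pileup row {bad}")
    if pileup.duplicated(["species", "contig", "pos", "sample"]).any():
        raise ParseError("duplicate (species, contig, pos, sample) pileup rows")
    return pileup


def call_sites(
    pileup: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_maf: float = DEFAULT_MIN_MAF,
    min_minor_count: int = DEFAULT_MIN_MINOR_COUNT,
) -> pd.DataFrame:
    """Per-(site, sample) major/minor allele calls.

    Returns one row per input row with depth, covered flag, major and
    minor alleles (minor is the second most frequent allele when present,
    else None), minor-allele frequency, and the polymorphic flag.
    """
    pileup = _validate_pileup(pileup)
    counts = pileup[COUNT_COLS].to_numpy(int)
    depth = counts.sum(axis=1)
    covered = depth >= min_depth

    # argmax takes the first maximum, i.e. alphabetical tie-break
    major_idx = counts.argmax(axis=1)
    masked = counts.copy()
    masked[np.arange(len(counts)), major_idx] = -1
    minor_idx = masked.argmax(axis=1)
    minor_count = counts[np.arange(len(counts)), minor_idx]

    bases = np.array(BASE_ORDER)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(depth > 0, minor_count / np.maximum(depth, 1), 0.0)
    polymorphic = (
        covered & (minor_count >= min_minor_count) & (maf >= min_maf)
    )
    calls = pileup[["species", "contig", "pos", "sample", "coding"]].copy()
    calls["depth"] = depth
    calls["covered"] = covered
    calls["major"] = bases[major_idx]
    calls["minor"] = np.where(minor_count > 0, bases[minor_idx], None)
    calls["maf"] = maf
    calls["polymorphic"] = polymorphic
    return calls


def build_catalog(
    calls: pd.DataFrame, prevalence_threshold: float = DEFAULT_PREVALENCE
) -> SNVCatalog:
    """Pool calls across samples into the bi-allelic SNV catalog.

    Pooled alleles at a site are the major alleles of covered samples
    plus the minor alleles of samples polymorphic there.  Sites with
    exactly two pooled alleles and prevalence (# polymorphic / # covered
    samples) strictly above the threshold are kept.
    """
    if len(calls) == 0:
        raise DomainError("no calls to build a catalog from")
    cov = calls[calls["covered"]]
    if len(cov) == 0:
        raise DomainError("no covered sites in any sample")

    key = ["species", "contig", "pos"]
    covered_mat = (
        cov.assign(flag=True)
        .pivot_table(index=key, columns="sample", values="flag",
                     aggfunc="any", fill_value=False)
        .astype(bool)
    )
    poly_mat = (
        cov.pivot_table(index=key, columns="sample", values="polymorphic",
                        aggfunc="any", fill_value=False)
        .astype(bool)
    )
    n_cov = covered_mat.sum(axis=1)
    n_poly = poly_mat.sum(axis=1)
    prevalence = n_poly / n_cov

    # pooled allele sets: majors of covered samples, minors where polymorphic
    majors = cov.groupby(key)["major"].agg(set)
    minors = (
        cov[cov["polymorphic"]].groupby(key)["minor"].agg(set)
    )
    alleles = majors.combine(
        minors.reindex(majors.index), lambda a, b: a | (b if isinstance(b, set) else set())
    )
    biallelic = alleles.map(len) == 2

    keep = biallelic & (prevalence > prevalence_threshold) & (n_poly > 0)
    kept = covered_mat.index[keep.reindex(covered_mat.index, fill_value=False)]

    coding = cov.groupby(key)["coding"].first()
    pair = alleles[keep].map(lambda s: "/".join(sorted(s)))
    sites = pd.DataFrame({
        "species": [k[0] for k in kept],
        "contig": [k[1] for k in kept],
        "pos": [k[2] for k in kept],
        "alleles": pair.reindex(kept).to_numpy(),
        "prevalence": prevalence.reindex(kept).to_numpy(),
        "coding": coding.reindex(kept).to_numpy(),
    })
    return SNVCatalog(
        sites=sites.reset_index(drop=True),
        presence=poly_mat.loc[kept].reset_index(drop=True),
        covered=covered_mat.loc[kept].reset_index(drop=True),
    )


def snv_fraction(
    catalog: SNVCatalog,
    calls: pd.DataFrame,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Species x sample SNV-fraction table.

    Numerator: catalog sites in coding regions polymorphic in the sample.
    Denominator: coding positions covered at >= ``min_depth`` in the
    sample.  Samples with zero covered coding length get NaN (warning).
    """
    cov_coding = calls[calls["coding"] & (calls["depth"] >= min_depth)]
    denom = (
        cov_coding.groupby(["species", "sample"]).size().unstack(fill_value=0)
    )
    coding_sites = catalog.sites["coding"].to_numpy(bool)
    pres = catalog.presence.loc[coding_sites]
    species = catalog.sites.loc[coding_sites, "species"].to_numpy()
    numer = pres.groupby(species).sum()
    numer = numer.reindex(index=denom.index, columns=denom.columns, fill_value=0)

    if (denom == 0).any().any():
        warnings.warn("species/sample pairs with no covered coding length: NaN")
    frac = numer / denom.replace(0, np.nan)
    frac.index.name = "species"
    return frac


def shared_snv_jaccard(catalog: SNVCatalog) -> DistanceMatrix:
    """Jaccard distances between samples over shared polymorphic sites.

    For each pair, only catalog sites covered in both samples count;
    similarity is |polymorphic in both| / |polymorphic in either| and the
    distance its complement.  Pairs with an empty union get distance 0.
    """
    samples = catalog.samples
    if len(samples) < 2:
        raise DomainError("shared-SNV Jaccard needs at least two samples")
    pres = catalog.presence.to_numpy(bool)
    cov = catalog.covered.to_numpy(bool)
    n = len(samples)
    d = np.zeros((n, n))
    warned = False
    for i, j in itertools.combinations(range(n), 2):
        both_cov = cov[:, i] & cov[:, j]
        pi, pj = pres[:, i] & both_cov, pres[:, j] & both_cov
        union = (pi | pj).sum()
        if union == 0:
            warned = True
            dist = 0.0
        else:
            dist = 1.0 - (pi & pj).sum() / union
        d[i, j] = d[j, i] = dist
    if warned:
        warnings.warn("sample pair(s) share no polymorphic sites: distance 0")
    return DistanceMatrix(ids=list(samples), values=d)
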