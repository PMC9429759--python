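# Methods

## Poisson loading design

Occupancy of droplets filled from a well-mixed suspension is
Poisson-distributed: `P(X = n) = e^(−λ) λⁿ / n!` with `λ = ρV`, where
`ρ` is the viable cell density (CFU/mL) and `V` the droplet volume.
Units are fixed package-wide — diameters μm, volumes pL, densities
CFU/mL — with the conversions (1000 μm³ = 1 pL, 1 pL = 10⁻⁹ mL) as
explicit constants. Probabilities are evaluated in log space
(`exp(−λ + n·ln λ − ln Γ(n+1))`) so occupancy tails remain finite for
λ up to ~100 in design exploration. Reported roundings ("~14 pL",
"~22%") are presentation only; all internal values are full precision.
The design target λ = 0.3 and its realisation 2×10⁷ CFU/mL at 14 pL are
not identical (ρV = 0.28): the package treats 0.3 as the design target
and the density as its one-significant-figure realisation, and the
calculator reports both directions exactly.

## The cultivation simulator

The simulator exists to exhibit one mechanism — competition release by
compartmentalisation — with the simplest model that produces it, and to
give downstream profilers inputs with planted ground truth.

**Community.** Species relative abundances are log-normal (default
σ = 1.5, normalised), partitioned among strains by a symmetric
Dirichlet (α = 2). A configurable fraction of strains (default 20%) is
pinned to 5×10⁻⁵ — below the 10⁻⁴ "rare" threshold — and the rest
renormalised. Each strain draws one exponential growth rate per medium,
uniform on 0.05–1.0 h⁻¹, with 15% of (strain, medium) pairs set to 0 to
emulate media that do not support a strain. Default media labels are
BHI and MRS and the default horizon 120 h, as configuration defaults
matching common practice for bee-gut bacteria. None of the rates or
capacities is calibrated to a real organism; they are order-of-magnitude
choices, exposed in the configuration.

**Encapsulation.** Per-droplet founding counts are Poisson(λ); founder
identities are i.i.d. draws from the strain abundances. The ensemble is
stored compactly (occupancy vector + flattened founder indices).

**Growth.** Within one compartment,
`dN_i/dt = r_i N_i (1 − Σ_j N_j / K)` — logistic growth with equal
competition coefficients, where the sum runs over co-occupants of a
droplet (default K = 10⁴ cells/droplet) or the whole vessel in bulk
(default K = 10⁹, inoculum 10⁶). Droplets with a single lineage (or all
lineages sharing one rate) use the closed-form logistic; mixed-rate
compartments are integrated with LSODA (rtol 10⁻⁸), and identical
founder multisets are solved once and multiplied. Consequences worth
knowing:

- In droplets every isolated founder reaches K regardless of its rate
  (given rt ≫ 1), so slow growers are not suppressed; in bulk the fast
  growers absorb the shared capacity and slow growers stop early. That
  asymmetry is the enrichment mechanism, and it holds by orders of
  magnitude for rare slow strains.
- A rare founder that is co-encapsulated with a fast strain still loses
  its droplet. Since a founder shares its droplet with Poisson(λ)
  others, the expected pooled/input share ratio for a rare strain is
  P(X=1)/P(X≥1) (< 1; ≈ 0.86 at λ = 0.3). "Enrichment" in this model is
  therefore relative to bulk competition, not an absolute gain over the
  inoculum share.

**Sequencing.** Reads are not simulated; allele counts are sampled
directly per site, which preserves exactly the statistical structure the
strain profiler assumes (read mapping is out of scope). Per species,
per-site depth is Poisson(c̄ · p_s · S) where c̄ is the configured mean
coverage, p_s the species' share of the pooled culture and S the number
of species — so an equal-share species is covered at c̄. Each counted
base is drawn from the within-species strain mixture at that site, then
flipped to one of the other three bases uniformly with the per-base
error probability (strand-agnostic). Marker-gene counts are Poisson
with mean chosen so length-normalised coverage is proportional to
species share. Genomes are uniform-random ACGT with non-overlapping
coding blocks (default 85% coding) and Binomial(L, d) planted
substitutions per strain; `markov_sequence` additionally provides
composition-biased sequence (first-order Markov chain with
Dirichlet-random transitions) for alignment-free comparisons, because
uniform-random sequence lacks the oligonucleotide signal real genomes
carry.

**Randomness.** Every stochastic operation derives its generator as
`default_rng(SeedSequence(entropy=root_seed, spawn_key=(op,)))` with a
fixed per-operation key, so results are bitwise reproducible and
insensitive to call order; the pipeline offsets the root seed per sample.

**What the simulator does not model** (hence what passing tests do not
show about real data): droplet merging/shrinkage, syntrophy and
quorum-sensing dependence, chimeric or mismapped reads, strand bias,
copy-number variation, lag phases, and death. Recovery results on
simulated data are a correctness check of the profilers under their own
assumptions, not a validation against wet-lab truth.

## Species profiling

Species coverage in a sample is the **mean** over that species' marker
genes of `count × read_length / gene_length` (read length default
150 bp); abundances are coverages normalised per sample. The mean (not
the sum) makes the estimate robust to unequal marker-panel sizes; this
is the package's own normalisation, documented rather than
reverse-engineered from any external pipeline. Shannon diversity uses
the natural log (configurable by wrapping; zero terms skipped), Simpson
is 1 − Σp². Bray–Curtis is 1 − 2Σmin(p,q)/Σ(p+q); Jaccard operates on
presence/absence with presence meaning abundance strictly above a
threshold (default 0). Pairs with empty unions get distance 0 with a
warning rather than NaN.

PCoA is classical scaling: B = −½·J·D²·J, eigendecomposition, retain
positive eigenvalues only (no Lingoes/Cailliez correction — matching
common usage; negative eigenvalues simply indicate non-Euclidean input),
coordinates are eigenvectors scaled by √eigenvalue, and proportions
explained are relative to the positive part. The implementation is
cross-checked against scikit-bio's PCoA in the test suite.

## Strain profiling

Per (site, sample) with depth ≥ `min_depth` (default 5), the two most
frequent alleles are major/minor, ties broken in fixed A<C<G<T order for
determinism; a sample is polymorphic at the site when minor-allele
frequency ≥ `min_maf` (0.05) **and** minor count ≥ `min_minor_count`
(2). The depth/MAF defaults are the package's own conservative
desk-scale choices, exposed as flags. The catalog keeps sites that are
bi-allelic after pooling across samples and whose prevalence —
polymorphic samples / **covered** samples — strictly exceeds the 5%
threshold. Two interpretation choices are deliberate:

- The prevalence denominator counts covered samples, not all samples,
  so low-coverage samples are not penalised.
- Pooled alleles are the major alleles of covered samples plus the
  minor alleles of samples passing the polymorphism thresholds. Pooling
  every nonzero base count instead would let any sequencing error make
  a deep site tri-allelic and empty the catalog.

The SNV fraction per (species, sample) is the number of polymorphic
catalog sites in protein-coding regions divided by the coding length
covered at ≥ `min_depth` in that sample (covered length, not total gene
length, is the denominator; total length is available by computing the
denominator externally). Shared-SNV Jaccard between two samples
restricts the catalog to sites covered in both and takes
1 − |polymorphic in both|/|polymorphic in either|; empty unions give
distance 0 with a warning. Pileup files are 1-based; coding intervals
are BED (0-based, half-open); strand is ignored since allele counts are
strandless. This module contains no randomness.

## Comparative genomics

**TETRA.** Overlapping tetranucleotide counts are accumulated over every
contig and its reverse complement (per-strand counting, so no junction
artifacts and the signature is strand-symmetric). Expected counts come
from the second-order Markov model `E(w₁w₂w₃w₄) =
c(w₁w₂w₃)·c(w₂w₃w₄)/c(w₂w₃)` with variance
`E·(c(w₂w₃)−c(w₁w₂w₃))·(c(w₂w₃)−c(w₂w₃w₄))/c(w₂w₃)²`; z = (obs−E)/√var,
zero where the variance vanishes. Genomes under 5 kb trigger a warning.
Signatures are compared by Pearson correlation.

**ANI.** The query is cut into consecutive 1020 bp fragments. A
fragment is anchored in the reference (both strands) wherever at least
two shared 15-mers fall on one ~100 bp diagonal band — the seed gate is
what makes unrelated genomes yield *no* qualifying fragments, as in
BLAST-style search — and is then aligned to the banded window with an
edit-distance-optimal gapped alignment (edlib). Identity is matches /
alignment columns from the cigar; a fragment qualifies at identity
≥ 30% over ≥ 70% of its length; ANI is the mean identity of qualifying
fragments × 100 and the aligned fraction is reported alongside. ANI is
directional; `anib_symmetric` averages both directions and feeds the
species rule, which is inclusive at the boundary (≥ 95% ⇒ same
species). Ambiguous bases are excluded from k-mer work.

**Orthologs.** Candidate protein pairs (sharing ≥ 2 amino-acid 4-mers)
are scored by local alignment (BLOSUM62, gap open/extend −11/−1). An
edge requires score / self-score-of-the-shorter-protein ≥ 0.3; because
the scorer is symmetric, this single normalised score is the package's
reading of "reciprocal hits", and the normalised score replaces E-value
semantics (which would require database-size modelling). Clusters are
connected components — the degenerate inflation-1.0 case; higher
inflation is not implemented — and the core genome is the clusters with
members from every genome, reported as a one-decimal percentage.

**Neighbor joining** delegates to scikit-bio's standard NJ; negative
branch lengths (possible for non-additive input) are clamped to zero
with a warning and the Newick string is semicolon-terminated.

## Numerical and scale choices

Default demo problem sizes — 5 species × 3 strains, 5 kb genomes, 10⁵
droplets per replicate, 3 replicates per medium, 50× coverage, 10⁻³
error — keep a full pipeline run around five seconds while leaving
every statistical check well-powered; comparative-genomic analyses use
100 kb genomes. Degenerate inputs are handled explicitly: zero-coverage
samples yield flagged all-zero abundance rows, all-equal distance
matrices return their available axes with a warning, samples with no
covered coding length get NaN SNV fractions, and undefined ANI (no
qualifying fragments) propagates as "undefined" through the species
rule.

## Limitations

The growth model ignores interactions beyond shared capacity (no
cross-feeding, inhibition, or pH effects), the sequencing model assumes
independent uniform errors, and marker-gene counts assume one fixed
panel per species. ANI here is a fragment-anchored approximation of
BLAST-based ANI: values agree closely on substitution-diverged strain
pairs (the regime tested), but heavily rearranged or repeat-rich
genomes may align differently than under a full local-alignment search.
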