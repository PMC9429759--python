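"""Pairwise genome relatedness and ortholog clustering.

Three alignment-level views of how related two genomes are:

* **TETRA** — z-scores of the 256 tetranucleotide counts against a
  second-order Markov expectation, compared between genomes by Pearson
  correlation; an alignment-free relatedness index.
* **ANIb** — average nucleotide identity: the query is cut into ~1 kb
  fragments, each fragment is anchored in the reference by shared k-mer
  seeds and aligned; ANI is the mean identity of qualifying fragments.
  The conventional >= 95% ANI rule delimits species.
* **Ortholog clustering** — reciprocal protein similarity above a
  normalised-score threshold, clustered as connected components; the core
  genome is the set of clusters with members in every genome.

A neighbor-joining tree writer rounds the module out so relatedness
matrices can be rendered as Newick trees.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .errors import DomainError
from .species import DistanceMatrix

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GenomeRecord:
    """A genome: id plus one or more contig sequences (uppercase)."""

    genome_id: str
    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs or all(len(s) == 0 for s in self.contigs.values()):
            raise DomainError(f"genome {self.genome_id!r} is empty")

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class OrthologClustering:
    """Protein clusters spanning genomes.

    ``clusters`` is a list of sets of (genome_id, protein_id);
    ``n_core`` counts clusters with members from every genome.
    """

    clusters: list[set[tuple[str, str]]]
    genomes: list[str]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_core(self) -> int:
        full = set(self.genomes)
        return sum(1 for c in self.clusters if {g for g, _ in c} == full)


def _codes(seq: str) -> np.ndarray:
    """Base codes 0..3, with anything non-ACGT mapped to -1 (skipped)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        codes[arr == ord(b)] = c
    return codes


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Overlapping k-mer counts over one coded strand, skipping windows
    that contain an ambiguous base."""
    counts = np.zeros(4**k, dtype=np.int64)
    if len(codes) < k:
        return counts
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if valid.any():
        idx = windows[valid] @ (4 ** np.arange(k - 1, -1, -1))
        counts = np.bincount(idx, minlength=4**k)
    return counts


def tetra_zscores(genome: GenomeRecord) -> np.ndarray:
    """256-component tetranucleotide z-score signature.

    Counts are accumulated over every contig and its reverse complement
    (so the signature is strand-symmetric).  The expected count of word
    w1w2w3w4 under a second-order Markov model is
    c(w1w2w3)*c(w2w3w4)/c(w2w3); z = (obs - exp)/sd, with z = 0 where the
    variance vanishes.
    """
    if genome.length < 5000:
        warnings.warn(
            f"genome {genome.genome_id!r} is under 5 kb; TETRA signature noisy"
        )
    c2 = np.zeros(4**2, dtype=np.int64)
    c3 = np.zeros(4**3, dtype=np.int64)
    c4 = np.zeros(4**4, dtype=np.int64)
    for seq in genome.contigs.values():
        for strand in (seq, seq.translate(_COMPLEMENT)[::-1]):
            codes = _codes(strand)
            c2 += _kmer_counts(codes, 2)
            c3 += _kmer_counts(codes, 3)
            c4 += _kmer_counts(codes, 4)

    z = np.zeros(256)
    for w in range(256):
        w1, rest = divmod(w, 64)       # rest = w2 w3 w4
        left = w >> 2                  # w1 w2 w3
        mid = (w >> 2) & 0b1111        # w2 w3
        right = rest                   # w2 w3 w4
        cm = c3[left] * c3[right]
        if c2[mid] == 0 or cm == 0:
            continue
        exp = cm / c2[mid]
        var = exp * ((c2[mid] - c3[left]) * (c2[mid] - c3[right])) / c2[mid] ** 2
        if var <= 0:
            continue
        z[w] = (c4[w] - exp) / np.sqrt(var)
    return z


def tetra_correlation(sig1: np.ndarray, sig2: np.ndarray) -> float:
    """Pearson correlation of two tetranucleotide signatures."""
    sig1, sig2 = np.asarray(sig1, float), np.asarray(sig2, float)
    if sig1.shape != sig2.shape:
        raise DomainError("signatures must have the same length")
    if sig1.std() == 0 or sig2.std() == 0:
        warnings.warn("zero-variance signature: correlation undefined")
        return float("nan")
    return float(np.corrcoef(sig1, sig2)[0, 1])


def _seed_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, indels) from an extended cigar string."""
    match = mismatch = indel = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n)
        if op == "=":
            match += n
        elif op in "XM":
            mismatch += n
        else:
            indel += n
    return match, mismatch, indel


def anib(
    query: GenomeRecord,
    reference: GenomeRecord,
    fragment_length: int = 1020,
    min_identity: float = 0.30,
    min_aln_frac: float = 0.70,
    seed_k: int = 15,
    band_width: int = 100,
    min_seeds: int = 2,
) -> tuple[float, float]:
    """Directional average nucleotide identity (percent) and the aligned
    fraction of query fragments.

    The query is cut into consecutive ``fragment_length`` pieces.  Each
    fragment is anchored in the reference wherever at least ``min_seeds``
    shared ``seed_k``-mers fall on one diagonal band, then aligned to the
    banded reference window (gapped, edit-distance optimal).  A fragment
    qualifies when its identity is >= ``min_identity`` over >=
    ``min_aln_frac`` of its length.  ANI is the mean identity of
    qualifying fragments x 100; fragments without a seeded anchor simply
    do not align (as for unrelated genomes).

    Returns ``(nan, 0.0)`` when no fragment qualifies.
    """
    ref_strands: list[str] = []
    for seq in reference.contigs.values():
        ref_strands.append(seq.upper())
        ref_strands.append(seq.upper().translate(_COMPLEMENT)[::-1])
    indexes = [_seed_index(s, seed_k) for s in ref_strands]

    identities: list[float] = []
    n_fragments = 0
    for seq in query.contigs.values():
        seq = seq.upper()
        for start in range(0, len(seq), fragment_length):
            frag = seq[start : start + fragment_length]
            if len(frag) < seed_k:
                continue
            n_fragments += 1
            best: tuple[float, float] | None = None
            for strand, index in zip(ref_strands, indexes):
                hit = _align_fragment(
                    frag, strand, index, seed_k, band_width, min_seeds
                )
                if hit is None:
                    continue
                ident, frac = hit
                if best is None or ident > best[0]:
                    best = (ident, frac)
            if best and best[0] >= min_identity and best[1] >= min_aln_frac:
                identities.append(best[0])

    if n_fragments == 0:
        raise DomainError("query genome yields no fragments")
    if not identities:
        return float("nan"), 0.0
    return 100.0 * float(np.mean(identities)), len(identities) / n_fragments


def _align_fragment(
    frag: str,
    ref: str,
    index: dict[str, list[int]],
    seed_k: int,
    band_width: int,
    min_seeds: int,
) -> tuple[float, float] | None:
    """Best banded alignment of one fragment against one reference strand.

    Returns (identity, aligned_fraction_of_fragment) or None when no
    diagonal band collects ``min_seeds`` seed hits.
    """
    bands: dict[int, set[int]] = {}
    step = max(1, seed_k // 3)
    for qpos in range(0, len(frag) - seed_k + 1, step):
        kmer = frag[qpos : qpos + seed_k]
        for rpos in index.get(kmer, ()):
            band = (rpos - qpos) // band_width
            for b in (band, band + 1):  # hits near a band edge count twice
                bands.setdefault(b, set()).add(qpos)
    candidates = [b for b, hits in bands.items() if len(hits) >= min_seeds]
    if not candidates:
        return None
    band = max(candidates, key=lambda b: len(bands[b]))
    diag_lo = band * band_width - band_width
    lo = max(0, diag_lo - 2 * band_width)
    hi = min(len(ref), diag_lo + len(frag) + 3 * band_width)
    window = ref[lo:hi]
    res = edlib.align(frag, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    match, mismatch, _indel = _cigar_stats(res["cigar"])
    aln_len = match + mismatch + _indel
    if aln_len == 0:
        return None
    return match / aln_len, (match + mismatch) / len(frag)


def anib_symmetric(a: GenomeRecord, b: GenomeRecord, **kwargs) -> float:
    """Mean of the two directional ANIb values (NaN-aware)."""
    ab, _ = anib(a, b, **kwargs)
    ba, _ = anib(b, a, **kwargs)
    return float(np.nanmean([ab, ba]))


def classify_species(ani_percent: float | None) -> str:
    """Apply the 95% ANI species rule (inclusive at the boundary)."""
    if ani_percent is None or (
        isinstance(ani_percent, float) and np.isnan(ani_percent)
    ):
        return "undefined"
    if not 0 <= ani_percent <= 100:
        raise DomainError(f"ANI must be in [0, 100], got {ani_percent}")
    return "same_species" if ani_percent >= 95.0 else "different_species"


# ---------------------------------------------------------------------------
# ortholog clustering

_AA_KMER = 4


def _protein_kmers(seq: str) -> set[str]:
    return {seq[i : i + _AA_KMER] for i in range(len(seq) - _AA_KMER + 1)}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def cluster_orthologs(
    proteins: dict[str, dict[str, str]],
    score_threshold: float = 0.3,
    min_shared_kmers: int = 2,
) -> OrthologClustering:
    """Cluster proteins across genomes into ortholog families.

    ``proteins`` maps genome id -> {protein id -> amino-acid sequence}.
    Candidate pairs (sharing >= ``min_shared_kmers`` length-4 amino-acid
    words) are scored by local alignment (BLOSUM62, gap open/extend
    -11/-1); an edge requires the score, normalised by the self-score of
    the shorter protein, to reach ``score_threshold``.  Clusters are the
    connected components of that graph; unmatched proteins are singleton
    clusters.  Output is invariant to genome and protein input order.
    """
    if len(proteins) < 2:
        raise DomainError("need at least two genomes to cluster orthologs")
    for g, prots in proteins.items():
        if not prots:
            raise DomainError(f"genome {g!r} has an empty protein set")

    genomes = sorted(proteins)
    items: list[tuple[str, str, str]] = [
        (g, p, proteins[g][p]) for g in genomes for p in sorted(proteins[g])
    ]
    aligner = _make_aligner()
    self_scores = [float(aligner.score(s, s)) for _, _, s in items]
    kmers = [_protein_kmers(s) for _, _, s in items]

    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(items)), 2):
        if find(i) == find(j):
            continue
        if len(kmers[i] & kmers[j]) < min_shared_kmers:
            continue
        score = float(aligner.score(items[i][2], items[j][2]))
        shorter = i if len(items[i][2]) <= len(items[j][2]) else j
        if self_scores[shorter] <= 0:
            continue
        if score / self_scores[shorter] >= score_threshold:
            parent[find(i)] = find(j)

    groups: dict[int, set[tuple[str, str]]] = {}
    for idx, (g, p, _) in enumerate(items):
        groups.setdefault(find(idx), set()).add((g, p))
    clusters = sorted(groups.values(), key=lambda c: sorted(c))
    return OrthologClustering(clusters=clusters, genomes=genomes)


def core_fraction(clustering: OrthologClustering | tuple[int, int]) -> float:
    """Core clusters as a percentage of all clusters.

    Accepts either a clustering or a bare ``(n_core, n_clusters)`` summary
    (for worked examples quoted from published totals).
    """
    if isinstance(clustering, OrthologClustering):
        n_core, n_clusters = clustering.n_core, clustering.n_clusters
    else:
        n_core, n_clusters = clustering
    if n_clusters < 1:
        raise DomainError("need at least one cluster")
    return 100.0 * n_core / n_clusters


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(distances: DistanceMatrix) -> str:
    """Neighbor-joining tree in Newick form.

    Negative branch lengths (possible for non-additive input) are clamped
    to zero with a warning.
    """
    if len(distances.ids) < 3:
        raise DomainError("neighbor joining needs at least three taxa")
    dm = _SkbioDM(distances.values, ids=distances.ids)
    tree = _skbio_nj(dm)
    clamped = False
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative branch length(s) clamped to 0")
    newick = str(tree).strip()
    if not newick.endswith(";"):
        newick += ";"
    return newick
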