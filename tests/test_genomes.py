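"""Comparative genomics: TETRA signatures, fragment-based ANI, the 95%
species rule, ortholog clustering, and neighbor joining."""

import io

import numpy as np
import pytest
from skbio import TreeNode

import picodrop as pk
from picodrop.errors import DomainError


class TestTetra:
    def test_homopolymer_z_near_zero(self):
        g = pk.GenomeRecord("homo", {"c": "A" * 6000})
        sig = pk.tetra_zscores(g)
        assert abs(sig[0]) < 0.1          # AAAA index 0
        assert abs(sig[255]) < 0.1        # TTTT from the reverse complement

    def test_strand_symmetric(self):
        seq = pk.markov_sequence(20_000, seed=1)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        s1 = pk.tetra_zscores(pk.GenomeRecord("f", {"c": seq}))
        s2 = pk.tetra_zscores(pk.GenomeRecord("r", {"c": rc}))
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_zscores_mostly_within_null_band(self):
        seq = pk.markov_sequence(100_000, seed=2, concentration=50.0)
        sig = pk.tetra_zscores(pk.GenomeRecord("g", {"c": seq}))
        assert np.mean(np.abs(sig) < 4) > 0.95

    def test_warns_below_5kb(self):
        with pytest.warns(UserWarning):
            pk.tetra_zscores(pk.GenomeRecord("small", {"c": "ACGT" * 300}))


class TestTetraCorrelation:
    def test_identical_genomes(self):
        sig = pk.tetra_zscores(pk.GenomeRecord("g", {"c": pk.markov_sequence(50_000, seed=3)}))
        assert pk.tetra_correlation(sig, sig) == pytest.approx(1.0)

    def test_same_species_regime(self):
        """Strains at 1% divergence correlate above 0.99, far above
        independent genomes."""
        ref = pk.markov_sequence(100_000, seed=4)
        mut = pk.mutate_sequence(ref, 0.01, seed=5)
        other = pk.markov_sequence(100_000, seed=6)
        s_ref = pk.tetra_zscores(pk.GenomeRecord("ref", {"c": ref}))
        s_mut = pk.tetra_zscores(pk.GenomeRecord("mut", {"c": mut}))
        s_other = pk.tetra_zscores(pk.GenomeRecord("other", {"c": other}))
        within = pk.tetra_correlation(s_ref, s_mut)
        between = pk.tetra_correlation(s_ref, s_other)
        assert within > 0.99
        assert within > between + 0.1

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning):
            r = pk.tetra_correlation(np.zeros(256), np.ones(256))
        assert np.isnan(r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            pk.tetra_correlation(np.zeros(256), np.zeros(16))


class TestAnib:
    def test_self_identity_is_100(self, markov_pair_100kb):
        ref, _ = markov_pair_100kb
        ani, frac = pk.anib(ref, ref)
        assert ani == pytest.approx(100.0, abs=1e-9)
        assert frac == pytest.approx(1.0)

    def test_planted_divergence_tracks_identity(self, markov_pair_100kb):
        ref, mut3 = markov_pair_100kb
        ani, frac = pk.anib(ref, mut3)
        assert ani == pytest.approx(97.0, abs=0.5)
        assert frac > 0.95

    def test_monotone_in_divergence(self):
        """ANI decreases with planted divergence over 0/1/3/5%."""
        ref = pk.markov_sequence(50_000, seed=7)
        query = pk.GenomeRecord("q", {"c": ref})
        anis = []
        for i, d in enumerate((0.0, 0.01, 0.03, 0.05)):
            mut = pk.GenomeRecord(f"m{i}", {"c": pk.mutate_sequence(ref, d, seed=8 + i)})
            ani, _ = pk.anib(query, mut)
            anis.append(ani)
            assert ani == pytest.approx(100 - 100 * d, abs=0.5)
        assert all(a > b - 0.3 for a, b in zip(anis, anis[1:]))

    def test_unrelated_genomes_have_no_qualifying_fragments(self):
        a = pk.GenomeRecord("a", {"c": pk.markov_sequence(100_000, seed=20, concentration=50.0)})
        b = pk.GenomeRecord("b", {"c": pk.markov_sequence(100_000, seed=21, concentration=50.0)})
        ani, frac = pk.anib(a, b)
        assert np.isnan(ani)
        assert frac == 0.0

    def test_reverse_complement_reference_found(self):
        seq = pk.markov_sequence(30_000, seed=22)
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        ani, frac = pk.anib(
            pk.GenomeRecord("f", {"c": seq}), pk.GenomeRecord("r", {"c": rc})
        )
        assert ani == pytest.approx(100.0, abs=1e-9)
        assert frac == pytest.approx(1.0)


class TestClassifySpecies:
    @pytest.mark.parametrize("ani,expected", [
        (96.2, "same_species"),
        (89.0, "different_species"),
        (95.0, "same_species"),      # inclusive boundary
        (94.999, "different_species"),
        (float("nan"), "undefined"),
        (None, "undefined"),
    ])
    def test_rule(self, ani, expected):
        assert pk.classify_species(ani) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            pk.classify_species(101.0)


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


class TestOrthologClustering:
    def test_identical_protein_sets_all_core(self):
        rng = np.random.default_rng(30)
        prots = {f"p{i}": random_protein(rng, 120) for i in range(5)}
        clustering = pk.cluster_orthologs({"g1": prots, "g2": dict(prots), "g3": dict(prots)})
        assert clustering.n_clusters == 5
        assert clustering.n_core == 5
        assert pk.core_fraction(clustering) == 100.0

    def test_unrelated_proteins_are_singletons(self):
        rng = np.random.default_rng(31)
        proteins = {
            g: {f"{g}.p{i}": random_protein(rng, 100) for i in range(3)}
            for g in ("g1", "g2")
        }
        clustering = pk.cluster_orthologs(proteins)
        assert clustering.n_clusters == 6
        assert clustering.n_core == 0

    def test_diverged_orthologs_still_cluster(self):
        rng = np.random.default_rng(32)
        base = random_protein(rng, 150)

        def mutate(seq, n):
            arr = list(seq)
            for pos in rng.choice(len(arr), size=n, replace=False):
                arr[pos] = random_protein(rng, 1)
            return "".join(arr)

        proteins = {
            "g1": {"fam": base, "own1": random_protein(rng, 90)},
            "g2": {"fam": mutate(base, 15), "own2": random_protein(rng, 90)},
            "g3": {"fam": mutate(base, 15), "own3": random_protein(rng, 90)},
        }
        clustering = pk.cluster_orthologs(proteins)
        assert clustering.n_clusters == 4
        assert clustering.n_core == 1
        assert pk.core_fraction(clustering) == pytest.approx(25.0)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(33)
        base = random_protein(rng, 140)
        proteins = {
            "g1": {"a": base, "b": random_protein(rng, 80)},
            "g2": {"c": base, "d": random_protein(rng, 80)},
        }
        reversed_input = {
            "g2": dict(reversed(list(proteins["g2"].items()))),
            "g1": dict(reversed(list(proteins["g1"].items()))),
        }
        c1 = pk.cluster_orthologs(proteins)
        c2 = pk.cluster_orthologs(reversed_input)
        assert sorted(map(sorted, c1.clusters)) == sorted(map(sorted, c2.clusters))

    def test_empty_genome_rejected(self):
        with pytest.raises(DomainError):
            pk.cluster_orthologs({"g1": {"p": "MKV"}, "g2": {}})


class TestCoreFraction:
    def test_published_worked_example(self):
        # 510 core clusters among 1710 gene families -> 29.8%
        assert round(pk.core_fraction((510, 1710)), 1) == 29.8

    def test_arithmetic(self):
        assert pk.core_fraction((1, 3)) == pytest.approx(33.333, abs=1e-3)
        with pytest.raises(DomainError):
            pk.core_fraction((0, 0))


def _splits(newick, taxa):
    """Non-trivial unrooted bipartitions, normalised away from taxa[0]."""
    tree = TreeNode.read(io.StringIO(newick))
    ref = taxa[0]
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(taxa) - side
        if 1 < len(side) < len(taxa) - 1:
            out.add(side)
    return out


def random_additive_tree(n_taxa, rng):
    """Random binary tree with uniform branch lengths; returns (newick,
    taxa, distance matrix) with additive path-length distances."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    clusters = [({t: 0.0}, t) for t in taxa]
    dist = {}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (da, na), (db, nb) = clusters[j], clusters[i]
        la, lb = rng.uniform(0.1, 1.0, size=2)
        for ta, ha in da.items():
            for tb, hb in db.items():
                dist[frozenset((ta, tb))] = ha + la + hb + lb
        merged = {t: h + la for t, h in da.items()}
        merged.update({t: h + lb for t, h in db.items()})
        newick = f"({na}:{la:.6f},{nb}:{lb:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, newick))
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            d[a, b] = d[b, a] = dist[frozenset((taxa[a], taxa[b]))]
    return clusters[0][1] + ";", taxa, d


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_exact(self):
        d = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        newick = pk.nj_tree(pk.DistanceMatrix(ids=list("abc"), values=d))
        tree = TreeNode.read(io.StringIO(newick))
        # x_a = (d_ab + d_ac - d_bc)/2 etc.
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_round_trip_preserves_leaf_set(self):
        rng = np.random.default_rng(40)
        _, taxa, d = random_additive_tree(6, rng)
        newick = pk.nj_tree(pk.DistanceMatrix(ids=taxa, values=d))
        tree = TreeNode.read(io.StringIO(newick))
        assert sorted(t.name for t in tree.tips()) == sorted(taxa)

    def test_recovers_random_additive_topologies(self):
        """NJ is consistent on additive distances: 20/20 random trees with
        up to 8 taxa are recovered exactly (bipartition sets equal)."""
        rng = np.random.default_rng(41)
        for trial in range(20):
            n_taxa = int(rng.integers(4, 9))
            true_newick, taxa, d = random_additive_tree(n_taxa, rng)
            est_newick = pk.nj_tree(pk.DistanceMatrix(ids=taxa, values=d))
            assert _splits(est_newick, taxa) == _splits(true_newick, taxa), (
                f"trial {trial}: topology mismatch"
            )

    def test_too_few_taxa_rejected(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(DomainError):
            pk.nj_tree(pk.DistanceMatrix(ids=["a", "b"], values=d))
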