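"""Strain-level SNV profiling: site calls, the bi-allelic prevalence
catalog, the SNV-fraction statistic, and shared-SNV Jaccard distances."""

import itertools

import numpy as np
import pandas as pd
import pytest

import picodrop as pk
from picodrop.errors import DomainError, ParseError

from conftest import make_two_strain_community, simple_pileup


class TestCallSites:
    def test_monoallelic_covered_site(self):
        p = simple_pileup([("sp", "c", 1, "A", "s1", (10, 0, 0, 0), True)])
        call = pk.call_sites(p).iloc[0]
        assert call["covered"] and not call["polymorphic"]
        assert call["major"] == "A" and call["minor"] is None

    def test_minor_count_threshold(self):
        # one minor read is below the min_minor_count=2 default
        p = simple_pileup([("sp", "c", 1, "A", "s1", (9, 1, 0, 0), True)])
        assert not pk.call_sites(p).iloc[0]["polymorphic"]

    def test_polymorphic_site_maf(self):
        p = simple_pileup([("sp", "c", 1, "A", "s1", (6, 0, 4, 0), True)])
        call = pk.call_sites(p).iloc[0]
        assert call["polymorphic"]
        assert call["maf"] == pytest.approx(0.4)
        assert (call["major"], call["minor"]) == ("A", "G")

    def test_depth_threshold_marks_uncovered(self):
        p = simple_pileup([("sp", "c", 1, "A", "s1", (2, 2, 0, 0), True)])
        call = pk.call_sites(p, min_depth=5).iloc[0]
        assert not call["covered"] and not call["polymorphic"]

    def test_ties_broken_alphabetically(self):
        p = simple_pileup([("sp", "c", 1, "A", "s1", (0, 5, 5, 5), True)])
        call = pk.call_sites(p).iloc[0]
        assert (call["major"], call["minor"]) == ("C", "G")

    def test_malformed_rows_rejected(self):
        p = simple_pileup([("sp", "c", 1, "N", "s1", (1, 0, 0, 0), True)])
        with pytest.raises(ParseError):
            pk.call_sites(p)
        p2 = simple_pileup([("sp", "c", 1, "A", "s1", (-1, 0, 0, 0), True)])
        with pytest.raises(ParseError):
            pk.call_sites(p2)

    @pytest.mark.parametrize("param,values", [
        ("min_depth", [1, 5, 10, 20]),
        ("min_maf", [0.01, 0.05, 0.1, 0.3]),
    ])
    def test_threshold_monotonicity(self, param, values):
        """Raising min_depth never gains covered sites; raising min_maf
        never gains polymorphic calls."""
        rng = np.random.default_rng(13)
        rows = []
        for pos in range(1, 201):
            c = rng.multinomial(rng.integers(0, 40), [0.7, 0.2, 0.05, 0.05])
            rows.append(("sp", "c", pos, "A", "s1", tuple(c), True))
        p = simple_pileup(rows)
        prev = None
        for v in values:
            calls = pk.call_sites(p, **{param: v})
            n = calls["covered" if param == "min_depth" else "polymorphic"].sum()
            if prev is not None:
                assert n <= prev
            prev = n


class TestBuildCatalog:
    def test_prevalence_keeps_site_above_threshold(self):
        rows = [("sp", "c", 1, "A", f"s{i}", (10, 0, 0, 0), True) for i in range(9)]
        rows.append(("sp", "c", 1, "A", "s9", (6, 4, 0, 0), True))
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert len(catalog) == 1
        site = catalog.sites.iloc[0]
        assert site["prevalence"] == pytest.approx(0.1)
        assert site["alleles"] == "A/C"

    def test_triallelic_site_excluded(self):
        rows = [
            ("sp", "c", 1, "A", "s1", (6, 4, 0, 0), True),
            ("sp", "c", 1, "A", "s2", (6, 0, 4, 0), True),
        ]
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert len(catalog) == 0

    def test_never_polymorphic_site_excluded(self):
        rows = [("sp", "c", 1, "A", f"s{i}", (10, 0, 0, 0), True) for i in range(4)]
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert len(catalog) == 0

    def test_prevalence_counts_covered_samples_only(self):
        rows = [
            ("sp", "c", 1, "A", "s1", (6, 4, 0, 0), True),   # polymorphic
            ("sp", "c", 1, "A", "s2", (10, 0, 0, 0), True),  # covered, mono
            ("sp", "c", 1, "A", "s3", (1, 0, 0, 0), True),   # uncovered
        ]
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert catalog.sites.iloc[0]["prevalence"] == pytest.approx(0.5)


class TestSnvFraction:
    def test_no_polymorphism_gives_zero(self):
        rows = [("sp", "c", p, "A", "s1", (10, 0, 0, 0), True) for p in range(1, 51)]
        rows.append(("sp", "c", 51, "A", "s1", (6, 4, 0, 0), True))
        calls = pk.call_sites(simple_pileup(rows))
        catalog = pk.build_catalog(calls)
        frac = pk.snv_fraction(catalog, calls)
        # 1 polymorphic coding site over 51 covered coding bp
        assert frac.loc["sp", "s1"] == pytest.approx(1 / 51)

    def test_two_percent_scale(self):
        """20 polymorphic coding sites over 1000 covered coding bp is the
        2% SNV-fraction scale."""
        rows = []
        for p in range(1, 1001):
            c = (6, 4, 0, 0) if p <= 20 else (10, 0, 0, 0)
            rows.append(("sp", "c", p, "A", "s1", c, True))
        calls = pk.call_sites(simple_pileup(rows))
        catalog = pk.build_catalog(calls)
        assert pk.snv_fraction(catalog, calls).loc["sp", "s1"] == pytest.approx(0.02)

    def test_noncoding_sites_excluded(self):
        rows = [
            ("sp", "c", 1, "A", "s1", (6, 4, 0, 0), False),  # non-coding SNV
            ("sp", "c", 2, "A", "s1", (10, 0, 0, 0), True),
            ("sp", "c", 3, "A", "s1", (6, 4, 0, 0), True),
        ]
        calls = pk.call_sites(simple_pileup(rows))
        catalog = pk.build_catalog(calls)
        assert pk.snv_fraction(catalog, calls).loc["sp", "s1"] == pytest.approx(1 / 2)

    def test_planted_divergence_recovered(self):
        """Two equal strains at divergence d sequenced deep with zero error
        have SNV fraction ~ the expected pairwise difference rate."""
        com = make_two_strain_community(abundances=(0.5, 0.5))
        d = 0.01
        genomes = pk.make_strain_genomes(
            com, genome_length=20_000, divergence_rate=d, seed=41
        )
        pile = pk.sequence_to_pileup(
            pk.uncultured_outcome(com), com, genomes, "s1",
            mean_coverage=100, error_rate=0.0, seed=42,
        )
        calls = pk.call_sites(pile)
        catalog = pk.build_catalog(calls, prevalence_threshold=0.0)
        frac = pk.snv_fraction(catalog, calls).loc["sp01", "s1"]
        g = genomes["sp01"]
        v1 = {(r.contig, r.pos, r.alt) for r in g.variants["sp01.st1"].itertuples()}
        v2 = {(r.contig, r.pos, r.alt) for r in g.variants["sp01.st2"].itertuples()}
        # expected: fraction of coding sites where the strains differ
        diff_positions = {(c, p) for c, p, _ in v1 ^ v2}
        coding = g.coding_mask("sp01.c1")
        expected = sum(coding[p] for _, p in diff_positions) / coding.sum()
        assert frac == pytest.approx(expected, rel=0.05)


class TestSharedSnvJaccard:
    @staticmethod
    def brute_force(poly_sets, covered_sets, samples):
        n = len(samples)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            common = covered_sets[i] & covered_sets[j]
            a = poly_sets[i] & common
            b = poly_sets[j] & common
            union = a | b
            d[i, j] = d[j, i] = 1 - len(a & b) / len(union) if union else 0.0
        return d

    def test_identical_profiles_distance_zero(self):
        rows = [
            ("sp", "c", p, "A", s, (6, 4, 0, 0), True)
            for p in (1, 2, 3) for s in ("s1", "s2")
        ]
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert pk.shared_snv_jaccard(catalog).values[0, 1] == 0.0

    def test_set_arithmetic_example(self):
        # polymorphic sites {1,2,3} vs {2,3,4} -> similarity 0.5
        rows = []
        for p in (1, 2, 3, 4):
            c1 = (6, 4, 0, 0) if p in (1, 2, 3) else (10, 0, 0, 0)
            c2 = (6, 4, 0, 0) if p in (2, 3, 4) else (10, 0, 0, 0)
            rows.append(("sp", "c", p, "A", "s1", c1, True))
            rows.append(("sp", "c", p, "A", "s2", c2, True))
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        assert pk.shared_snv_jaccard(catalog).values[0, 1] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_catalogs(self):
        """Vectorised Jaccard equals explicit set arithmetic on random
        10-sample x 50-site instances."""
        rng = np.random.default_rng(99)
        for _ in range(5):
            n_sites, samples = 50, [f"s{i}" for i in range(10)]
            rows = []
            poly_sets = [set() for _ in samples]
            covered_sets = [set() for _ in samples]
            for p in range(1, n_sites + 1):
                for i, s in enumerate(samples):
                    u = rng.random()
                    if u < 0.2:
                        counts = (1, 0, 0, 0)            # uncovered
                    elif u < 0.6:
                        counts = (10, 0, 0, 0)           # covered monoallelic
                        covered_sets[i].add(p)
                    else:
                        counts = (6, 4, 0, 0)            # polymorphic
                        covered_sets[i].add(p)
                        poly_sets[i].add(p)
                    rows.append(("sp", "c", p, "A", s, counts, True))
            catalog = pk.build_catalog(
                pk.call_sites(simple_pileup(rows)), prevalence_threshold=0.0
            )
            kept = set(catalog.sites["pos"])
            expected = self.brute_force(
                [s & kept for s in poly_sets],
                [s & kept for s in covered_sets],
                samples,
            )
            np.testing.assert_allclose(
                pk.shared_snv_jaccard(catalog).values, expected, atol=1e-12
            )

    def test_single_sample_rejected(self):
        rows = [("sp", "c", 1, "A", "s1", (6, 4, 0, 0), True)]
        catalog = pk.build_catalog(pk.call_sites(simple_pileup(rows)))
        with pytest.raises(DomainError):
            pk.shared_snv_jaccard(catalog)


class TestEndToEndRecovery:
    def test_planted_variants_recovered_exactly(self):
        """With zero sequencing error and deep coverage, the catalog is
        exactly the set of sites where co-cultured strains differ — no
        false positives, no false negatives."""
        com = make_two_strain_community(abundances=(0.5, 0.5))
        genomes = pk.make_strain_genomes(
            com, genome_length=5000, divergence_rate=0.01, seed=55
        )
        piles = [
            pk.sequence_to_pileup(
                pk.uncultured_outcome(com), com, genomes, f"s{i}",
                mean_coverage=50, error_rate=0.0, seed=60 + i,
            )
            for i in range(3)
        ]
        calls = pk.call_sites(pd.concat(piles, ignore_index=True))
        catalog = pk.build_catalog(calls, prevalence_threshold=0.05)
        g = genomes["sp01"]
        seq1 = g.strain_sequence("sp01.st1", "sp01.c1")
        seq2 = g.strain_sequence("sp01.st2", "sp01.c1")
        truth = {i + 1 for i, (a, b) in enumerate(zip(seq1, seq2)) if a != b}
        recovered = set(catalog.sites["pos"])
        assert recovered == truth

    def test_replicates_cluster_by_mixture(self):
        """Samples enriching different strain pairs expose different
        polymorphic site sets: shared-SNV Jaccard distances are smaller
        between replicates of one mixture than across mixtures."""

        def three_strain_community(abundances):
            strains = pd.DataFrame({
                "strain_id": ["sp01.st1", "sp01.st2", "sp01.st3"],
                "species_id": ["sp01"] * 3,
                "abundance": list(abundances),
            })
            growth = pd.DataFrame(
                np.ones((3, 1)), index=strains["strain_id"], columns=["BHI"]
            )
            return pk.StrainCommunity(strains=strains, growth_rates=growth)

        base = three_strain_community([1 / 3] * 3)
        genomes = pk.make_strain_genomes(
            base, genome_length=5000, divergence_rate=0.01, seed=70
        )
        mix_a = three_strain_community([0.5, 0.5, 0.0])   # strains 1+2
        mix_b = three_strain_community([0.5, 0.0, 0.5])   # strains 1+3
        piles = []
        for i, (com, tag) in enumerate(
            [(mix_a, "mixA1"), (mix_a, "mixA2"), (mix_b, "mixB1"), (mix_b, "mixB2")]
        ):
            piles.append(pk.sequence_to_pileup(
                pk.uncultured_outcome(com), com, genomes, tag,
                mean_coverage=40, error_rate=0.0, seed=80 + i,
            ))
        calls = pk.call_sites(pd.concat(piles, ignore_index=True))
        catalog = pk.build_catalog(calls)
        dm = pk.shared_snv_jaccard(catalog).to_frame()
        within = [dm.loc["mixA1", "mixA2"], dm.loc["mixB1", "mixB2"]]
        across = [dm.loc[a, b] for a in ("mixA1", "mixA2")
                  for b in ("mixB1", "mixB2")]
        assert max(within) < min(across)
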