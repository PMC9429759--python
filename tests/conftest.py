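import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import picodrop as pk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_two_strain_community(
    abundances=(0.5, 0.5), rates=((1.0, 1.0), (1.0, 1.0)), media=("BHI", "MRS")
):
    """Minimal one-species, two-strain community with explicit parameters."""
    strains = pd.DataFrame({
        "strain_id": ["sp01.st1", "sp01.st2"],
        "species_id": ["sp01", "sp01"],
        "abundance": list(abundances),
    })
    growth = pd.DataFrame(
        np.array(rates, dtype=float), index=strains["strain_id"], columns=list(media)
    )
    return pk.StrainCommunity(strains=strains, growth_rates=growth,
                              references={"sp01": "sp01.ref"})


@pytest.fixture(scope="session")
def demo_community():
    return pk.make_community(seed=11)


@pytest.fixture(scope="session")
def demo_genomes(demo_community):
    return pk.make_strain_genomes(demo_community, genome_length=5000, seed=11)


def simple_pileup(rows):
    """Build a pileup frame from (species, contig, pos, ref, sample,
    (a,c,g,t), coding) tuples."""
    recs = [
        {"species": sp, "contig": ct, "pos": pos, "ref": ref, "sample": sm,
         "count_A": c[0], "count_C": c[1], "count_G": c[2], "count_T": c[3],
         "coding": coding}
        for sp, ct, pos, ref, sm, c, coding in rows
    ]
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def markov_pair_100kb():
    """A 100 kb composition-biased reference and its 3%-diverged strain."""
    ref = pk.markov_sequence(100_000, seed=5)
    mut = pk.mutate_sequence(ref, 0.03, seed=6)
    return (
        pk.GenomeRecord("ref", {"c1": ref}),
        pk.GenomeRecord("mut3", {"c1": mut}),
    )
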