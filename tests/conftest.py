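import pytest

from poasankey.fixtures import generate_msa_fixture, generate_tree_fixture
from poasankey.msa_io import Alignment
from poasankey.poa_graph import build_poa


@pytest.fixture
def tiny_nuc_aln():
    """The 2x4 nucleotide example used across modules."""
    return Alignment(
        ids=("s1", "s2"), rows=("AC-T", "ACGT"), n_columns=4, alphabet="nucleotide"
    ).validate()


@pytest.fixture
def protein_aln():
    return generate_msa_fixture(
        n_seqs=10, n_columns=30, alphabet="protein",
        substitution_rate=0.4, gap_rate=0.1, seed=11,
    )


@pytest.fixture
def random_graph():
    aln = generate_msa_fixture(
        n_seqs=8, n_columns=25, substitution_rate=0.3, gap_rate=0.15, seed=7
    )
    return aln, build_poa(aln)


@pytest.fixture
def tree_and_aln():
    aln = generate_msa_fixture(n_seqs=6, n_columns=15, seed=5, gap_rate=0.1)
    tree = generate_tree_fixture(aln.ids, seed=5)
    return tree, aln


def random_alignments(count, *, max_seqs=12, max_cols=40, seed0=100,
                      alphabets=("nucleotide", "protein")):
    """Deterministic stream of varied random alignments."""
    import random

    rng = random.Random(seed0)
    for i in range(count):
        yield generate_msa_fixture(
            n_seqs=rng.randint(1, max_seqs),
            n_columns=rng.randint(1, max_cols),
            alphabet=alphabets[i % len(alphabets)],
            substitution_rate=rng.uniform(0.0, 0.6),
            gap_rate=rng.uniform(0.0, 0.3),
            seed=seed0 + i,
        )
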