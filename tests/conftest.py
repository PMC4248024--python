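import numpy as np
import pytest

from nadsel import seqio, synthdata


@pytest.fixture(scope="session")
def small_tree():
    return seqio.PhyloTree.from_newick(synthdata.symmetric_tree_newick(6, 0.2))


@pytest.fixture(scope="session")
def six_taxon_newick():
    return synthdata.symmetric_tree_newick(6, 0.2)


@pytest.fixture(scope="session")
def m0_alignment(small_tree):
    """500-codon alignment evolved under a single omega = 0.3 class."""
    aln, labels = synthdata.simulate_codon_alignment(
        small_tree, kappa=2.0, site_classes=[(0.3, 1.0)], n_codons=500, seed=11
    )
    return aln, labels


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_codon(rng):
    from nadsel.seqio import SENSE_CODONS

    return SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
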