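import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from radpartition.phylo_engine import SubstModel
from radpartition.synth_rad import SimConfig, simulate_loci, simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def jc_model():
    return SubstModel(n_categories=1)


@pytest.fixture(scope="session")
def gtr_model():
    return SubstModel(
        base_freqs=(0.3, 0.2, 0.25, 0.25),
        exchangeabilities=(1.5, 3.0, 0.8, 1.2, 2.5, 1.0),
        alpha=0.7,
        n_categories=3,
    )


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return simulate_tree(8, 0.3, rng_seed=11)


@pytest.fixture(scope="session")
def strong_signal_dataset(eight_taxon_tree):
    """Complete 8-taxon dataset with strong phylogenetic signal."""
    cfg = SimConfig(
        n_taxa=8, n_loci=30, locus_length=70, tree_depth=0.3,
        rng_seed=11, min_individuals=8, model=SubstModel(alpha=1.0),
    )
    truth, loci = simulate_loci(eight_taxon_tree, cfg)
    return truth, loci
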