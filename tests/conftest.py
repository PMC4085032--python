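import numpy as np
import pytest

from decisiphy.synthetic_data import simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quartet_tree():
    from decisiphy.trees_io import parse_newick

    return parse_newick("((a:1,b:1):1,(c:1,d:1):1);")


def random_tree(n_tips, seed, **kwargs):
    return simulate_tree(n_tips, seed=seed, **kwargs)


def random_coverage(n_taxa, n_loci, seed, density=0.5, taxa=None):
    """Random boolean presence matrix as a CoverageMatrix."""
    from decisiphy.coverage_decisiveness import CoverageMatrix

    rng = np.random.default_rng(seed)
    presence = rng.random((n_taxa, n_loci)) < density
    taxa = taxa if taxa is not None else [f"g{i + 1:04d}" for i in range(n_taxa)]
    return CoverageMatrix(taxa, [f"L{j + 1}" for j in range(n_loci)], presence)
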