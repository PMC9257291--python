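import numpy as np
import pytest

from wingcontrast.phylo import read_newick, simulate_yule, vcv_from_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_tree():
    """Three-tip tree with hand-computable shared path lengths."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule(50, 1.0, seed=7)


@pytest.fixture(scope="session")
def vcv50(yule50):
    return vcv_from_tree(yule50, scale=True)
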