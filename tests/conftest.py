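import numpy as np
import pytest
from hypothesis import settings

import diveconv as dc
from diveconv import waterfowl

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def waterfowl_tree():
    return waterfowl.default_tree()


@pytest.fixture(scope="session")
def waterfowl_partition():
    return waterfowl.default_partition()


@pytest.fixture
def toy_tree():
    """Four-tip balanced tree with modest branch lengths."""
    return dc.read_tree_newick("((a:0.05,b:0.05):0.02,(c:0.05,d:0.05):0.02);")


@pytest.fixture
def toy_partition():
    return dc.TaxonPartition(frozenset({"a", "b"}), frozenset({"c", "d"}))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
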