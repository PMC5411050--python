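import pytest

import topophylo as tp


@pytest.fixture(scope="session")
def three_leaf_tree():
    return tp.parse_newick("((A:1,B:1):1,C:1);")


@pytest.fixture(scope="session")
def yule16():
    """The standard 16-OTU fixture: Yule tree, exponential(1) lengths."""
    return tp.yule_tree(tp.TreeGenSpec(kind="yule", n_leaves=16, seed=42))


@pytest.fixture(scope="session")
def yule16_layout(yule16):
    """Converged default layout of the 16-OTU fixture (computed once)."""
    return tp.layout_tree(yule16)
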