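import dendropy
import numpy as np
import pytest


def make_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             rooting="default-rooted", preserve_underscores=True)
    # label internal nodes so oracles and implementation can be keyed together
    i = 0
    for node in tree.postorder_node_iter():
        if node.child_nodes() and node.label is None:
            node.label = f"node{i}"
            i += 1
    return tree


@pytest.fixture
def five_tip_tree() -> dendropy.Tree:
    return make_tree("((A:0.3,B:0.5):0.2,(C:0.4,(D:0.1,E:0.6):0.3):0.1);")


@pytest.fixture
def eight_tip_tree() -> dendropy.Tree:
    return make_tree(
        "(((A:0.2,B:0.4):0.3,(C:0.5,D:0.1):0.2):0.3,"
        "((E:0.6,F:0.2):0.4,(G:0.3,H:0.5):0.1):0.2);"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231101)
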