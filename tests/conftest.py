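import numpy as np
import pytest

import stageshift as ss


@pytest.fixture
def small_tree():
    """Three-tip tree with total branch length 5."""
    return ss.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_community():
    return ss.LifeStageCommunity(
        islands=["a", "b", "c"],
        species=["x", "y", "z", "w"],
        abundance=np.array([[3, 0, 2, 0], [0, 1, 0, 4], [5, 2, 0, 0]]),
        stage="sapling",
    )


def brute_force_pd(tree, species):
    """Independent Faith-PD oracle: union of edges on root-to-tip paths.

    Walks the dendropy node structure directly, which shares no code with
    the edge-incidence index used by the implementation.
    """
    species = set(species)
    edges = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in species:
            continue
        node = leaf
        while node.parent_node is not None:
            edges[id(node.edge)] = node.edge.length or 0.0
            node = node.parent_node
    return sum(edges.values()) + (tree.seed_node.edge.length or 0.0)
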