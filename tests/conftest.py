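import numpy as np
import pytest

from ecoassembly import CountTable
from ecoassembly.io import read_tree

CHERRY_NEWICK = "(A:1,B:1);"
BALANCED_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def cherry_tree():
    return read_tree(CHERRY_NEWICK)


@pytest.fixture
def balanced_tree():
    """Four-tip balanced tree: d(A,B)=d(C,D)=2, cross-clade distances 4."""
    return read_tree(BALANCED_NEWICK)


@pytest.fixture
def small_table():
    return CountTable(
        ["s1", "s2", "s3"],
        ["A", "B", "C", "D"],
        np.array([[5, 5, 0, 0], [0, 0, 5, 5], [2, 2, 2, 2]]),
    )


def brute_force_tip_distances(tree):
    """Independent cophenetic oracle: path lengths via parent traversal."""
    leaves = list(tree.leaf_node_iter())
    paths = {}
    for leaf in leaves:
        path = {}
        node, dist = leaf, 0.0
        while node is not None:
            path[id(node)] = dist
            dist += node.edge.length or 0.0
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = [l.taxon.label for l in leaves]
    nodes_by_leaf = {l.taxon.label: l for l in leaves}
    out = {}
    for a in labels:
        for b in labels:
            if a == b:
                out[(a, b)] = 0.0
                continue
            # find deepest shared ancestor by walking up from b
            node = nodes_by_leaf[b]
            dist_b = 0.0
            while id(node) not in paths[a]:
                dist_b += node.edge.length or 0.0
                node = node.parent_node
            out[(a, b)] = paths[a][id(node)] + dist_b
    return labels, out


def brute_force_bmntd(abund_a, abund_b, tree, taxon_ids, weighted=True):
    """Independent betaMNTD oracle enumerating tip distances from the tree."""
    labels, dists = brute_force_tip_distances(tree)
    present_a = [i for i, x in enumerate(abund_a) if x > 0]
    present_b = [i for i, x in enumerate(abund_b) if x > 0]
    total_a = sum(abund_a[i] for i in present_a)
    total_b = sum(abund_b[i] for i in present_b)
    term_a = 0.0
    for i in present_a:
        nearest = min(dists[(taxon_ids[i], taxon_ids[j])] for j in present_b)
        f = abund_a[i] / total_a if weighted else 1.0 / len(present_a)
        term_a += f * nearest
    term_b = 0.0
    for j in present_b:
        nearest = min(dists[(taxon_ids[j], taxon_ids[i])] for i in present_a)
        f = abund_b[j] / total_b if weighted else 1.0 / len(present_b)
        term_b += f * nearest
    return 0.5 * (term_a + term_b)
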