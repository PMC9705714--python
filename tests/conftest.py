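import io

import numpy as np
import pytest
from skbio import TreeNode

from assemblage.data_model import OtuTable


@pytest.fixture
def toy_tree() -> TreeNode:
    """Three-tip tree: ((A:1,B:1):1,C:2); root-to-tip depth 2 everywhere."""
    return TreeNode.read(io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def toy_table() -> OtuTable:
    return OtuTable(["A", "B", "C"], ["s1", "s2"],
                    np.array([[5, 0], [3, 7], [0, 2]]))


def random_table_and_tree(rng, n_taxa, n_samples, max_count=50):
    """Random small instance for oracle comparisons."""
    tree = random_tree(rng, n_taxa)
    taxa = sorted(t.name for t in tree.tips())
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    # guarantee no empty sample
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1
    ids = [f"s{j}" for j in range(n_samples)]
    return OtuTable(taxa, ids, counts), tree


def random_tree(rng, n_taxa) -> TreeNode:
    """Random binary tree with uniform random branch lengths."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 2.0)))
             for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
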