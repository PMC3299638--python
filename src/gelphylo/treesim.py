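"""Random tree generation for testing tree reconstruction.

Two generators: arbitrary binary trees with independent branch lengths
(whose path-length matrices are additive, the regime where Neighbor
Joining is exact) and clock trees with synchronized leaf depths (whose
path-length matrices are ultrametric, the regime where UPGMA is exact).
Path-length matrices are computed directly on the generated tree, giving
an oracle independent of any reconstruction code.
"""

from __future__ import annotations

import numpy as np

from .phylogeny import PhyloTree, TreeNode, patristic_distances


def random_binary_tree(n_leaves: int, rng: np.random.Generator,
                       length_range: tuple[float, float] = (0.5, 5.0),
                       labels: list[str] | None = None) -> PhyloTree:
    """Random rooted binary tree with i.i.d. uniform branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = labels or [f"t{k}" for k in range(n_leaves)]
    lo, hi = length_range
    nodes = [TreeNode(name=lb, length=float(rng.uniform(lo, hi))) for lb in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(lo, hi)),
                          children=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    return PhyloTree(root=TreeNode(children=nodes))


def random_clock_tree(n_leaves: int, rng: np.random.Generator,
                      labels: list[str] | None = None) -> PhyloTree:
    """Random ultrametric (molecular-clock) tree.

    Clusters merge in random pairs at strictly increasing heights, so every
    leaf sits at the same depth and all merge heights are distinct (no ties
    for reconstruction to disambiguate).
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    labels = labels or [f"t{k}" for k in range(n_leaves)]
    items: list[tuple[TreeNode, float]] = [(TreeNode(name=lb), 0.0) for lb in labels]
    height = 0.0
    while len(items) > 1:
        height += float(rng.uniform(0.5, 2.0))
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        (na, ha), (nb, hb) = items[i], items[j]
        na.length, nb.length = height - ha, height - hb
        merged = (TreeNode(children=[na, nb]), height)
        items = [items[k] for k in range(len(items)) if k not in (i, j)] + [merged]
    return PhyloTree(root=items[0][0])


def tree_distance_matrix(tree: PhyloTree) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix of a tree, with its label order."""
    labels = sorted(tree.leaf_names())
    return patristic_distances(tree, labels), labels
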