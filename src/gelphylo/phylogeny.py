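"""Distance-based phylogenetic tree construction and serialization.

Five methods operate on a symmetric zero-diagonal distance matrix:

* Neighbor Joining (Saitou-Nei, Studier-Keppler Q-criterion): recovers the
  generating tree exactly on additive matrices; returns an unrooted tree
  serialized at its final 3-way anchor. Negative branch lengths are kept
  as computed (Phylip's behaviour).
* UPGMA / WPGMA / single / complete linkage: agglomerative, producing
  rooted ultrametric trees; a merge at distance d places the new node at
  height d/2, and a child's branch length is the height difference to its
  parent.

Ties (several pairs at the minimal criterion) are broken by the smallest
index pair, making every method deterministic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from Bio import Phylo

from .errors import LabelError, MatrixError, ParseError

METHODS = ("nj", "upgma", "wpgma", "single", "complete")


@dataclass
class TreeNode:
    """A tree node; ``length`` is the branch length to the parent (None at root)."""

    name: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """A phylogenetic tree with labeled leaves and real-valued branch lengths.

    Agglomerative trees are rooted and binary; NJ trees are unrooted and
    anchored at a (usually) trifurcating internal node for serialization.
    """

    root: TreeNode

    def __post_init__(self):
        names = self.leaf_names()
        if len(set(names)) != len(names) or any(not n for n in names):
            raise LabelError("leaf labels must be unique and non-empty")

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (branch lengths summed; None counts as 0)."""
        depths: dict[str, float] = {}

        def rec(node: TreeNode, acc: float) -> None:
            acc += node.length or 0.0
            if node.is_leaf:
                depths[node.name] = acc
            for child in node.children:
                rec(child, acc)

        rec(self.root, 0.0)
        return depths

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.leaf_depths().values())
        return max(depths) - min(depths) <= tol


def _check_matrix(D: np.ndarray, n_labels: int) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise MatrixError(f"distance matrix must be square, got shape {D.shape}")
    if D.shape[0] != n_labels:
        raise MatrixError(f"{n_labels} labels for a {D.shape[0]}x{D.shape[0]} matrix")
    if D.shape[0] < 2:
        raise MatrixError("need at least 2 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise MatrixError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise MatrixError("distance matrix must have a zero diagonal")
    return D


def _argmin_pair(M: np.ndarray) -> tuple[int, int]:
    """Lexicographically smallest (i, j), i < j, minimizing M over the strict
    upper triangle."""
    n = M.shape[0]
    masked = M.copy()
    masked[np.tril_indices(n)] = np.inf
    flat = int(np.argmin(masked))
    return flat // n, flat % n


def neighbor_joining(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor Joining on a symmetric zero-diagonal distance matrix.

    Iteratively joins the pair (i, j) minimizing the Studier-Keppler
    criterion Q(i,j) = (n-2) d(i,j) - r_i - r_j, assigns limb lengths from
    the divergences, and reduces the matrix, finishing with a 3-way anchor
    (or a single edge for two taxa). On an additive matrix the leaf-to-leaf
    path lengths of the result equal the input distances exactly.
    """
    D = _check_matrix(D, len(labels)).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(lb)) for lb in labels]

    if len(nodes) == 2:
        a, b = nodes
        a.length, b.length = float(D[0, 1]), 0.0
        return PhyloTree(root=TreeNode(children=[a, b]))

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        i, j = _argmin_pair(Q)
        limb_i = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        limb_j = D[i, j] - limb_i
        nodes[i].length, nodes[j].length = float(limb_i), float(limb_j)
        joined = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)], new_row[keep]]),
                       np.append(new_row[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [joined]

    a, b, c = nodes
    a.length = float(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    b.length = float(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    c.length = float(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    return PhyloTree(root=TreeNode(children=[a, b, c]))


def agglomerate(D: np.ndarray, labels: list[str], method: str) -> PhyloTree:
    """Agglomerative tree building: upgma, wpgma, single, or complete linkage.

    Repeatedly merges the closest pair of clusters at height d/2; the
    distance from the merged cluster A+B to any other cluster X is updated
    by the method's rule (size-weighted mean, simple mean, min, or max).
    """
    if method not in ("upgma", "wpgma", "single", "complete"):
        raise ValueError(f"unknown agglomerative method '{method}'; "
                         f"choose from upgma, wpgma, single, complete")
    D = _check_matrix(D, len(labels)).copy()
    nodes = [TreeNode(name=str(lb)) for lb in labels]
    sizes = [1] * len(nodes)
    heights = [0.0] * len(nodes)

    while len(nodes) > 1:
        i, j = _argmin_pair(D)
        h = 0.5 * D[i, j]
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        merged = TreeNode(children=[nodes[i], nodes[j]])

        di, dj = D[i, :], D[j, :]
        if method == "upgma":
            new_row = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        elif method == "wpgma":
            new_row = 0.5 * (di + dj)
        elif method == "single":
            new_row = np.minimum(di, dj)
        else:
            new_row = np.maximum(di, dj)

        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        D = np.vstack([np.column_stack([D[np.ix_(keep, keep)], new_row[keep]]),
                       np.append(new_row[keep], 0.0)])
        nodes = [nodes[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]
        heights = [heights[k] for k in keep] + [h]

    return PhyloTree(root=nodes[0])


def build_tree(D: np.ndarray, labels: list[str], method: str) -> PhyloTree:
    """Dispatch to :func:`neighbor_joining` or :func:`agglomerate`."""
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; choose from {METHODS}")
    if method == "nj":
        return neighbor_joining(D, labels)
    return agglomerate(D, labels, method)


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize as Newick with branch lengths at ``precision`` significant digits."""

    def fmt(node: TreeNode) -> str:
        body = (node.name or "") if node.is_leaf else \
            "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            body += f":{node.length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`."""
    try:
        clade_tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as exc:
        raise ParseError(f"malformed Newick: {exc}") from exc

    def convert(clade) -> TreeNode:
        return TreeNode(name=clade.name,
                        length=None if clade.branch_length is None
                        else float(clade.branch_length),
                        children=[convert(c) for c in clade.clades])

    root = convert(clade_tree.root)
    return PhyloTree(root=root)  # PhyloTree validates label uniqueness


def relabel(tree: PhyloTree, mapping: dict[str, str]) -> PhyloTree:
    """Rename leaves through ``mapping``; topology and lengths untouched."""
    current = set(tree.leaf_names())
    unknown = set(mapping) - current
    if unknown:
        raise LabelError(f"labels not in tree: {sorted(unknown)}")
    new_names = [mapping.get(n, n) for n in tree.leaf_names()]
    if len(set(new_names)) != len(new_names):
        raise LabelError("relabeling would create duplicate leaf names")

    def copy(node: TreeNode) -> TreeNode:
        name = mapping.get(node.name, node.name) if node.is_leaf else node.name
        return TreeNode(name=name, length=node.length,
                        children=[copy(c) for c in node.children])

    return PhyloTree(root=copy(tree.root))


def render_ascii(tree: PhyloTree) -> str:
    """Deterministic indented text rendering with branch lengths."""
    lines: list[str] = []

    def rec(node: TreeNode, prefix: str, is_last: bool, is_root: bool) -> None:
        label = node.name if node.is_leaf else "+"
        blen = "" if node.length is None else f":{node.length:.6g}"
        if is_root:
            lines.append(f"{label}{blen}")
            child_prefix = ""
        else:
            connector = "`-- " if is_last else "|-- "
            lines.append(f"{prefix}{connector}{label}{blen}")
            child_prefix = prefix + ("    " if is_last else "|   ")
        for k, child in enumerate(node.children):
            rec(child, child_prefix, k == len(node.children) - 1, False)

    rec(tree.root, "", True, True)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tree comparison utilities (patristic distances, bipartitions, RF distance)

def patristic_distances(tree: PhyloTree, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``labels``."""
    index = {name: k for k, name in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def rec(node: TreeNode) -> dict[int, float]:
        """Map leaf index -> distance from this node (below it)."""
        if node.is_leaf:
            return {index[node.name]: 0.0}
        below: dict[int, float] = {}
        child_maps = []
        for child in node.children:
            cmap = {leaf: d + (child.length or 0.0)
                    for leaf, d in rec(child).items()}
            child_maps.append(cmap)
        for a in range(len(child_maps)):
            for b in range(a + 1, len(child_maps)):
                for la, da in child_maps[a].items():
                    for lb, db in child_maps[b].items():
                        D[la, lb] = D[lb, la] = da + db
            below.update(child_maps[a])
        return below

    rec(tree.root)
    return D


def bipartitions(tree: PhyloTree) -> dict[frozenset[str], float]:
    """Internal-edge bipartitions (as the smaller-side leaf set is ambiguous,
    each split is keyed by the leaf set on the child side, normalized to the
    lexicographically smaller of the two complementary sets) with branch lengths.

    Trivial splits (single leaf / all leaves) are excluded, so the keys are
    exactly the internal edges — the standard input to the Robinson-Foulds
    comparison of unrooted topologies.
    """
    all_leaves = frozenset(tree.leaf_names())
    splits: dict[frozenset[str], float] = {}

    def rec(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(rec(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            key = min(below, other, key=lambda s: sorted(s))
            length = node.length or 0.0
            # a rooted binary tree encodes the root split on both root edges
            splits[key] = splits.get(key, 0.0) + length
        return below

    for child in tree.root.children:
        rec(child)
    return splits


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance: size of the symmetric difference of
    the two trees' internal-edge bipartition sets."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise MatrixError("trees must share the same leaf set")
    s1, s2 = set(bipartitions(t1)), set(bipartitions(t2))
    return len(s1 ^ s2)
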