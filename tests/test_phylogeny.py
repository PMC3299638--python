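import io as _io

import numpy as np
import pytest

from gelphylo.errors import LabelError, MatrixError, ParseError
from gelphylo.phylogeny import (METHODS, agglomerate, bipartitions, build_tree,
                                neighbor_joining, patristic_distances, read_newick,
                                relabel, render_ascii, rf_distance, write_newick)
from gelphylo.treesim import (random_binary_tree, random_clock_tree,
                              tree_distance_matrix)


def random_symmetric(rng, n, lo=1.0, hi=10.0):
    A = rng.uniform(lo, hi, size=(n, n))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    return D


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        tree = neighbor_joining(np.array([[0.0, 8.0], [8.0, 0.0]]), ["a", "b"])
        depths = tree.leaf_depths()
        assert depths["a"] + depths["b"] == pytest.approx(8.0)
        assert write_newick(tree) == "(a:8,b:0);"

    def test_three_taxon_closed_form(self, rng):
        for _ in range(20):
            D = random_symmetric(rng, 3)
            tree = neighbor_joining(D, ["a", "b", "c"])
            lengths = {n.name: n.length for n in tree.root.children}
            assert lengths["a"] == pytest.approx((D[0, 1] + D[0, 2] - D[1, 2]) / 2)
            assert lengths["b"] == pytest.approx((D[0, 1] + D[1, 2] - D[0, 2]) / 2)
            assert lengths["c"] == pytest.approx((D[0, 2] + D[1, 2] - D[0, 1]) / 2)

    def test_additive_recovery(self, rng):
        # oracle: path distances of a random tree; NJ must reproduce both
        # the topology and every pairwise path length
        for _ in range(30):
            n = int(rng.integers(4, 13))
            truth = random_binary_tree(n, rng)
            D, labels = tree_distance_matrix(truth)
            tree = neighbor_joining(D, labels)
            assert rf_distance(truth, tree) == 0
            assert np.abs(patristic_distances(tree, labels) - D).max() < 1e-9

    def test_invalid_matrices(self):
        with pytest.raises(MatrixError):
            neighbor_joining(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(MatrixError):
            neighbor_joining(np.array([[1.0, 2.0], [2.0, 1.0]]), ["a", "b"])
        with pytest.raises(MatrixError):
            neighbor_joining(np.zeros((3, 3)), ["a", "b"])

    def test_taxon_order_invariance(self, rng):
        truth = random_binary_tree(7, rng)
        D, labels = tree_distance_matrix(truth)
        perm = rng.permutation(len(labels))
        tree_a = neighbor_joining(D, labels)
        tree_b = neighbor_joining(D[np.ix_(perm, perm)], [labels[k] for k in perm])
        assert rf_distance(tree_a, tree_b) == 0
        assert np.allclose(patristic_distances(tree_a, labels),
                           patristic_distances(tree_b, labels))

    def test_reference_implementation_agreement(self, rng):
        # independent reference: scikit-bio's NJ (negative branches kept)
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        for _ in range(10):
            n = int(rng.integers(4, 10))
            D = random_symmetric(rng, n)
            labels = [f"t{k}" for k in range(n)]
            mine = neighbor_joining(D, labels)
            buf = _io.StringIO()
            skbio_nj(DistanceMatrix(D, ids=labels), neg_as_zero=False).write(
                buf, format="newick")
            ref = read_newick(buf.getvalue())
            assert rf_distance(mine, ref) == 0
            assert np.abs(patristic_distances(mine, labels)
                          - patristic_distances(ref, labels)).max() < 1e-6


class TestAgglomerative:
    def test_two_taxa_root_at_half_distance(self):
        for method in ("upgma", "wpgma", "single", "complete"):
            tree = agglomerate(np.array([[0.0, 8.0], [8.0, 0.0]]), ["a", "b"], method)
            assert tree.leaf_depths() == {"a": pytest.approx(4.0),
                                          "b": pytest.approx(4.0)}

    def test_three_taxa_hand_case(self):
        # d(a,b)=2, d(a,c)=d(b,c)=8: all methods join (a,b) at height 1,
        # then merge c at 8 (root height 4) since d(a,c)=d(b,c)
        D = np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]])
        for method in ("upgma", "wpgma", "single", "complete"):
            tree = agglomerate(D, ["a", "b", "c"], method)
            depths = tree.leaf_depths()
            assert depths == {"a": pytest.approx(4.0), "b": pytest.approx(4.0),
                              "c": pytest.approx(4.0)}
            ab = next(c for c in tree.root.children if not c.is_leaf)
            assert sorted(n.name for n in ab.children) == ["a", "b"]
            assert all(ch.length == pytest.approx(1.0) for ch in ab.children)

    def test_upgma_reconstructs_clock_trees(self, rng):
        for _ in range(30):
            truth = random_clock_tree(int(rng.integers(4, 13)), rng)
            D, labels = tree_distance_matrix(truth)
            tree = agglomerate(D, labels, "upgma")
            assert rf_distance(truth, tree) == 0
            assert np.abs(patristic_distances(tree, labels) - D).max() < 1e-9

    @pytest.mark.parametrize("method", ["upgma", "wpgma", "single", "complete"])
    def test_ultrametric_output(self, rng, method):
        for _ in range(10):
            D = random_symmetric(rng, int(rng.integers(4, 10)))
            tree = agglomerate(D, [f"t{k}" for k in range(len(D))], method)
            assert tree.is_ultrametric(tol=1e-9)
            # heights non-negative toward the root: no negative branch lengths
            assert all(n.length >= -1e-12 for n in tree.root.walk()
                       if n is not tree.root)

    def test_upgma_equals_wpgma_on_balanced_merges(self):
        # two well-separated pairs: every merge joins equal-size clusters,
        # where the weighted and unweighted updates coincide
        D = np.array([
            [0.0, 2.0, 10.0, 12.0],
            [2.0, 0.0, 12.0, 10.0],
            [10.0, 12.0, 0.0, 2.0],
            [12.0, 10.0, 2.0, 0.0]])
        labels = ["a", "b", "c", "d"]
        up = agglomerate(D, labels, "upgma")
        wp = agglomerate(D, labels, "wpgma")
        assert rf_distance(up, wp) == 0
        assert np.allclose(patristic_distances(up, labels),
                           patristic_distances(wp, labels))

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            agglomerate(np.zeros((2, 2)), ["a", "b"], "nj")


class TestNewick:
    def test_round_trip_random_tree(self, rng):
        tree = random_binary_tree(10, rng)
        text = write_newick(tree, precision=12)
        back = read_newick(text)
        labels = sorted(tree.leaf_names())
        assert rf_distance(tree, back) == 0
        assert np.abs(patristic_distances(tree, labels)
                      - patristic_distances(back, labels)).max() < 1e-6

    def test_three_leaf_parse(self):
        tree = read_newick("((a:1,b:1):2,c:3);")
        assert sorted(tree.leaf_names()) == ["a", "b", "c"]
        assert tree.leaf_depths() == {"a": pytest.approx(3.0),
                                      "b": pytest.approx(3.0),
                                      "c": pytest.approx(3.0)}

    def test_terminator_and_default_precision(self, rng):
        tree = random_binary_tree(5, rng)
        text = write_newick(tree)
        assert text.endswith(";")
        assert rf_distance(read_newick(text), tree) == 0

    def test_malformed_input(self):
        with pytest.raises(ParseError):
            read_newick("((a:1,b:1:2,c:3);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(LabelError):
            read_newick("((a:1,a:1):2,c:3);")


class TestRelabelRender:
    def test_identity_and_involution(self, rng):
        tree = random_binary_tree(6, rng)
        labels = sorted(tree.leaf_names())
        same = relabel(tree, {})
        assert rf_distance(tree, same) == 0
        swap = {labels[0]: labels[1], labels[1]: labels[0]}
        twice = relabel(relabel(tree, swap), swap)
        assert rf_distance(tree, twice) == 0
        assert np.allclose(patristic_distances(tree, labels),
                           patristic_distances(twice, labels))

    def test_collision_rejected(self, rng):
        tree = random_binary_tree(4, rng)
        a, b = sorted(tree.leaf_names())[:2]
        with pytest.raises(LabelError):
            relabel(tree, {a: "x", b: "x"})

    def test_unknown_label_rejected(self, rng):
        tree = random_binary_tree(4, rng)
        with pytest.raises(LabelError):
            relabel(tree, {"nope": "x"})

    def test_render_ascii_deterministic_and_complete(self, rng):
        tree = random_binary_tree(7, rng)
        text = render_ascii(tree)
        assert text == render_ascii(tree)
        for name in tree.leaf_names():
            assert name in text

    def test_render_two_leaves(self):
        tree = neighbor_joining(np.array([[0.0, 4.0], [4.0, 0.0]]), ["a", "b"])
        text = render_ascii(tree)
        assert "a" in text and "b" in text


class TestBuildTreeDispatch:
    @pytest.mark.parametrize("method", METHODS)
    def test_all_methods_run(self, rng, method):
        D = random_symmetric(rng, 6)
        tree = build_tree(D, [f"t{k}" for k in range(6)], method)
        assert sorted(tree.leaf_names()) == [f"t{k}" for k in range(6)]

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            build_tree(np.zeros((2, 2)), ["a", "b"], "parsimony")
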