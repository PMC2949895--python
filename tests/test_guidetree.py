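import numpy as np
import pytest

from paralign import nj_tree, sequence_weights, store_create, write_newick
from paralign.diststore import IncompleteMatrixError, iter_pairs
from paralign.guidetree import GuideTree, checkpoint_tree
from paralign.io_formats import Clade, read_newick

from tests._oracles import (
    distance_matrix_from_tree,
    random_binary_tree,
    tree_path_distances,
    unrooted_splits,
)


def store_from_matrix(D):
    N = D.shape[0]
    store = store_create(N)
    for _, i, j in iter_pairs(N):
        store.put(i, j, float(D[i, j]))
    return store


class TestNjTree:
    def test_two_leaves_split_evenly(self):
        store = store_create(2)
        store.put(0, 1, 0.4)
        tree = nj_tree(store, ids=["a", "b"])
        (c1, c2) = tree.root.children
        assert {c1.name, c2.name} == {"a", "b"}
        assert c1.length == c2.length == pytest.approx(0.2)

    def test_additive_four_taxon_recovery(self):
        # caterpillar ((A,B),(C,D)) with known branch lengths
        A = Clade(name="A", length=0.2)
        B = Clade(name="B", length=0.3)
        C = Clade(name="C", length=0.25)
        D = Clade(name="D", length=0.15)
        left = Clade(children=[A, B], length=0.1)
        right = Clade(children=[C, D], length=0.1)
        true = Clade(children=[left, right])
        ids = ["A", "B", "C", "D"]
        tree = nj_tree(store_from_matrix(distance_matrix_from_tree(true, ids) / 2), ids)
        assert unrooted_splits(tree.root) == unrooted_splits(true)
        # additive input: all leaf-to-leaf path lengths reproduced exactly
        recovered = tree_path_distances(tree.root)
        expected = tree_path_distances(true)
        for key in expected:
            assert recovered[key] == pytest.approx(expected[key] / 2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_eight_taxon_topology_recovery(self, seed):
        rng = np.random.default_rng(seed)
        true = random_binary_tree(8, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        tree = nj_tree(store_from_matrix(D / D.max()), ids)
        assert unrooted_splits(tree.root) == unrooted_splits(true)

    def test_incomplete_store_is_an_error(self):
        store = store_create(4)
        store.put(0, 1, 0.5)
        with pytest.raises(IncompleteMatrixError):
            nj_tree(store)

    def test_topology_invariant_to_input_order(self, rng):
        true = random_binary_tree(7, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        base = nj_tree(store_from_matrix(D / D.max()), ids)
        perm = rng.permutation(len(ids))
        Dp = D[np.ix_(perm, perm)]
        permuted = nj_tree(store_from_matrix(Dp / Dp.max()), [ids[k] for k in perm])
        assert unrooted_splits(permuted.root) == unrooted_splits(base.root)

    def test_child_leaf_counts_sum_to_parent(self, rng):
        true = random_binary_tree(9, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        tree = nj_tree(store_from_matrix(D / D.max()), ids)

        def check(node):
            if node.is_leaf:
                return 1
            counts = [check(ch) for ch in node.children]
            assert sum(counts) == len(node.leaves())
            return sum(counts)

        check(tree.root)

    def test_branch_lengths_never_negative(self, rng):
        # noisy, non-additive distances provoke negative NJ estimates
        N = 10
        D = rng.uniform(0.05, 1.0, size=(N, N))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(store_from_matrix(D / D.max()))
        tree.validate()  # validates lengths >= 0 everywhere

    def test_agrees_with_scikit_bio_on_additive_matrix(self, rng):
        """Independent NJ implementation recovers the same topology."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        true = random_binary_tree(8, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        ours = nj_tree(store_from_matrix(D / D.max()), ids)
        sk_tree = skbio_nj(DistanceMatrix(D, ids))
        sk_root = read_newick(str(sk_tree))
        assert unrooted_splits(sk_root) == unrooted_splits(ours.root)


class TestSequenceWeights:
    def make_tree(self, root):
        # wrap a hand-built clade; bypass validate (test scaffolding only)
        return GuideTree(root=root)

    def test_symmetric_tree_gives_equal_weights(self):
        kids = [Clade(name=n, length=0.5) for n in "abcd"]
        root = Clade(children=[
            Clade(children=kids[:2], length=0.2),
            Clade(children=kids[2:], length=0.2),
        ])
        w = sequence_weights(self.make_tree(root))
        assert set(w.values()) == {1.0}

    def test_caterpillar_hand_computed(self):
        # root -> (a:0.4, inner:0.2 -> (b:0.3, c:0.1))
        inner = Clade(children=[Clade(name="b", length=0.3),
                                Clade(name="c", length=0.1)], length=0.2)
        root = Clade(children=[Clade(name="a", length=0.4), inner])
        w = sequence_weights(self.make_tree(root))
        # raw sums: a = 0.4; b = 0.2/2 + 0.3 = 0.4; c = 0.2/2 + 0.1 = 0.2
        assert w["a"] == pytest.approx(1.0)
        assert w["b"] == pytest.approx(1.0)
        assert w["c"] == pytest.approx(0.5)

    def test_zero_length_tree_gives_uniform_weights(self):
        root = Clade(children=[Clade(name="a", length=0.0),
                               Clade(name="b", length=0.0)])
        assert sequence_weights(self.make_tree(root)) == {"a": 1.0, "b": 1.0}

    def test_weights_positive_and_max_normalized(self, rng):
        true = random_binary_tree(12, rng)
        w = sequence_weights(self.make_tree(true))
        assert max(w.values()) == 1.0 and min(w.values()) > 0


class TestCheckpoints:
    def test_snapshot_count_is_joins(self, rng, tmp_path):
        true = random_binary_tree(4, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        nj_tree(store_from_matrix(D / D.max()), ids, checkpoint_dir=tmp_path)
        assert len(sorted(tmp_path.glob("tree-*.nwk"))) == 3  # N-1 joins

    def test_final_snapshot_equals_returned_tree(self, rng, tmp_path):
        true = random_binary_tree(6, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        tree = nj_tree(store_from_matrix(D / D.max()), ids, checkpoint_dir=tmp_path)
        last = sorted(tmp_path.glob("tree-*.nwk"))[-1]
        assert last.read_text() == write_newick(tree)

    def test_disabled_checkpointing_writes_nothing(self, rng, tmp_path):
        true = random_binary_tree(4, rng)
        ids = sorted(true.leaf_names())
        D = distance_matrix_from_tree(true, ids)
        nj_tree(store_from_matrix(D / D.max()), ids, checkpoint_dir=None)
        assert list(tmp_path.iterdir()) == []

    def test_checkpoint_tree_suffix_convention(self, tmp_path):
        tree = Clade(children=[Clade(name="x", length=1.0), Clade(name="y", length=1.0)])
        path = checkpoint_tree(tree, tmp_path, 7)
        assert path.name == "tree-000000007.nwk" and path.exists()
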