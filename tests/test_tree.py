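import numpy as np
import pytest

from conftest import random_binary_newick
from spamplace.tree import ReferenceTree, TreeError


def _edge_pairs(tree):
    """(parent_index, child_index) per edge number, for oracle graphs."""
    return {
        no: (tree.edge_child(no).parent.index, tree.edge_child(no).index)
        for no in tree.edge_numbers()
    }


class TestParsing:
    def test_counts(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        assert t.n_edges == 4  # 3 pendant + 1 internal
        assert t.leaf_labels == ["A", "B", "C"]

    def test_deterministic_numbering(self, toy_tree_newick):
        a = ReferenceTree.from_newick(toy_tree_newick)
        b = ReferenceTree.from_newick(toy_tree_newick)
        assert a.to_newick(edge_numbers=True) == b.to_newick(edge_numbers=True)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            ReferenceTree.from_newick("((A:1,A:1):1,C:2);")

    def test_unrooted_trifurcation_accepted(self):
        t = ReferenceTree.from_newick("(A:1,B:1,C:1);")
        assert len(t.root.children) == 3
        assert t.n_edges == 3

    def test_newick_round_trip(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            nwk = random_binary_newick(rng, int(rng.integers(4, 12)))
            t1 = ReferenceTree.from_newick(nwk)
            t2 = ReferenceTree.from_newick(t1.to_newick())
            assert t1.to_newick() == t2.to_newick()
            assert abs(t1.total_edge_length() - t2.total_edge_length()) < 1e-9


class TestLca:
    def test_siblings_and_identity(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        assert t.lca("A", "B") is t.leaf("A").parent
        assert t.lca("A", "C") is t.root
        assert t.lca("C", "C") is t.leaf("C")

    def test_unknown_label(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        with pytest.raises(TreeError):
            t.lca("A", "Z")

    def test_agrees_with_path_set_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            t = ReferenceTree.from_newick(random_binary_newick(rng, 10))
            labels = t.leaf_labels
            a, b = rng.choice(labels, size=2, replace=False)

            def root_path(label):
                out = []
                n = t.leaf(label)
                while n is not None:
                    out.append(n.index)
                    n = n.parent
                return out

            shared = set(root_path(a)) & set(root_path(b))
            # deepest shared ancestor = first shared node on either root path
            want = next(i for i in root_path(a) if i in shared)
            assert t.lca(a, b).index == want


class TestParentEdge:
    def test_cases(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        leaf_c = t.leaf("C")
        e = t.parent_edge(leaf_c)
        assert t.edge_length(e) == 2.0
        internal = t.lca("A", "B")
        assert t.parent_edge(internal).child == internal.index
        assert t.parent_edge(t.root) is None


class TestNodeDistance:
    def test_conventions(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        ea = t.parent_edge(t.leaf("A"))
        eb = t.parent_edge(t.leaf("B"))
        assert t.node_distance(ea, ea) == 0
        assert t.node_distance(ea, eb) == 1  # cherry: one shared parent node

    def test_agrees_with_line_graph_bfs(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(23)
        for _ in range(4):
            t = ReferenceTree.from_newick(random_binary_newick(rng, 9))
            g = nx.Graph()
            for no, (u, v) in _edge_pairs(t).items():
                g.add_edge(u, v, number=no)
            lg = nx.line_graph(g)
            relabel = {
                frozenset(e): g.edges[e]["number"] for e in g.edges
            }
            nums = t.edge_numbers()
            for _ in range(10):
                e1, e2 = rng.choice(nums, size=2, replace=True)
                if e1 == e2:
                    assert t.node_distance(int(e1), int(e2)) == 0
                    continue
                n1 = next(e for e in lg.nodes if relabel[frozenset(e)] == e1)
                n2 = next(e for e in lg.nodes if relabel[frozenset(e)] == e2)
                want = nx.shortest_path_length(lg, n1, n2)
                assert t.node_distance(int(e1), int(e2)) == want

    def test_metric_properties(self):
        rng = np.random.default_rng(29)
        t = ReferenceTree.from_newick(random_binary_newick(rng, 8))
        nums = t.edge_numbers()
        for _ in range(25):
            a, b, c = rng.choice(nums, size=3)
            dab = t.node_distance(int(a), int(b))
            assert dab == t.node_distance(int(b), int(a))
            assert dab <= t.node_distance(int(a), int(c)) + t.node_distance(int(c), int(b)) + 1


class TestInsert:
    def test_length_conservation_and_bookkeeping(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        before_total = t.total_edge_length()
        e = t.parent_edge(t.leaf("C"))
        t2 = t.insert_query_edge(e, split=0.5, pendant=0.3, label="Q")
        assert t2.n_leaves == t.n_leaves + 1
        assert t2.n_edges == t.n_edges + 2
        assert t2.total_edge_length() == pytest.approx(before_total + 0.3, abs=1e-12)
        # both halves of the split edge are length 1 (original length 2)
        assert t2.edge_length(e.number) == pytest.approx(1.0)

    def test_untouched_edge_numbers_preserved(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        e = t.parent_edge(t.leaf("C"))
        t2 = t.insert_query_edge(e, 0.25, 0.1, "Q")
        for no in t.edge_numbers():
            if no == e.number:
                continue
            assert t2.edge_child(no).label == t.edge_child(no).label

    def test_split_arithmetic(self):
        rng = np.random.default_rng(31)
        t = ReferenceTree.from_newick(random_binary_newick(rng, 6))
        for no in t.edge_numbers():
            split = float(rng.uniform(0, 1))
            L = t.edge_length(no)
            t2 = t.insert_query_edge(no, split, 0.05, "Q")
            lower = t2.edge_length(no)
            assert lower == pytest.approx(split * L, abs=1e-12)

    def test_label_collision(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        with pytest.raises(TreeError, match="already present"):
            t.insert_query_edge(t.parent_edge(t.leaf("C")), 0.5, 0.0, "A")


class TestPrune:
    def test_merged_edge_identified(self, balanced8_newick):
        t = ReferenceTree.from_newick(balanced8_newick)
        pruned, true_edges = t.prune_leaf("A")
        assert pruned.n_leaves == 7
        assert len(true_edges) == 1
        # merged edge: B's pendant edge absorbed the suppressed node,
        # length 0.05 + 0.05
        child = pruned.edge_child(true_edges[0])
        assert child.label == "B"
        assert child.length == pytest.approx(0.10)

    def test_too_small_tree_rejected(self, toy_tree_newick):
        t = ReferenceTree.from_newick(toy_tree_newick)
        with pytest.raises(TreeError, match="fewer than 3"):
            t.prune_leaf("A")


class TestMidpoint:
    def test_two_leaf_symmetric_tie(self):
        t = ReferenceTree.from_newick("(A:1,B:1);")
        # midpoint exactly at the root: tie resolves to the lower edge number
        assert t.midpoint_edge().number == min(t.edge_numbers())

    def test_longest_path_halving(self):
        # chain: A far from C; longest path A-C of length 5, midpoint 2.5
        t = ReferenceTree.from_newick("((A:3,B:0.1):1,C:1);")
        mid = t.midpoint_edge()
        assert t.edge_child(mid).label == "A"
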