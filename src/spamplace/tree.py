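"""Rooted, edge-weighted reference trees with stable edge numbering.

Edges are identified with their child node and carry stable integer numbers
assigned in preorder (root's first child's edge is 0, children in input
order).  The numbering is what jplace placement records refer to, so it is
kept deterministic across parses of the same Newick string.
"""

from __future__ import annotations

import copy
import warnings
from collections import deque
from typing import Iterable, NamedTuple

import dendropy

__all__ = ["TreeError", "EdgeRef", "ReferenceTree", "parse_newick"]


class TreeError(ValueError):
    pass


class EdgeRef(NamedTuple):
    """Reference to one edge: its stable number and its child-node id."""

    number: int
    child: int


class _Node:
    __slots__ = ("label", "length", "children", "parent", "edge_number", "index")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length  # length of the edge to the parent
        self.children: list[_Node] = []
        self.parent: _Node | None = None
        self.edge_number: int | None = None
        self.index: int = -1

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


class ReferenceTree:
    """A rooted phylogeny with labelled leaves and numbered, weighted edges."""

    def __init__(self, root: _Node):
        self.root = root
        self._renumber()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "ReferenceTree":
        """Parse a Newick string (via dendropy) into a reference tree.

        Unrooted (basal trifurcation) input is accepted and treated as
        rooted at the basal node.  Missing branch lengths default to 0 with
        a warning; duplicate leaf labels are an error.
        """
        try:
            dt = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc

        missing_lengths = 0

        def convert(dnode) -> _Node:
            nonlocal missing_lengths
            if dnode.is_leaf():
                label = dnode.taxon.label if dnode.taxon is not None else dnode.label
                node = _Node(label=label)
            else:
                node = _Node(label=None)
            if dnode.edge.length is None:
                missing_lengths += 1
                node.length = 0.0
            else:
                node.length = float(dnode.edge.length)
            for dchild in dnode.child_nodes():
                node.add(convert(dchild))
            return node

        root = convert(dt.seed_node)
        root.length = 0.0
        if missing_lengths > 1:  # the root edge legitimately has none
            warnings.warn(
                f"{missing_lengths - 1} branch lengths missing; defaulting to 0",
                stacklevel=2,
            )
        tree = cls(root)
        labels = [leaf.label for leaf in tree.leaf_nodes()]
        if any(lb is None or lb == "" for lb in labels):
            raise TreeError("every leaf must be labelled")
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        if dupes:
            raise TreeError(f"duplicate leaf labels: {dupes}")
        return tree

    def _renumber(self) -> None:
        """Assign preorder node indices and edge numbers."""
        self._nodes: list[_Node] = []
        self._edges: dict[int, _Node] = {}
        self._leaves: dict[str, _Node] = {}
        edge_no = 0
        stack = [self.root]
        order: list[_Node] = []
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        for i, node in enumerate(order):
            node.index = i
            self._nodes.append(node)
            if node.parent is not None:
                node.edge_number = edge_no
                self._edges[edge_no] = node
                edge_no += 1
            else:
                node.edge_number = None
            if node.is_leaf() and node.label is not None:
                self._leaves[node.label] = node

    # -- basic queries ------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaves)

    def leaf_nodes(self) -> list[_Node]:
        return [n for n in self._nodes if n.is_leaf()]

    def node(self, index: int) -> _Node:
        return self._nodes[index]

    def leaf(self, label: str) -> _Node:
        try:
            return self._leaves[label]
        except KeyError:
            raise TreeError(f"unknown leaf label {label!r}") from None

    def edge_child(self, edge: int | EdgeRef) -> _Node:
        number = edge.number if isinstance(edge, EdgeRef) else edge
        try:
            return self._edges[number]
        except KeyError:
            raise TreeError(f"no edge numbered {number}") from None

    def edge_ref(self, edge: int | EdgeRef) -> EdgeRef:
        node = self.edge_child(edge)
        return EdgeRef(number=node.edge_number, child=node.index)

    def edge_numbers(self) -> list[int]:
        return sorted(self._edges)

    def edge_length(self, edge: int | EdgeRef) -> float:
        return self.edge_child(edge).length

    def total_edge_length(self) -> float:
        return sum(n.length for n in self._nodes if n.parent is not None)

    def first_root_child_edge(self) -> EdgeRef:
        return self.edge_ref(self.root.children[0].edge_number)

    # -- ancestry -----------------------------------------------------

    def _ancestors(self, node: _Node) -> list[_Node]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def lca(self, leaf_a: str, leaf_b: str) -> _Node:
        """Lowest common ancestor of two labelled leaves."""
        a = self.leaf(leaf_a)
        b = self.leaf(leaf_b)
        anc_a = set(id(n) for n in self._ancestors(a))
        node = b
        while node is not None:
            if id(node) in anc_a:
                return node
            node = node.parent
        raise TreeError("nodes share no ancestor (corrupt tree)")  # pragma: no cover

    def parent_edge(self, node: _Node) -> EdgeRef | None:
        """The edge from ``node`` toward the root; ``None`` at the root."""
        if node.parent is None:
            return None
        return EdgeRef(number=node.edge_number, child=node.index)

    def is_ancestor(self, anc: _Node, node: _Node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    # -- distances ----------------------------------------------------

    def _adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {n.index: [] for n in self._nodes}
        for n in self._nodes:
            if n.parent is not None:
                adj[n.index].append(n.parent.index)
                adj[n.parent.index].append(n.index)
        return adj

    def _node_hops(self, a: int, b: int) -> int:
        if a == b:
            return 0
        adj = self._adjacency()
        seen = {a}
        frontier = deque([(a, 0)])
        while frontier:
            u, dist = frontier.popleft()
            for v in adj[u]:
                if v == b:
                    return dist + 1
                if v not in seen:
                    seen.add(v)
                    frontier.append((v, dist + 1))
        raise TreeError("disconnected tree")  # pragma: no cover

    def node_distance(self, e1: int | EdgeRef, e2: int | EdgeRef) -> int:
        """Topological distance between two edges: the number of nodes on
        the path connecting them (same edge -> 0, adjacent edges -> 1)."""
        n1 = self.edge_child(e1)
        n2 = self.edge_child(e2)
        if n1 is n2:
            return 0
        ends1 = (n1.index, n1.parent.index)
        ends2 = (n2.index, n2.parent.index)
        best = min(self._node_hops(a, b) for a in ends1 for b in ends2)
        return best + 1

    def path_length(self, node_a: _Node, node_b: _Node) -> float:
        """Sum of branch lengths along the path between two nodes."""
        anc_a = {}
        d = 0.0
        n = node_a
        while n is not None:
            anc_a[id(n)] = d
            d += n.length
            n = n.parent
        d = 0.0
        n = node_b
        while n is not None:
            if id(n) in anc_a:
                return d + anc_a[id(n)]
            d += n.length
            n = n.parent
        raise TreeError("disconnected tree")  # pragma: no cover

    # -- editing ------------------------------------------------------

    def copy(self) -> "ReferenceTree":
        return ReferenceTree(copy.deepcopy(self.root))

    def insert_query_edge(
        self,
        edge: int | EdgeRef,
        split: float,
        pendant: float,
        label: str,
    ) -> "ReferenceTree":
        """Attach a new leaf on ``edge``, returning a modified copy.

        The edge (length L) is split into a distal part of length
        ``split * L`` (child side, keeping the original edge number) and a
        proximal part of length ``(1 - split) * L``; the new leaf hangs from
        the split point by an edge of length ``pendant``.  Untouched edges
        keep their numbers.
        """
        if not (0.0 <= split <= 1.0):
            raise TreeError("split must be in [0, 1]")
        if pendant < 0:
            raise TreeError("pendant length must be >= 0")
        if label in self._leaves:
            raise TreeError(f"leaf label {label!r} already present")

        number = edge.number if isinstance(edge, EdgeRef) else edge
        new = self.copy()
        child = new.edge_child(number)
        parent = child.parent
        L = child.length

        mid = _Node(label=None, length=(1.0 - split) * L)
        new_leaf = _Node(label=label, length=pendant)
        pos = parent.children.index(child)
        parent.children[pos] = mid
        mid.parent = parent
        child.length = split * L
        mid.add(child)
        mid.add(new_leaf)

        next_no = max(new._edges) + 1 if new._edges else 0
        # child keeps its number; mid's edge and the pendant edge get fresh
        # numbers without disturbing the rest.
        mid.edge_number = next_no
        new_leaf.edge_number = next_no + 1
        new._edges[next_no] = mid
        new._edges[next_no + 1] = new_leaf
        new._leaves[label] = new_leaf
        # refresh node indices/lists only (edge numbers stay as set)
        new._reindex_nodes()
        return new

    def _reindex_nodes(self) -> None:
        self._nodes = []
        stack = [self.root]
        order = []
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(node.children))
        for i, node in enumerate(order):
            node.index = i
            self._nodes.append(node)

    def clade_leafset(self, node: _Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def prune_leaf(self, label: str) -> tuple["ReferenceTree", tuple[int, ...]]:
        """Remove one leaf and return (pruned tree, true attachment edges).

        The leaf's former parent becomes degree-2 and is suppressed (its two
        incident edges merge, lengths summed); the merged edge is where the
        leaf was attached, and its number in the re-numbered pruned tree is
        returned.  If the parent was the root or a multifurcation, no single
        merged edge exists and the parent edges of the remaining sibling
        subtrees are returned instead (placement on any of them counts as
        distance 0).
        """
        if label not in self._leaves:
            raise TreeError(f"unknown leaf label {label!r}")
        if self.n_leaves <= 3:
            raise TreeError("pruning would leave fewer than 3 leaves")

        work = self.copy()
        leaf = work._leaves[label]
        v = leaf.parent
        v.children.remove(leaf)

        true_clades: list[frozenset[str]] = []
        if len(v.children) == 1 and v.parent is not None:
            w = v.children[0]
            w.length += v.length
            pos = v.parent.children.index(v)
            v.parent.children[pos] = w
            w.parent = v.parent
            true_clades.append(work.clade_leafset(w))
        elif len(v.children) == 1 and v.parent is None:
            # root left with one child: that child becomes the new root
            w = v.children[0]
            w.parent = None
            w.length = 0.0
            work.root = w
            true_clades.extend(work.clade_leafset(c) for c in w.children)
        else:
            # multifurcation: v survives; nearest edges are those around v
            if v.parent is not None:
                true_clades.append(work.clade_leafset(v))
            else:
                true_clades.extend(work.clade_leafset(c) for c in v.children)

        pruned = ReferenceTree(work.root)
        clade_to_edge = {
            pruned.clade_leafset(node): no for no, node in pruned._edges.items()
        }
        true_edges = tuple(
            sorted(clade_to_edge[c] for c in true_clades if c in clade_to_edge)
        )
        if not true_edges:  # pragma: no cover - defensive
            raise TreeError("could not locate the attachment edge after pruning")
        return pruned, true_edges

    # -- serialization ------------------------------------------------

    def _fmt_length(self, x: float) -> str:
        return format(x, ".10g")

    def to_newick(self, edge_numbers: bool = False) -> str:
        """Serialize to Newick; with ``edge_numbers=True`` each branch length
        is followed by ``{edge_num}`` as in jplace tree strings."""

        def render(node: _Node) -> str:
            if node.is_leaf():
                core = node.label
            else:
                core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.parent is None:
                return core
            s = f"{core}:{self._fmt_length(node.length)}"
            if edge_numbers:
                s += "{%d}" % node.edge_number
            return s

        return render(self.root) + ";"

    # -- midpoint -----------------------------------------------------

    def midpoint_edge(self) -> EdgeRef:
        """The edge containing the midpoint of the longest leaf-to-leaf path.

        Ties (longest path, or midpoint exactly on a node) resolve to the
        lowest edge number.
        """
        leaves = sorted(self._leaves)
        if len(leaves) < 2:
            raise TreeError("midpoint needs at least two leaves")
        best = None
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                dist = self.path_length(self._leaves[a], self._leaves[b])
                if best is None or dist > best[0] + 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        half = dist / 2.0

        # path of edges from a up to the LCA, then down to b
        na, nb = self._leaves[a], self._leaves[b]
        lca = self.lca(a, b)
        up = []
        n = na
        while n is not lca:
            up.append(n)  # edge above n
            n = n.parent
        down = []
        n = nb
        while n is not lca:
            down.append(n)
            n = n.parent
        path = up + list(reversed(down))  # edges in walking order from a to b

        candidates = []
        cum = 0.0
        for node in path:
            lo, hi = cum, cum + node.length
            if lo - 1e-12 <= half <= hi + 1e-12:
                candidates.append(node.edge_number)
            cum = hi
        return self.edge_ref(min(candidates))


def parse_newick(text: str) -> ReferenceTree:
    """Module-level convenience wrapper for :meth:`ReferenceTree.from_newick`."""
    return ReferenceTree.from_newick(text)
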