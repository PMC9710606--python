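"""Placement heuristics: choosing an attachment edge for each query read.

Five heuristics are available, all driven by the per-reference statistics
(filtered SpaM count s(Q,S) and Jukes–Cantor distance d(Q,S)):

* ``min-dist``   — pendant edge of the reference leaf minimizing d(Q,S).
* ``spam-count`` — pendant edge of the reference leaf maximizing s(Q,S).
* ``lca-dist``   — parent edge of the LCA of the two closest references.
* ``lca-count``  — parent edge of the LCA of the two highest-count references.
* ``spam-x``     — combines the count heuristics: if the top two counts s1 >=
  s2 satisfy |s1 - s2| > (s1 + s2) / X the query goes above the best leaf
  (spam-count), otherwise to the LCA edge (lca-count).  Default X = 4.

Queries without any filtered SpaM are recorded at the root (first child edge
of the root, pendant 0) and flagged.

Branch lengths: the chosen edge is split at its midpoint; the pendant length
is the estimated distance to the best reference minus the path length from
the attachment point to that reference leaf, clamped at 0.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .spam_core import PairStats
from .tree import EdgeRef, ReferenceTree

__all__ = [
    "Heuristic",
    "PlacementConfig",
    "Placement",
    "rank_references",
    "place_min_dist",
    "place_spam_count",
    "place_lca",
    "decide_spam_x",
    "place_query",
    "assign_branch_lengths",
]


class Heuristic(str, Enum):
    MIN_DIST = "min-dist"
    SPAM_COUNT = "spam-count"
    LCA_DIST = "lca-dist"
    LCA_COUNT = "lca-count"
    SPAM_X = "spam-x"


@dataclass(frozen=True)
class PlacementConfig:
    heuristic: Heuristic = Heuristic.SPAM_X
    x: float = 4.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("X must be positive")


@dataclass
class Placement:
    query_id: str
    edge: EdgeRef
    distal_length: float = 0.0
    pendant_length: float = 0.0
    heuristic_used: str = ""
    fallback_root: bool = False


def _query_rng(seed: int, query_id: str) -> np.random.Generator:
    """Tie-breaking RNG keyed on (seed, query id).

    Keyed per query so results do not depend on the order queries are
    processed in.
    """
    return np.random.default_rng([seed, zlib.crc32(query_id.encode("utf-8"))])


def rank_references(
    stats: dict[str, PairStats],
    by: str,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """References with s > 0, best first, ties broken by seeded random draw.

    ``by`` is ``"distance"`` (ascending d) or ``"count"`` (descending s).
    """
    if by not in ("distance", "count"):
        raise ValueError(f"unknown ranking criterion {by!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    refs = sorted(r for r, st in stats.items() if st.s > 0)
    if not refs:
        return []
    tiebreak = {r: float(t) for r, t in zip(refs, rng.random(len(refs)))}
    if by == "distance":
        return sorted(refs, key=lambda r: (stats[r].d, tiebreak[r]))
    return sorted(refs, key=lambda r: (-stats[r].s, tiebreak[r]))


def _leaf_placement(
    query_id: str,
    ranked: list[str],
    tree: ReferenceTree,
    heuristic: Heuristic,
) -> Placement:
    best = ranked[0]
    edge = tree.parent_edge(tree.leaf(best))
    return Placement(query_id=query_id, edge=edge, heuristic_used=heuristic.value)


def place_min_dist(
    query_id: str,
    stats: dict[str, PairStats],
    tree: ReferenceTree,
    config: PlacementConfig,
) -> Placement:
    rng = _query_rng(config.seed, query_id)
    ranked = rank_references(stats, by="distance", rng=rng)
    return _leaf_placement(query_id, ranked, tree, Heuristic.MIN_DIST)


def place_spam_count(
    query_id: str,
    stats: dict[str, PairStats],
    tree: ReferenceTree,
    config: PlacementConfig,
) -> Placement:
    rng = _query_rng(config.seed, query_id)
    ranked = rank_references(stats, by="count", rng=rng)
    return _leaf_placement(query_id, ranked, tree, Heuristic.SPAM_COUNT)


def _lca_edge(tree: ReferenceTree, s1: str, s2: str) -> EdgeRef:
    v = tree.lca(s1, s2)
    edge = tree.parent_edge(v)
    if edge is None:
        # v is the root: no parent edge exists, attach on the root's child
        # edge on the path toward the best reference.
        n = tree.leaf(s1)
        while n.parent is not tree.root:
            n = n.parent
        edge = tree.parent_edge(n)
    return edge


def place_lca(
    query_id: str,
    stats: dict[str, PairStats],
    tree: ReferenceTree,
    config: PlacementConfig,
    by: str = "distance",
) -> Placement:
    rng = _query_rng(config.seed, query_id)
    ranked = rank_references(stats, by=by, rng=rng)
    heuristic = Heuristic.LCA_DIST if by == "distance" else Heuristic.LCA_COUNT
    if len(ranked) == 1:
        # only one reference carries signal: degrade to the leaf heuristic
        return _leaf_placement(query_id, ranked, tree, heuristic)
    edge = _lca_edge(tree, ranked[0], ranked[1])
    return Placement(query_id=query_id, edge=edge, heuristic_used=heuristic.value)


def decide_spam_x(s1: int, s2: int, x: float) -> str:
    """Route a query: ``"leaf"`` iff |s1 - s2| > (s1 + s2) / X, else ``"lca"``."""
    if s1 < s2:
        raise ValueError("expects s1 >= s2")
    if x <= 0:
        raise ValueError("X must be positive")
    return "leaf" if abs(s1 - s2) > (s1 + s2) / x else "lca"


def _root_fallback(query_id: str, tree: ReferenceTree, heuristic: Heuristic) -> Placement:
    edge = tree.first_root_child_edge()
    return Placement(
        query_id=query_id,
        edge=edge,
        distal_length=0.5 * tree.edge_length(edge),
        pendant_length=0.0,
        heuristic_used=heuristic.value,
        fallback_root=True,
    )


def place_query(
    query_id: str,
    stats: dict[str, PairStats],
    tree: ReferenceTree,
    config: PlacementConfig,
) -> Placement:
    """Dispatch to the configured heuristic and assign branch lengths."""
    usable = {r: st for r, st in stats.items() if st.s > 0}
    if not usable:
        return _root_fallback(query_id, tree, config.heuristic)

    h = config.heuristic
    if h == Heuristic.MIN_DIST:
        placement = place_min_dist(query_id, usable, tree, config)
    elif h == Heuristic.SPAM_COUNT:
        placement = place_spam_count(query_id, usable, tree, config)
    elif h == Heuristic.LCA_DIST:
        placement = place_lca(query_id, usable, tree, config, by="distance")
    elif h == Heuristic.LCA_COUNT:
        placement = place_lca(query_id, usable, tree, config, by="count")
    elif h == Heuristic.SPAM_X:
        rng = _query_rng(config.seed, query_id)
        ranked = rank_references(usable, by="count", rng=rng)
        s1 = usable[ranked[0]].s
        s2 = usable[ranked[1]].s if len(ranked) > 1 else 0
        if decide_spam_x(s1, s2, config.x) == "leaf":
            placement = place_spam_count(query_id, usable, tree, config)
        else:
            placement = place_lca(query_id, usable, tree, config, by="count")
        placement.heuristic_used = Heuristic.SPAM_X.value
    else:  # pragma: no cover
        raise ValueError(f"unknown heuristic {h!r}")

    return assign_branch_lengths(placement, usable, tree, config)


def assign_branch_lengths(
    placement: Placement,
    stats: dict[str, PairStats],
    tree: ReferenceTree,
    config: PlacementConfig | None = None,
) -> Placement:
    """Set distal and pendant lengths on a chosen edge.

    The edge is split at its midpoint (distal = half the edge length).  The
    pendant length is d(Q, S1) minus the path length from the attachment
    point to the best-ranked reference leaf S1, clamped at zero; without a
    finite distance the pendant is zero.
    """
    seed = config.seed if config is not None else 42
    rng = _query_rng(seed, placement.query_id)
    by = (
        "distance"
        if placement.heuristic_used in (Heuristic.MIN_DIST.value, Heuristic.LCA_DIST.value)
        else "count"
    )
    ranked = rank_references(stats, by=by, rng=rng)

    edge_len = tree.edge_length(placement.edge)
    placement.distal_length = 0.5 * edge_len

    pendant = 0.0
    if ranked:
        s1_leaf = tree.leaf(ranked[0])
        d1 = stats[ranked[0]].d
        if d1 is not None:
            child = tree.edge_child(placement.edge)
            if tree.is_ancestor(child, s1_leaf):
                path = placement.distal_length + tree.path_length(child, s1_leaf)
            else:
                path = (edge_len - placement.distal_length) + tree.path_length(
                    child.parent, s1_leaf
                )
            pendant = max(0.0, d1 - path)
    placement.pendant_length = pendant
    return placement
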