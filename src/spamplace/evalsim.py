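"""Synthetic data and pruning-based accuracy (PAC) evaluation.

Sequence simulation evolves a uniform-random root sequence down a reference
tree under the Jukes–Cantor model: along a branch of length b (expected
substitutions per site) each site mutates independently with probability
p(b) = (3/4)(1 - e^{-4b/3}) to a uniformly chosen different base.  No indels
and no sequencing-error model are simulated.

The PAC harness prunes single leaves from the tree, fragments the pruned
taxon's sequence into fixed-length reads, places the reads on the pruned
tree, and scores each placement by the topological *node distance* (number
of nodes on the path between the chosen edge and the true attachment edge;
0 for the same edge, 1 for adjacent edges).  The mean over reads gives one
pruning's accuracy; the grand mean over prunings summarizes a run.
"""

from __future__ import annotations

import math
import warnings
import zlib
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

import numpy as np

from .io_formats import TaxonMap, pool_reference_stats
from .placement import Placement, PlacementConfig, place_query
from .spam_core import MatchConfig, compute_pair_stats, reverse_complement
from .tree import EdgeRef, ReferenceTree

__all__ = [
    "SimConfig",
    "PruningResult",
    "PacReport",
    "simulate_sequences",
    "fragment_reads",
    "sample_read_bag",
    "pac_run",
    "control_baselines",
    "coverage_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    tree: ReferenceTree
    length: int = 10_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("root sequence length must be >= 1")


def _substitution_prob(branch_length: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * branch_length / 3.0))


def simulate_sequences(sim: SimConfig) -> dict[str, str]:
    """Evolve sequences along the tree; returns leaf label -> sequence.

    Deterministic for a fixed seed: nodes are visited in preorder and all
    draws come from one seeded generator.
    """
    rng = np.random.default_rng(sim.seed)
    root_codes = rng.integers(0, 4, size=sim.length, dtype=np.uint8)

    leaf_seqs: dict[str, str] = {}

    def descend(node, codes: np.ndarray) -> None:
        if node.parent is not None:
            p = _substitution_prob(node.length)
            if p > 0:
                hit = rng.random(sim.length) < p
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                codes = codes.copy()
                codes[hit] = (codes[hit] + shift) % 4
        if node.is_leaf():
            leaf_seqs[node.label] = _BASES[codes].tobytes().decode("ascii")
        for child in node.children:
            descend(child, codes)

    descend(sim.tree.root, root_codes)
    return leaf_seqs


def fragment_reads(seq: str, read_len: int, min_len: int = 44) -> list[str]:
    """Split a sequence into consecutive non-overlapping segments.

    The final shorter remainder is kept only if at least ``min_len`` long
    (shorter fragments cannot contain a spaced-word occurrence of the
    default pattern); dropped remainders trigger a warning.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    reads = [seq[i : i + read_len] for i in range(0, len(seq), read_len)]
    if reads and len(reads[-1]) < read_len and len(reads[-1]) < min_len:
        reads.pop()
        if not reads:
            warnings.warn("sequence shorter than the minimum read length; no reads", stacklevel=2)
    return reads


def sample_read_bag(seq: str, read_len: int, coverage: float, seed: int) -> list[str]:
    """Sample ceil(coverage * |seq| / read_len) reads at uniform positions.

    Reads come from both strands with equal probability; reproducible for a
    fixed seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len > len(seq):
        raise ValueError("read_len exceeds the sequence length")
    n_reads = math.ceil(coverage * len(seq) / read_len)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(seq) - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    out = []
    for start, strand in zip(starts, strands):
        read = seq[start : start + read_len]
        out.append(reverse_complement(read) if strand else read)
    return out


@dataclass
class PruningResult:
    pruned_leaf: str
    true_edges: tuple[int, ...]
    read_edges: list[int]
    read_node_distances: list[int]

    @property
    def mean_node_distance(self) -> float:
        if not self.read_node_distances:
            return float("nan")
        return float(np.mean(self.read_node_distances))


@dataclass
class PacReport:
    prunings: list[PruningResult]

    @property
    def grand_mean(self) -> float:
        means = [p.mean_node_distance for p in self.prunings if p.read_node_distances]
        return float(np.mean(means)) if means else float("nan")


PlaceFn = Callable[[str, dict, ReferenceTree, tuple[int, ...]], EdgeRef | int]


def _nd_to_true(tree: ReferenceTree, edge: EdgeRef | int, true_edges: tuple[int, ...]) -> int:
    return min(tree.node_distance(edge, te) for te in true_edges)


def pac_run(
    tree: ReferenceTree,
    leaf_seqs: Mapping[str, str],
    read_len: int = 150,
    match_config: MatchConfig | None = None,
    placement_config: PlacementConfig | None = None,
    n_prunings: int | None = None,
    seed: int = 42,
    place_fn: PlaceFn | None = None,
) -> PacReport:
    """Pruning-based accuracy run over single-leaf prunings.

    For each pruning, the removed leaf's sequence is fragmented into reads,
    the reads are placed on the pruned tree and the node distance to the
    true attachment edge recorded.  ``place_fn`` overrides the placer (used
    for oracle self-tests); it receives (query_id, per-leaf stats, pruned
    tree, true edges) and returns an edge.
    """
    if tree.n_leaves < 4:
        raise ValueError("PAC needs a tree with at least 4 leaves")
    if match_config is None:
        match_config = MatchConfig()
    if placement_config is None:
        placement_config = PlacementConfig()

    labels = tree.leaf_labels
    rng = np.random.default_rng(seed)
    if n_prunings is None or n_prunings >= len(labels):
        chosen = list(rng.permutation(labels))
    else:
        chosen = list(rng.choice(labels, size=n_prunings, replace=False))

    results = []
    for label in chosen:
        pruned, true_edges = tree.prune_leaf(label)
        refs = {lb: seq for lb, seq in leaf_seqs.items() if lb != label}
        min_len = match_config.pattern_set.min_length
        reads = fragment_reads(leaf_seqs[label], read_len, min_len=min_len)
        queries = {f"{label}_read{i}": r for i, r in enumerate(reads)}
        stats = compute_pair_stats(refs, queries, match_config) if queries else {}

        read_edges: list[int] = []
        nds: list[int] = []
        for qid in sorted(queries):
            per_ref = {r: st for (q, r), st in stats.items() if q == qid}
            if place_fn is not None:
                edge = place_fn(qid, per_ref, pruned, true_edges)
            else:
                edge = place_query(qid, per_ref, pruned, placement_config).edge
            number = edge.number if isinstance(edge, EdgeRef) else int(edge)
            read_edges.append(number)
            nds.append(_nd_to_true(pruned, number, true_edges))
        results.append(
            PruningResult(
                pruned_leaf=label,
                true_edges=true_edges,
                read_edges=read_edges,
                read_node_distances=nds,
            )
        )
    return PacReport(prunings=results)


def control_baselines(tree: ReferenceTree, true_edge: EdgeRef | int) -> tuple[int, int]:
    """Node distances of the two trivial control placements.

    Returns (root_nd, midpoint_nd): the node distance from the true edge to
    the root's first child edge and to the edge containing the tree
    midpoint (half of the longest leaf-to-leaf path).
    """
    root_nd = tree.node_distance(tree.first_root_child_edge(), true_edge)
    midpoint_nd = tree.node_distance(tree.midpoint_edge(), true_edge)
    return root_nd, midpoint_nd


def coverage_experiment(
    tree: ReferenceTree,
    leaf_seqs: Mapping[str, str],
    coverage: float,
    read_len: int = 150,
    match_config: MatchConfig | None = None,
    placement_config: PlacementConfig | None = None,
    n_replicates: int = 3,
    seed: int = 42,
) -> float:
    """Mean node distance with bag-of-reads references at a given coverage.

    Each replicate prunes one leaf (different per replicate), replaces every
    remaining reference by a sampled read bag at the requested coverage,
    pools per-record statistics back to the leaf level, places the pruned
    taxon's fragment reads and records the mean node distance.  Returns the
    average over replicates.
    """
    if match_config is None:
        match_config = MatchConfig()
    if placement_config is None:
        placement_config = PlacementConfig()

    labels = tree.leaf_labels
    rng = np.random.default_rng(seed)
    pruned_labels = list(rng.choice(labels, size=min(n_replicates, len(labels)), replace=False))

    means = []
    for rep, label in enumerate(pruned_labels):
        pruned, true_edges = tree.prune_leaf(label)
        bag_refs: dict[str, str] = {}
        mapping: dict[str, str] = {}
        for lb, seq in leaf_seqs.items():
            if lb == label:
                continue
            bag_seed = int(
                np.random.default_rng([seed, rep, zlib.crc32(lb.encode())]).integers(2**31)
            )
            for i, read in enumerate(sample_read_bag(seq, read_len, coverage, bag_seed)):
                rid = f"{lb}|bag{i}"
                bag_refs[rid] = read
                mapping[rid] = lb
        taxon_map = TaxonMap(mapping=mapping)

        min_len = match_config.pattern_set.min_length
        reads = fragment_reads(leaf_seqs[label], read_len, min_len=min_len)
        queries = {f"{label}_read{i}": r for i, r in enumerate(reads)}
        record_stats = compute_pair_stats(bag_refs, queries, match_config)
        stats = pool_reference_stats(record_stats, taxon_map)

        nds = []
        for qid in sorted(queries):
            per_ref = {r: st for (q, r), st in stats.items() if q == qid}
            placement = place_query(qid, per_ref, pruned, placement_config)
            nds.append(_nd_to_true(pruned, placement.edge.number, true_edges))
        means.append(float(np.mean(nds)))
    return float(np.mean(means))
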