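"""End-to-end placement: sequences + tree + reads -> placements + jplace."""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

from .io_formats import TaxonMap, pool_reference_stats
from .placement import Placement, PlacementConfig, place_query
from .spam_core import MatchConfig, PairStats, compute_pair_stats
from .tree import ReferenceTree

__all__ = ["PlacementRun", "run_placement"]


@dataclass
class PlacementRun:
    placements: list[Placement]
    stats: dict[tuple[str, str], PairStats]
    n_fallback: int

    def metadata(self, match_config: MatchConfig, placement_config: PlacementConfig) -> dict:
        return {
            "program": "spamplace",
            "heuristic": placement_config.heuristic.value,
            "spam_x": placement_config.x,
            "threshold": match_config.threshold,
            "patterns": [p.template for p in match_config.pattern_set],
            "seed": placement_config.seed,
        }


def run_placement(
    references: Mapping[str, str],
    tree: ReferenceTree,
    queries: Mapping[str, str],
    match_config: MatchConfig | None = None,
    placement_config: PlacementConfig | None = None,
    taxon_map: TaxonMap | None = None,
) -> PlacementRun:
    """Place every query on the reference tree.

    ``taxon_map`` maps reference record ids to tree leaves (bag-of-reads
    mode); by default record ids must equal leaf labels.  Reference records
    that do not resolve to a leaf raise an error up front.
    """
    if match_config is None:
        match_config = MatchConfig()
    if placement_config is None:
        placement_config = PlacementConfig()
    if taxon_map is None:
        taxon_map = TaxonMap()
    taxon_map.validate(references.keys(), tree)

    record_stats = compute_pair_stats(references, queries, match_config)
    stats = pool_reference_stats(record_stats, taxon_map)

    placements = []
    n_fallback = 0
    for qid in sorted(queries):
        per_ref = {r: st for (q, r), st in stats.items() if q == qid}
        placement = place_query(qid, per_ref, tree, placement_config)
        n_fallback += placement.fallback_root
        placements.append(placement)
    return PlacementRun(placements=placements, stats=stats, n_fallback=n_fallback)
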