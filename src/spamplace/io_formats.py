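"""Sequence input, record-to-leaf mapping, and jplace/TSV output.

FASTA/FASTQ reading goes through Biopython; qualities are ignored.  The
jplace writer emits version-3 documents with a single placement per query
(this tool reports one location, so the likelihood-weight ratio is fixed at
1 and the likelihood at 0).

Bag-of-reads references (a taxon represented by unassembled reads instead of
one contiguous sequence) are expressed with a :class:`TaxonMap`: many record
ids map to one tree leaf and their match statistics are pooled before
placement.
"""

from __future__ import annotations

import json
import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .spam_core import FORWARD, PairStats
from .tree import ReferenceTree

__all__ = [
    "TaxonMap",
    "JPLACE_FIELDS",
    "read_sequences",
    "pool_reference_stats",
    "jplace_document",
    "validate_jplace",
    "write_jplace",
    "read_jplace",
    "write_tsv_summary",
]

JPLACE_FIELDS = [
    "edge_num",
    "likelihood",
    "like_weight_ratio",
    "distal_length",
    "pendant_length",
]


def read_sequences(path: str | Path, format: str | None = None) -> dict[str, str]:
    """Read FASTA or FASTQ into an id -> sequence mapping.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased with U mapped to T.  The format is inferred from the file
    extension unless given explicitly.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".fq", ".fastq"):
            format = "fastq"
        else:
            format = "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")

    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), format):
        sid = record.id
        if sid in out:
            raise ValueError(f"duplicate sequence id {sid!r} in {path}")
        out[sid] = str(record.seq).upper().replace("U", "T")
    if not out:
        raise ValueError(f"no sequence records found in {path}")
    return out


@dataclass(frozen=True)
class TaxonMap:
    """Mapping from sequence record ids to reference-tree leaf labels."""

    mapping: dict[str, str] | None = None

    def leaf_of(self, record_id: str) -> str:
        if self.mapping is None:
            return record_id
        return self.mapping.get(record_id, record_id)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonMap":
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            record_id, leaf = parts
            if record_id in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate record id {record_id!r}")
            mapping[record_id] = leaf
        return cls(mapping=mapping)

    def validate(self, record_ids, tree: ReferenceTree) -> None:
        """Check every record resolves to an existing leaf."""
        leaves = set(tree.leaf_labels)
        offenders = sorted(
            rid for rid in record_ids if self.leaf_of(rid) not in leaves
        )
        if offenders:
            raise ValueError(
                f"records not mapping to any tree leaf: {offenders[:10]}"
                + ("..." if len(offenders) > 10 else "")
            )


def pool_reference_stats(
    stats: Mapping[tuple[str, str], PairStats],
    taxon_map: TaxonMap | None = None,
) -> dict[tuple[str, str], PairStats]:
    """Pool per-record statistics into per-leaf statistics.

    SpaM counts and don't-care column/mismatch totals are summed over all
    records of a leaf; the mismatch proportion and distance follow from the
    pooled counts.  With the identity map this is a no-op.
    """
    if taxon_map is None:
        taxon_map = TaxonMap()
    acc: dict[tuple[str, str], list[int]] = {}
    for (q, rec), st in stats.items():
        key = (q, taxon_map.leaf_of(rec))
        a = acc.setdefault(key, [0, 0, 0])
        a[0] += st.s
        a[1] += st.dc_columns
        a[2] += st.dc_mismatches
    return {
        key: PairStats(s=a[0], dc_columns=a[1], dc_mismatches=a[2], strand=FORWARD)
        for key, a in acc.items()
    }


def jplace_document(tree: ReferenceTree, placements, meta: dict | None = None) -> dict:
    """Build a jplace v3 document (plain dict, JSON-serializable)."""
    records = []
    for p in sorted(placements, key=lambda p: p.query_id):
        records.append(
            {
                "p": [
                    [
                        int(p.edge.number),
                        0.0,
                        1.0,
                        float(p.distal_length),
                        float(p.pendant_length),
                    ]
                ],
                "n": [p.query_id],
            }
        )
    metadata = {"invocation": "spamplace"}
    if meta:
        metadata.update(meta)
    return {
        "version": 3,
        "tree": tree.to_newick(edge_numbers=True),
        "fields": list(JPLACE_FIELDS),
        "placements": records,
        "metadata": metadata,
    }


_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")


def validate_jplace(doc: dict) -> None:
    """Structural validation of a jplace v3 document.

    Raises ``ValueError`` on the first violation: missing keys, wrong field
    list, malformed placement records, or an edge number absent from the
    braced tree string.
    """
    for key in ("version", "tree", "fields", "placements", "metadata"):
        if key not in doc:
            raise ValueError(f"jplace document missing key {key!r}")
    if doc["version"] != 3:
        raise ValueError(f"unsupported jplace version {doc['version']!r}")
    fields = doc["fields"]
    for required in ("edge_num", "distal_length", "pendant_length"):
        if required not in fields:
            raise ValueError(f"fields list missing {required!r}")
    tree_edges = {int(m) for m in _EDGE_NUM_RE.findall(doc["tree"])}
    edge_idx = fields.index("edge_num")
    for rec in doc["placements"]:
        if "p" not in rec or ("n" not in rec and "nm" not in rec):
            raise ValueError("placement record needs 'p' and 'n'/'nm'")
        for row in rec["p"]:
            if len(row) != len(fields):
                raise ValueError("placement row length does not match fields")
            if int(row[edge_idx]) not in tree_edges:
                raise ValueError(f"edge_num {row[edge_idx]} not in tree string")


def write_jplace(tree: ReferenceTree, placements, meta: dict | None, path: str | Path) -> dict:
    doc = jplace_document(tree, placements, meta)
    validate_jplace(doc)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc


def read_jplace(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    validate_jplace(doc)
    return doc


def write_tsv_summary(placements, stats, path: str | Path) -> None:
    """Human-readable per-query table: edge, distance, count, heuristic."""
    lines = ["query\tedge_num\tbest_ref_d\tbest_ref_s\theuristic\tfallback_root"]
    for p in sorted(placements, key=lambda p: p.query_id):
        per_ref = {r: st for (q, r), st in stats.items() if q == p.query_id and st.s > 0}
        if per_ref:
            best = min(
                per_ref, key=lambda r: (per_ref[r].d if per_ref[r].d is not None else 99.0)
            )
            d = per_ref[best].d
            s = max(st.s for st in per_ref.values())
            d_str = f"{d:.6f}" if d is not None else "NA"
        else:
            d_str, s = "NA", 0
        lines.append(
            f"{p.query_id}\t{p.edge.number}\t{d_str}\t{s}\t{p.heuristic_used}\t"
            f"{int(p.fallback_root)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
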