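"""Spaced-word occurrence enumeration, match filtering and distance estimation.

The engine behind placement: for every query read Q and reference sequence S
it counts *filtered spaced-word matches* (SpaMs) — gap-free local alignments
of pattern length whose don't-care-column substitution score (HOXD70 by
default) exceeds a threshold t — and estimates the Jukes–Cantor distance
d(Q, S) from the pooled mismatch proportion at the don't-care columns of
those filtered matches.

Matching follows the sorted-list scheme: all spaced-word occurrences of the
references go into one list, those of a batch of queries into another, both
sorted lexicographically by the nucleotides at the match positions only.
Equal-key blocks are then crossed, each candidate SpaM scored over its
don't-care columns, and low-scoring (background) SpaMs discarded.  A query
occurrence may match many reference occurrences and vice versa.

Internally, occurrences are held as numpy arrays and keys are packed into
int64 (two bits per base, first match position most significant, so numeric
order equals lexicographic order over A<C<G<T).  This limits the pattern
weight to 31, far above any practically useful value.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from .patterns import Pattern, PatternSet, default_pattern

__all__ = [
    "HOXD70",
    "SATURATION_DISTANCE",
    "FORWARD",
    "REVERSE",
    "SpacedWordOccurrence",
    "OccurrenceList",
    "SpamMatch",
    "PairCounts",
    "PairStats",
    "MatchConfig",
    "reverse_complement",
    "enumerate_occurrences",
    "build_occurrence_list",
    "score_spam",
    "match_and_filter",
    "jukes_cantor",
    "compute_pair_stats",
]

BASES = "ACGT"
FORWARD = "forward"
REVERSE = "reverse"

#: HOXD70 nucleotide substitution scores (Chiaromonte, Yap & Miller 2002),
#: rows/columns ordered A, C, G, T.
HOXD70 = np.array(
    [
        [91, -114, -31, -123],
        [-114, 100, -125, -31],
        [-31, -125, 100, -114],
        [-123, -31, -114, 91],
    ],
    dtype=np.int64,
)

#: Distance reported when the mismatch proportion reaches the Jukes–Cantor
#: saturation boundary p >= 3/4, where the formula is undefined.
SATURATION_DISTANCE = 5.0

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SpacedWordOccurrence:
    """One spaced-word occurrence (W, i) in a sequence.

    ``key`` holds the nucleotides at the match positions (the spaced word
    with wildcards removed); ``dontcare_chars`` those at the don't-care
    positions.  ``pos`` is the 1-based window start on the enumerated strand.
    """

    seq_id: str
    pos: int
    key: str
    dontcare_chars: str
    strand: str = FORWARD


@dataclass(frozen=True)
class SpamMatch:
    """A scored spaced-word match between a reference and a query occurrence."""

    ref_occ: SpacedWordOccurrence
    query_occ: SpacedWordOccurrence
    score: int
    mismatches: int


def _window_arrays(seq: str, pattern: Pattern):
    """Vectorized enumeration of valid windows.

    Returns (pos1, keys, dc, n_skipped): 1-based start positions, packed
    int64 keys, an (n, D) uint8 array of don't-care base codes, and the
    number of windows skipped because they contain non-ACGT characters.
    """
    ell = pattern.length
    n_win = len(seq) - ell + 1
    empty = (
        np.empty(0, dtype=np.int64),
        np.empty(0, dtype=np.int64),
        np.empty((0, len(pattern.dontcare_positions)), dtype=np.uint8),
        0,
    )
    if n_win <= 0:
        return empty
    if pattern.weight > 31:
        raise ValueError("pattern weight > 31 is not supported by the packed-key engine")

    codes = _encode(seq)
    ok = (codes < 4).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(ok)))
    valid = (cum[ell:] - cum[:-ell]) == ell  # whole window is A/C/G/T
    n_skipped = int(n_win - valid.sum())
    if not valid.any():
        return empty[0], empty[1], empty[2], n_skipped

    starts = np.flatnonzero(valid)
    m_off = pattern.match_offsets()
    d_off = pattern.dontcare_offsets()

    keys = np.zeros(len(starts), dtype=np.int64)
    for off in m_off:
        keys = keys * 4 + codes[starts + off]
    if len(d_off):
        dc = codes[starts[:, None] + d_off[None, :]]
    else:
        dc = np.empty((len(starts), 0), dtype=np.uint8)
    return starts + 1, keys, dc, n_skipped


def _key_to_str(key: int, weight: int) -> str:
    out = []
    for _ in range(weight):
        out.append(BASES[key & 3])
        key >>= 2
    return "".join(reversed(out))


def enumerate_occurrences(
    seq: str, pattern: Pattern, strand: str = FORWARD, seq_id: str = ""
) -> list[SpacedWordOccurrence]:
    """List all spaced-word occurrences of ``pattern`` in ``seq``.

    ``strand="reverse"`` enumerates over the reverse complement of ``seq``;
    positions are then 1-based on the reverse-complemented string.  Windows
    containing non-ACGT characters are skipped silently.
    """
    if strand not in (FORWARD, REVERSE):
        raise ValueError(f"unknown strand {strand!r}")
    s = seq.upper()
    if strand == REVERSE:
        s = reverse_complement(s)
    pos1, keys, dc, _ = _window_arrays(s, pattern)
    w = pattern.weight
    out = []
    for i in range(len(pos1)):
        out.append(
            SpacedWordOccurrence(
                seq_id=seq_id,
                pos=int(pos1[i]),
                key=_key_to_str(int(keys[i]), w),
                dontcare_chars="".join(BASES[c] for c in dc[i]),
                strand=strand,
            )
        )
    return out


@dataclass
class OccurrenceList:
    """Spaced-word occurrences of many sequences, sorted by packed key.

    Sorted by (key, strand, sequence, position) so equal-key occurrences form
    contiguous blocks and runs are reproducible.
    """

    pattern: Pattern
    ids: list[str]
    seq_idx: np.ndarray  # int64, index into ids
    pos: np.ndarray  # int64, 1-based on the enumerated strand
    keys: np.ndarray  # int64 packed
    dc: np.ndarray  # (n, D) uint8 base codes
    strand: np.ndarray  # uint8: 0 forward, 1 reverse
    skipped_windows: int = 0

    def __len__(self) -> int:
        return len(self.keys)

    def entries(self) -> list[SpacedWordOccurrence]:
        w = self.pattern.weight
        return [
            SpacedWordOccurrence(
                seq_id=self.ids[self.seq_idx[i]],
                pos=int(self.pos[i]),
                key=_key_to_str(int(self.keys[i]), w),
                dontcare_chars="".join(BASES[c] for c in self.dc[i]),
                strand=REVERSE if self.strand[i] else FORWARD,
            )
            for i in range(len(self))
        ]


def build_occurrence_list(
    seqs: Mapping[str, str] | Sequence[tuple[str, str]],
    pattern: Pattern,
    strands: Sequence[str] = (FORWARD,),
) -> OccurrenceList:
    """Build the sorted occurrence list of a set of sequences."""
    if isinstance(seqs, Mapping):
        items = list(seqs.items())
    else:
        items = list(seqs)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dupes}")

    D = len(pattern.dontcare_positions)
    seq_idx_parts, pos_parts, key_parts, dc_parts, strand_parts = [], [], [], [], []
    skipped = 0
    for si, (sid, seq) in enumerate(items):
        s = seq.upper()
        for strand in strands:
            if strand == FORWARD:
                pos1, keys, dc, nsk = _window_arrays(s, pattern)
            elif strand == REVERSE:
                pos1, keys, dc, nsk = _window_arrays(reverse_complement(s), pattern)
            else:
                raise ValueError(f"unknown strand {strand!r}")
            skipped += nsk
            seq_idx_parts.append(np.full(len(keys), si, dtype=np.int64))
            pos_parts.append(pos1)
            key_parts.append(keys)
            dc_parts.append(dc)
            strand_parts.append(
                np.full(len(keys), 1 if strand == REVERSE else 0, dtype=np.uint8)
            )

    if key_parts:
        seq_idx = np.concatenate(seq_idx_parts)
        pos = np.concatenate(pos_parts)
        keys = np.concatenate(key_parts)
        dc = np.concatenate(dc_parts) if D else np.empty((sum(map(len, key_parts)), 0), np.uint8)
        strand = np.concatenate(strand_parts)
    else:
        seq_idx = np.empty(0, np.int64)
        pos = np.empty(0, np.int64)
        keys = np.empty(0, np.int64)
        dc = np.empty((0, D), np.uint8)
        strand = np.empty(0, np.uint8)

    order = np.lexsort((pos, seq_idx, strand, keys))
    return OccurrenceList(
        pattern=pattern,
        ids=ids,
        seq_idx=seq_idx[order],
        pos=pos[order],
        keys=keys[order],
        dc=dc[order],
        strand=strand[order],
        skipped_windows=skipped,
    )


def score_spam(ref_dc: str, query_dc: str, matrix: np.ndarray = HOXD70) -> tuple[int, int]:
    """Score one spaced-word match over its don't-care columns.

    Returns ``(score, mismatches)`` where score is the substitution-matrix
    sum over aligned don't-care columns and mismatches counts differing
    columns.  Match-position columns never contribute (they are identical by
    construction).
    """
    if len(ref_dc) != len(query_dc):
        raise ValueError("don't-care strings differ in length")
    if not ref_dc:
        return 0, 0
    a = _encode(ref_dc.upper())
    b = _encode(query_dc.upper())
    if (a > 3).any() or (b > 3).any():
        raise ValueError("don't-care strings must be over ACGT")
    score = int(matrix[a.astype(np.intp), b.astype(np.intp)].sum())
    mism = int((a != b).sum())
    return score, mism


@dataclass
class PairCounts:
    """Raw accumulators for one (query, reference, strand) pair."""

    s: int = 0
    dc_columns: int = 0
    dc_mismatches: int = 0

    def merge(self, other: "PairCounts") -> None:
        self.s += other.s
        self.dc_columns += other.dc_columns
        self.dc_mismatches += other.dc_mismatches


@dataclass(frozen=True)
class PairStats:
    """Filtered-SpaM statistics for one (query, reference) pair.

    ``s`` is the filtered SpaM count s(Q, S); ``p`` the pooled don't-care
    mismatch proportion; ``d`` the Jukes–Cantor distance.  ``p`` and ``d``
    are ``None`` when no filtered SpaM exists.
    """

    s: int
    dc_columns: int
    dc_mismatches: int
    strand: str = FORWARD

    def __post_init__(self) -> None:
        if not (0 <= self.dc_mismatches <= self.dc_columns):
            raise ValueError("invalid mismatch/column counts")

    @property
    def p(self) -> float | None:
        if self.s == 0 or self.dc_columns == 0:
            return None
        return self.dc_mismatches / self.dc_columns

    @property
    def d(self) -> float | None:
        p = self.p
        if p is None:
            return 0.0 if self.s > 0 else None
        return jukes_cantor(p)


@dataclass
class MatchConfig:
    """Parameters of the matching stage.

    threshold: SpaMs scoring <= threshold are discarded as background
    (strictly greater-than survives).  batch_size limits how many queries are
    in memory at once; results are independent of it.
    """

    pattern_set: PatternSet = field(
        default_factory=lambda: PatternSet((default_pattern(),))
    )
    threshold: int = 0
    batch_size: int = 2000
    seed: int = 42
    matrix: np.ndarray = field(default_factory=lambda: HOXD70.copy())
    threads: int = 1

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        m = np.asarray(self.matrix)
        if m.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")


_PAIR_CHUNK = 5_000_000  # max candidate SpaMs expanded at once


def _grouped_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0), [0..c1), ... concatenated."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    starts = ends - counts
    return np.arange(total, dtype=np.int64) - np.repeat(starts, counts)


def match_and_filter(
    L1: OccurrenceList, L2: OccurrenceList, config: MatchConfig
) -> dict[tuple[str, str, str], PairCounts]:
    """Cross equal-key blocks of the two sorted lists and filter by score.

    L1 holds reference occurrences, L2 query occurrences.  Every pair of
    occurrences sharing a key is a candidate SpaM; pairs with don't-care
    score strictly greater than ``config.threshold`` contribute to the
    returned per-(query, reference, strand) accumulators.
    """
    if L1.pattern.template != L2.pattern.template:
        raise ValueError("occurrence lists were built with different patterns")
    out: dict[tuple[str, str, str], PairCounts] = {}
    if len(L1) == 0 or len(L2) == 0:
        return out

    D = L1.dc.shape[1]
    matrix = np.asarray(config.matrix, dtype=np.int64)
    t = config.threshold

    u1, start1_all, c1_all = np.unique(L1.keys, return_index=True, return_counts=True)
    u2, start2_all, c2_all = np.unique(L2.keys, return_index=True, return_counts=True)
    common, i1, i2 = np.intersect1d(u1, u2, return_indices=True)
    if len(common) == 0:
        return out

    s1 = start1_all[i1]
    c1 = c1_all[i1]
    s2 = start2_all[i2]
    c2 = c2_all[i2]
    block_pairs = c1 * c2

    n_ref = len(L1.ids)
    n_q = len(L2.ids)
    s_acc = np.zeros(n_q * 2 * n_ref, dtype=np.int64)
    mism_acc = np.zeros(n_q * 2 * n_ref, dtype=np.int64)

    # Chunk block ranges so the expanded pair arrays stay bounded.
    chunk_bounds = [0]
    acc = 0
    for bi, bp in enumerate(block_pairs):
        if acc + bp > _PAIR_CHUNK and bi > chunk_bounds[-1]:
            chunk_bounds.append(bi)
            acc = 0
        acc += int(bp)
    chunk_bounds.append(len(block_pairs))

    for lo, hi in zip(chunk_bounds[:-1], chunk_bounds[1:]):
        if lo == hi:
            continue
        a = c1[lo:hi]
        b = c2[lo:hi]
        st1 = s1[lo:hi]
        st2 = s2[lo:hi]
        ab = a * b
        # Reference occurrence index per pair: each of the a ref occs of a
        # block is repeated b times.
        ref_occ = np.repeat(st1, a) + _grouped_arange(a)
        I = np.repeat(ref_occ, np.repeat(b, a))
        # Query occurrence index per pair: the block's b query occs tiled a
        # times.
        w = _grouped_arange(ab)
        b_rep = np.repeat(b, ab)
        J = np.repeat(st2, ab) + (w % b_rep)

        if D:
            scores = np.zeros(len(I), dtype=np.int64)
            mism = np.zeros(len(I), dtype=np.int64)
            dc1 = L1.dc
            dc2 = L2.dc
            for k in range(D):
                x = dc1[I, k].astype(np.intp)
                y = dc2[J, k].astype(np.intp)
                scores += matrix[x, y]
                mism += x != y
        else:
            scores = np.zeros(len(I), dtype=np.int64)
            mism = np.zeros(len(I), dtype=np.int64)

        keep = scores > t
        if not keep.any():
            continue
        Ik = I[keep]
        Jk = J[keep]
        g = (L2.seq_idx[Jk] * 2 + L2.strand[Jk]) * n_ref + L1.seq_idx[Ik]
        s_acc += np.bincount(g, minlength=len(s_acc))
        mism_acc += np.bincount(g, weights=mism[keep], minlength=len(s_acc)).astype(np.int64)

    nz = np.flatnonzero(s_acc)
    for g in nz:
        r = int(g % n_ref)
        qs = int(g // n_ref)
        q, strand_code = divmod(qs, 2)
        key = (L2.ids[q], L1.ids[r], REVERSE if strand_code else FORWARD)
        out[key] = PairCounts(
            s=int(s_acc[g]),
            dc_columns=int(s_acc[g]) * D,
            dc_mismatches=int(mism_acc[g]),
        )
    return out


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - (4/3) p).

    For ``p >= 0.75`` (outside the formula's domain) the saturation sentinel
    :data:`SATURATION_DISTANCE` is returned.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"mismatch proportion must be in [0, 1], got {p}")
    if p >= 0.75:
        return SATURATION_DISTANCE
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _strand_sort_key(c: PairCounts) -> tuple[int, int, int]:
    return (c.s, c.dc_columns, -c.dc_mismatches)


def _resolve_strand(
    counts: dict[tuple[str, str, str], PairCounts]
) -> dict[tuple[str, str], PairStats]:
    """Keep, per (query, reference), the strand with the stronger signal.

    The winning strand maximizes (s, dc_columns, -dc_mismatches); exact ties
    go to the forward strand.  The key is symmetric under strand swap, so a
    reverse-complemented query yields identical statistics.
    """
    out: dict[tuple[str, str], PairStats] = {}
    pair_keys: dict[tuple[str, str], dict[str, PairCounts]] = {}
    for (q, r, strand), c in counts.items():
        pair_keys.setdefault((q, r), {})[strand] = c
    for (q, r), by_strand in pair_keys.items():
        fwd = by_strand.get(FORWARD)
        rev = by_strand.get(REVERSE)
        if fwd is not None and rev is not None:
            chosen, strand = (
                (fwd, FORWARD)
                if _strand_sort_key(fwd) >= _strand_sort_key(rev)
                else (rev, REVERSE)
            )
        elif fwd is not None:
            chosen, strand = fwd, FORWARD
        else:
            chosen, strand = rev, REVERSE
        if chosen.s > 0:
            out[(q, r)] = PairStats(
                s=chosen.s,
                dc_columns=chosen.dc_columns,
                dc_mismatches=chosen.dc_mismatches,
                strand=strand,
            )
    return out


def _merge_counts(
    into: dict[tuple[str, str, str], PairCounts],
    new: dict[tuple[str, str, str], PairCounts],
) -> None:
    for k, c in new.items():
        if k in into:
            into[k].merge(c)
        else:
            into[k] = PairCounts(c.s, c.dc_columns, c.dc_mismatches)


def compute_pair_stats(
    references: Mapping[str, str],
    queries: Mapping[str, str],
    config: MatchConfig | None = None,
) -> dict[tuple[str, str], PairStats]:
    """Full matching pipeline: (query, reference) -> :class:`PairStats`.

    References are enumerated on the forward strand only; queries on both
    strands, with the per-pair statistics of the stronger strand retained.
    Queries are processed in batches (optionally across threads); the result
    is independent of batch size, thread count and input order.  Pairs
    without any filtered SpaM are absent from the result.
    """
    if config is None:
        config = MatchConfig()
    if not references:
        raise ValueError("reference set must be non-empty")
    if not queries:
        return {}

    ref_lists = [
        build_occurrence_list(references, pat, strands=(FORWARD,))
        for pat in config.pattern_set
    ]

    q_items = sorted(queries.items())  # order-independence
    batches = [
        q_items[i : i + config.batch_size]
        for i in range(0, len(q_items), config.batch_size)
    ]

    def run_batch(batch: list[tuple[str, str]]):
        counts: dict[tuple[str, str, str], PairCounts] = {}
        for pat, L1 in zip(config.pattern_set, ref_lists):
            L2 = build_occurrence_list(batch, pat, strands=(FORWARD, REVERSE))
            _merge_counts(counts, match_and_filter(L1, L2, config))
        return counts

    all_counts: dict[tuple[str, str, str], PairCounts] = {}
    if config.threads > 1 and len(batches) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as ex:
            for counts in ex.map(run_batch, batches):
                _merge_counts(all_counts, counts)
    else:
        for batch in batches:
            _merge_counts(all_counts, run_batch(batch))

    return _resolve_strand(all_counts)
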