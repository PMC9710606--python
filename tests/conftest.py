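"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's sorted-list machinery: the
exhaustive SpaM oracle scores every (i1, i2) window pair directly, and the
tree oracles work on explicit path sets / networkx graphs, so agreement with
the package is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from spamplace.patterns import Pattern
from spamplace.spam_core import FORWARD, REVERSE, HOXD70, reverse_complement

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------- SpaM oracle


def _oracle_one_strand(ref: str, query: str, pattern: Pattern, t: int):
    """Exhaustive all-position-pairs filtered-SpaM counts (s, cols, mism)."""
    ell = pattern.length
    m_pos = [i - 1 for i in pattern.match_positions]
    d_pos = [i - 1 for i in pattern.dontcare_positions]

    def windows(seq):
        out = []
        for i in range(len(seq) - ell + 1):
            win = seq[i : i + ell]
            if set(win) <= set(BASES):
                out.append(win)
        return out

    s = cols = mism = 0
    for rwin in windows(ref):
        for qwin in windows(query):
            if any(rwin[j] != qwin[j] for j in m_pos):
                continue
            score = sum(HOXD70[_IDX[rwin[j]], _IDX[qwin[j]]] for j in d_pos)
            if score > t:
                s += 1
                cols += len(d_pos)
                mism += sum(rwin[j] != qwin[j] for j in d_pos)
    return s, cols, mism


def spam_oracle(ref: str, query: str, pattern: Pattern, t: int):
    """Per-strand oracle counts: {strand: (s, cols, mism)} with s > 0 only."""
    out = {}
    fwd = _oracle_one_strand(ref, query, pattern, t)
    rev = _oracle_one_strand(ref, reverse_complement(query), pattern, t)
    if fwd[0]:
        out[FORWARD] = fwd
    if rev[0]:
        out[REVERSE] = rev
    return out


def spam_oracle_best_strand(ref: str, query: str, pattern: Pattern, t: int):
    """Best-strand oracle: (s, cols, mism, strand) or None.

    Strand selection mirrors the documented rule: maximize
    (s, cols, -mism), ties to forward.
    """
    per = spam_oracle(ref, query, pattern, t)
    if not per:
        return None
    best = None
    for strand in (FORWARD, REVERSE):
        if strand not in per:
            continue
        s, cols, mism = per[strand]
        key = (s, cols, -mism)
        if best is None or key > best[0]:
            best = (key, (s, cols, mism, strand))
    return best[1]


# ---------------------------------------------------------------- tree helpers


def random_binary_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """Random rooted binary tree with random branch lengths, as Newick."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.01, 1.0, size=2)
        nodes.append(f"({a}:{la:.4f},{b}:{lb:.4f})")
    return nodes[0] + ";"


@pytest.fixture
def toy_tree_newick() -> str:
    return "((A:1,B:1):1,C:2);"


@pytest.fixture
def balanced8_newick() -> str:
    """Balanced 8-leaf tree, every branch 0.05 substitutions/site."""
    c = "0.05"
    return (
        f"(((A:{c},B:{c}):{c},(C:{c},D:{c}):{c}):{c},"
        f"((E:{c},F:{c}):{c},(G:{c},H:{c}):{c}):{c});"
    )
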