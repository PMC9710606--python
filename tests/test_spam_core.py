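import math

import numpy as np
import pytest

from conftest import random_seq, spam_oracle, spam_oracle_best_strand
from spamplace.patterns import PatternSet, parse_pattern
from spamplace.spam_core import (
    FORWARD,
    REVERSE,
    SATURATION_DISTANCE,
    MatchConfig,
    build_occurrence_list,
    compute_pair_stats,
    enumerate_occurrences,
    jukes_cantor,
    match_and_filter,
    reverse_complement,
    score_spam,
)


class TestEnumerate:
    def test_spaced_word_key_from_window(self):
        # positions 1,2,4,7 of the window spell out the spaced word AT*G**C
        occ = enumerate_occurrences("ATAGTTC", parse_pattern("1101001"))
        assert len(occ) == 1
        assert occ[0].key == "ATGC"
        assert occ[0].pos == 1
        assert occ[0].dontcare_chars == "ATT"

    def test_sequence_shorter_than_pattern(self):
        assert enumerate_occurrences("ACG", parse_pattern("1101001")) == []

    def test_every_window_of_homopolymer(self):
        occ = enumerate_occurrences("AAAAAAAA", parse_pattern("11"))
        assert len(occ) == 7
        assert {o.key for o in occ} == {"AA"}
        assert [o.pos for o in occ] == list(range(1, 8))

    def test_non_acgt_windows_skipped(self):
        occ = enumerate_occurrences("AANAA", parse_pattern("11"))
        assert [o.pos for o in occ] == [1, 4]

    def test_reverse_strand_is_reverse_complement_scan(self):
        seq = "ACGTTGCA"
        fwd_on_rc = enumerate_occurrences(reverse_complement(seq), parse_pattern("101"))
        rev = enumerate_occurrences(seq, parse_pattern("101"), strand=REVERSE)
        assert [(o.pos, o.key) for o in rev] == [(o.pos, o.key) for o in fwd_on_rc]


class TestOccurrenceList:
    def test_sorted_and_blocks_contiguous(self):
        rng = np.random.default_rng(5)
        seqs = {f"s{i}": random_seq(rng, 80) for i in range(4)}
        L = build_occurrence_list(seqs, parse_pattern("1011"))
        keys = [e.key for e in L.entries()]
        assert keys == sorted(keys)
        # equal keys form one contiguous block
        seen_done = set()
        prev = None
        for k in keys:
            if k != prev:
                assert k not in seen_done
                if prev is not None:
                    seen_done.add(prev)
                prev = k

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_occurrence_list([("a", "ACGT"), ("a", "ACGT")], parse_pattern("11"))


class TestScore:
    @pytest.mark.parametrize(
        "a,b,score,mism",
        [("A", "A", 91, 0), ("A", "G", -31, 1), ("", "", 0, 0), ("CG", "CA", 100 - 31, 1)],
    )
    def test_hoxd70_scoring(self, a, b, score, mism):
        assert score_spam(a, b) == (score, mism)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            score_spam("AC", "A")


class TestMatchAndFilter:
    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(31)
        pattern = parse_pattern("1100101")
        config = MatchConfig(pattern_set=PatternSet((pattern,)), threshold=0)
        for _ in range(5):
            ref = random_seq(rng, 150)
            query = random_seq(rng, 120)
            L1 = build_occurrence_list({"R": ref}, pattern)
            L2 = build_occurrence_list({"Q": query}, pattern, strands=(FORWARD, REVERSE))
            got = match_and_filter(L1, L2, config)
            want = spam_oracle(ref, query, pattern, t=0)
            got_simple = {
                strand: (c.s, c.dc_columns, c.dc_mismatches)
                for (_, _, strand), c in got.items()
            }
            assert got_simple == want

    def test_no_shared_keys_gives_empty_result(self):
        pattern = parse_pattern("111")
        config = MatchConfig(pattern_set=PatternSet((pattern,)))
        L1 = build_occurrence_list({"R": "AAAAAA"}, pattern)
        L2 = build_occurrence_list({"Q": "CCCCCC"}, pattern, strands=(FORWARD,))
        assert match_and_filter(L1, L2, config) == {}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(8)
        pattern = parse_pattern("110101")
        ref, query = random_seq(rng, 200), random_seq(rng, 200)
        L1 = build_occurrence_list({"R": ref}, pattern)
        L2 = build_occurrence_list({"Q": query}, pattern, strands=(FORWARD, REVERSE))
        prev = None
        for t in (-300, -100, 0, 100, 300):
            config = MatchConfig(pattern_set=PatternSet((pattern,)), threshold=t)
            total_s = sum(c.s for c in match_and_filter(L1, L2, config).values())
            if prev is not None:
                assert total_s <= prev
            prev = total_s

    def test_pattern_mismatch_is_error(self):
        L1 = build_occurrence_list({"R": "ACGTACGT"}, parse_pattern("11"))
        L2 = build_occurrence_list({"Q": "ACGTACGT"}, parse_pattern("101"))
        with pytest.raises(ValueError, match="different patterns"):
            match_and_filter(L1, L2, MatchConfig())


class TestJukesCantor:
    def test_zero_and_known_value(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.1) == pytest.approx(0.1073256327, abs=1e-9)

    def test_saturation_sentinel(self):
        assert jukes_cantor(0.75) == SATURATION_DISTANCE
        assert jukes_cantor(0.9) == SATURATION_DISTANCE

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            jukes_cantor(p)

    def test_inverts_expected_mismatch_fraction(self):
        for d0 in (0.05, 0.2, 0.6):
            p0 = 0.75 * (1 - math.exp(-4 * d0 / 3))
            assert jukes_cantor(p0) == pytest.approx(d0, rel=1e-12)


class TestComputePairStats:
    def test_identical_sequences_have_zero_distance(self):
        rng = np.random.default_rng(2)
        seq = random_seq(rng, 300)
        stats = compute_pair_stats({"R": seq}, {"Q": seq})
        st = stats[("Q", "R")]
        assert st.p == 0.0
        assert st.d == 0.0
        assert st.s >= 1

    def test_exact_substring(self):
        rng = np.random.default_rng(3)
        ref = random_seq(rng, 600)
        stats = compute_pair_stats({"R": ref}, {"Q": ref[100:250]})
        st = stats[("Q", "R")]
        assert st.d == 0.0 and st.s >= 1

    def test_reverse_complement_query_gives_identical_stats(self):
        rng = np.random.default_rng(4)
        ref = random_seq(rng, 400)
        q = ref[50:200]
        fwd = compute_pair_stats({"R": ref}, {"Q": q})[("Q", "R")]
        rev = compute_pair_stats({"R": ref}, {"Q": reverse_complement(q)})[("Q", "R")]
        assert (fwd.s, fwd.dc_columns, fwd.dc_mismatches) == (
            rev.s,
            rev.dc_columns,
            rev.dc_mismatches,
        )
        assert {fwd.strand, rev.strand} == {FORWARD, REVERSE}

    def test_batching_and_threading_invariance(self):
        rng = np.random.default_rng(6)
        refs = {f"R{i}": random_seq(rng, 250) for i in range(3)}
        queries = {f"Q{i}": random_seq(rng, 100) for i in range(17)}
        base = compute_pair_stats(refs, queries, MatchConfig(batch_size=10_000))
        for bs, threads in ((1, 1), (5, 1), (5, 3)):
            other = compute_pair_stats(
                refs, queries, MatchConfig(batch_size=bs, threads=threads)
            )
            assert other == base

    def test_best_strand_matches_oracle(self):
        rng = np.random.default_rng(9)
        pattern = parse_pattern("110011")
        config = MatchConfig(pattern_set=PatternSet((pattern,)), threshold=0)
        for _ in range(4):
            ref = random_seq(rng, 120)
            query = random_seq(rng, 90)
            stats = compute_pair_stats({"R": ref}, {"Q": query}, config)
            want = spam_oracle_best_strand(ref, query, pattern, t=0)
            if want is None:
                assert ("Q", "R") not in stats
            else:
                st = stats[("Q", "R")]
                assert (st.s, st.dc_columns, st.dc_mismatches, st.strand) == want

    def test_empty_queries(self):
        assert compute_pair_stats({"R": "ACGTACGT"}, {}) == {}

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            compute_pair_stats({}, {"Q": "ACGT"})
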