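"""Filter cascade: quality, DP adapter clipping, homopolymer and length
rules, redundancy collapse and read-accounting conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rasikit.read_processing import (ADAPTER3, ADAPTER5, ProcessingParams,
                                     clip_adapters, collapse_library,
                                     filter_length, filter_quality,
                                     find_adapter3, merge_tag_sets,
                                     process_read, process_records,
                                     trim_homopolymers)

from oracles import clip_oracle

RNG = np.random.default_rng(1234)


def _rand(n, rng=RNG):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


class TestQualityFilter:
    def test_high_quality_passes(self):
        assert filter_quality("ACGT" * 9, [40] * 36, 20, 0.1)

    def test_low_mean_fails(self):
        assert not filter_quality("ACGT" * 9, [2] * 36, 20, 0.1)

    def test_n_fraction_fails(self):
        seq = "N" * 11 + "ACGT" * 6  # 30% N
        assert not filter_quality(seq, [40] * len(seq), 20, 0.1)

    def test_missing_qualities_pass(self):
        assert filter_quality("ACGT", None, 20, 0.1)


class TestAdapterClipping:
    def test_exact_adapter_recovers_insert(self):
        insert = _rand(36, np.random.default_rng(0))
        result = clip_adapters(insert + ADAPTER3)
        assert result.status == "kept"
        assert result.insert == insert
        assert result.adapter3_edits == 0
        assert result.adapter3_start == 36

    def test_single_substitution_in_adapter_recovered(self):
        insert = _rand(36, np.random.default_rng(1))
        mutated = "C" + ADAPTER3[1:] if ADAPTER3[0] != "C" else "G" + ADAPTER3[1:]
        read = insert + mutated
        result = clip_adapters(read)
        assert result.status == "kept"
        assert result.insert == insert
        assert result.adapter3_edits == 1
        # agrees with the per-offset enumeration oracle
        assert clip_oracle(read, ADAPTER3, 6, 0.2) == (
            result.adapter3_start, result.adapter3_edits, result.adapter3_overlap)

    def test_truncated_adapter_at_read_end(self):
        insert = _rand(36, np.random.default_rng(2))
        read = (insert + ADAPTER3)[:44]   # only 8 adapter bases survive
        result = clip_adapters(read)
        assert result.status == "kept"
        assert result.insert == insert
        assert result.adapter3_overlap == 8

    def test_read_without_adapter_is_discarded(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            result = clip_adapters(_rand(30, rng) + "AAAAGGGG")
            # random tails can occasionally resemble the adapter; the planted
            # tail here shares no 6-mer with it
            assert result.status in ("kept", "no_adapter")
        assert clip_adapters("GGGGGGGGGGAAAAAAAAAA").status == "no_adapter"

    def test_clipping_is_idempotent_on_clean_inserts(self):
        # inserts guaranteed free of the adapter seed cannot be re-clipped
        rng = np.random.default_rng(4)
        seed6 = ADAPTER3[:6]
        checked = 0
        while checked < 25:
            insert = _rand(32, rng)
            if seed6 in insert:
                continue
            first = clip_adapters(insert + ADAPTER3)
            assert first.insert == insert
            again = clip_adapters(first.insert)
            if again.status == "no_adapter":
                checked += 1

    def test_five_prime_adapter_remnant_removed(self):
        insert = _rand(30, np.random.default_rng(5))
        read = ADAPTER5[-10:] + insert + ADAPTER3
        result = clip_adapters(read)
        assert result.status == "kept"
        assert result.adapter5_clipped
        assert result.insert == insert

    def test_tie_breaks_toward_longest_insert(self):
        # two exact full adapter copies: the rightmost (longest insert) wins
        insert = _rand(10, np.random.default_rng(6))
        read = insert + ADAPTER3 + ADAPTER3
        result = clip_adapters(read)
        assert result.adapter3_start == len(insert) + len(ADAPTER3)


class TestClipperOracleEquivalence:
    """DP decisions equal exhaustive per-offset enumeration (small sample;
    the full 1000-read sweep runs in the acceptance suite)."""

    def test_mixed_reads_agree_with_oracle(self):
        rng = np.random.default_rng(99)
        for i in range(120):
            insert = _rand(int(rng.integers(8, 41)), rng)
            kind = i % 4
            if kind == 0:
                read = (insert + ADAPTER3)[:44]
            elif kind == 1:
                pos = int(rng.integers(0, len(ADAPTER3)))
                mutated = ADAPTER3[:pos] + "ACGT"[int(rng.integers(0, 4))] + ADAPTER3[pos + 1:]
                read = (insert + mutated)[:44]
            elif kind == 2:
                pos = int(rng.integers(0, 20))
                mutated = ADAPTER3[:pos] + ADAPTER3[pos + 1:]  # deletion
                read = (insert + mutated)[:44]
            else:
                read = _rand(int(rng.integers(15, 45)), rng)
            assert find_adapter3(read, ADAPTER3, 6, 0.2) == \
                clip_oracle(read, ADAPTER3, 6, 0.2), read


class TestHomopolymerTrimming:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT" + "A" * 13, "ACGT"),     # 13 > 12 forces the trim
        ("ACGT" + "A" * 12, "ACGT" + "A" * 12),   # 12 is not "longer than 12"
        ("G" * 20, ""),                   # whole read is one run
        ("T" * 13 + "ACGT", "ACGT"),      # 5' runs too
        ("C" * 14 + "ACGT" + "G" * 15, "ACGT"),
    ])
    def test_terminal_runs(self, seq, expected):
        trimmed, _ = trim_homopolymers(seq)
        assert trimmed == expected

    def test_internal_run_flagged_not_split(self):
        seq = "ACGT" + "A" * 15 + "CGTA"
        trimmed, internal = trim_homopolymers(seq)
        assert trimmed == seq
        assert internal

    def test_iterative_trimming(self):
        # removing the outer run exposes another over-long run
        seq = "A" * 13 + "G" * 13 + "ACGTACGTACG"
        trimmed, _ = trim_homopolymers(seq)
        assert trimmed == "ACGTACGTACG"

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_no_terminal_run_exceeds_limit_afterwards(self, seq):
        trimmed, _ = trim_homopolymers(seq, max_run=12)
        if trimmed:
            head = len(trimmed) - len(trimmed.lstrip(trimmed[0]))
            tail = len(trimmed) - len(trimmed.rstrip(trimmed[-1]))
            assert head <= 12 and tail <= 12
        # trimming only removes characters
        assert trimmed in seq or trimmed == ""


class TestLengthFilter:
    @pytest.mark.parametrize("length,passes", [(10, False), (11, True), (36, True)])
    def test_boundary(self, length, passes):
        assert filter_length("A" * length, 11) is passes


class TestCollapse:
    def test_multiplicities(self):
        tags = collapse_library(["ACGTACGTACGT", "ACGTACGTACGT", "ACGTACGTACGT",
                                 "TTTTACGTACGT"], "eggs")
        by_seq = {t.sequence: t for t in tags}
        assert by_seq["ACGTACGTACGT"].counts == {"eggs": 3}
        assert by_seq["TTTTACGTACGT"].counts == {"eggs": 1}
        assert sum(t.total_count for t in tags) == 4

    def test_merge_unions_count_maps(self):
        eggs = collapse_library(["ACGTACGTACGT"] * 2, "eggs")
        l2 = collapse_library(["ACGTACGTACGT"] * 5, "L2")
        merged = merge_tag_sets([eggs, l2])
        assert len(merged) == 1
        assert merged[0].counts == {"eggs": 2, "L2": 5}
        assert merged[0].total_count == 7

    def test_empty_input(self):
        assert collapse_library([], "eggs") == []

    def test_ids_independent_of_input_order(self):
        seqs = ["ACGTACGTACGT", "TTGGACGTACGT", "ACGTACGTACGT", "CCCGACGTACGT"]
        a = collapse_library(seqs, "x")
        b = collapse_library(seqs[::-1], "x")
        assert [(t.tag_id, t.sequence, t.counts) for t in a] == \
            [(t.tag_id, t.sequence, t.counts) for t in b]


class TestConservation:
    def test_statuses_partition_every_read(self):
        """On simulated reads of all kinds, the summary identity holds and
        kept reads equal the collapsed count mass."""
        from rasikit.synthetic_data import Scenario, build_truth, \
            simulate_small_rna_library

        scenario = Scenario(stage_totals={"eggs": 3000, "L2": 2000, "pupae": 1000})
        truth = build_truth(5, scenario)
        rng = np.random.default_rng(6)
        reads, _ = simulate_small_rna_library(rng, truth, "eggs")
        records = ((rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in reads)
        tags, summary, statuses = process_records(records, "eggs")
        assert summary.raw_reads == len(reads) == 3000
        assert summary.raw_reads == (summary.low_quality + summary.no_adapter
                                     + summary.too_short + summary.high_quality_reads)
        assert sum(t.total_count for t in tags) == summary.high_quality_reads

    def test_zero_error_reads_recover_planted_inserts_exactly(self):
        rng = np.random.default_rng(8)
        params = ProcessingParams()
        for _ in range(50):
            insert = _rand(int(rng.integers(15, 37)), rng)
            if ADAPTER3[:6] in insert:
                continue
            result = process_read(insert + ADAPTER3, [37] * (len(insert) + 24), params)
            assert result.status == "kept"
            assert result.insert == insert
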