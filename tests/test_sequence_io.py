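"""Read cleaning, collapsing and length accounting."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from vamir._util import ConfigError
from vamir.sequence_io import (
    LengthHistogram,
    RawRead,
    collapse_reads,
    length_distribution,
    length_filter,
    polya_filter,
    quality_filter,
    trim_adapters,
)

import oracles

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"

seqs = st.text(alphabet="ACGT", min_size=15, max_size=30)


def make_reads(sequences, qual=None):
    return [RawRead(f"r{i}", s, qual) for i, s in enumerate(sequences)]


class TestTrimAdapters:
    def test_exact_adapter_suffix_removed(self):
        read = RawRead("r1", "ACGTACGT" + ADAPTER3[:10])
        (out,) = trim_adapters([read], ADAPTER3)
        assert out.sequence == "ACGTACGT"

    def test_read_equal_to_adapter_yields_no_insert(self):
        assert trim_adapters([RawRead("r1", ADAPTER3)], ADAPTER3) == []

    def test_read_without_adapter_dropped(self):
        # insert runs past the read end: length is unknowable, read dropped
        assert trim_adapters([RawRead("r1", "ACGTACGTACGTACGTACGTACGT")], ADAPTER3) == []

    def test_one_mismatch_in_overlap_still_trimmed(self):
        adapter_part = "A" + ADAPTER3[1:10]  # 1 mismatch in a 10-nt overlap
        read = RawRead("r1", "GGGGCCCC" + adapter_part)
        (out,) = trim_adapters([read], ADAPTER3, max_mismatch_rate=0.1)
        start = oracles.brute_best_adapter_start(read.sequence, ADAPTER3, 6, 0.1)
        assert out.sequence == read.sequence[:start] == "GGGGCCCC"

    def test_agrees_with_brute_force_best_overlap(self):
        rng = random.Random(42)
        for _ in range(200):
            insert = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 25)))
            n_ad = rng.randint(0, len(ADAPTER3))
            seq = insert + ADAPTER3[:n_ad]
            start = oracles.brute_best_adapter_start(seq, ADAPTER3, 6, 0.1)
            out = trim_adapters([RawRead("r", seq)], ADAPTER3)
            if start is None or start == 0:
                assert out == []
            else:
                assert out[0].sequence == seq[:start]

    def test_empty_adapter_rejected(self):
        with pytest.raises(ConfigError):
            trim_adapters([RawRead("r1", "ACGT")], "")

    def test_five_prime_adapter_removed(self):
        adapter5 = "GTTCAGAGTTCTACAGTCCGACGATC"
        read = RawRead("r1", adapter5[-8:] + "ACGTACGTACGT" + ADAPTER3)
        (out,) = trim_adapters([read], ADAPTER3, adapter5)
        assert out.sequence == "ACGTACGTACGT"

    def test_order_preserved(self):
        reads = make_reads([f"ACGTACGTACG{b}" + ADAPTER3 for b in "ACGT"])
        out = trim_adapters(reads, ADAPTER3)
        assert [r.identifier for r in out] == [r.identifier for r in reads]


class TestQualityFilter:
    def test_n_containing_read_removed(self):
        reads = make_reads(["ACGTNACGTACGTACGT", "ACGTACGTACGTACGTA"])
        out = quality_filter(reads, max_n_fraction=0.0)
        assert [r.sequence for r in out] == ["ACGTACGTACGTACGTA"]

    def test_perfect_reads_pass_unchanged(self):
        reads = [RawRead("r", "ACGTACGTACGTACG", [40] * 15)]
        assert quality_filter(reads) == reads

    def test_low_mean_quality_removed(self):
        low = RawRead("lo", "ACGTACGTACGTACG", [10] * 15)
        hi = RawRead("hi", "ACGTACGTACGTACG", [35] * 15)
        assert quality_filter([low, hi], min_mean_quality=20) == [hi]

    def test_planted_low_quality_reads_are_exactly_removed(self):
        rng = random.Random(0)
        good = [RawRead(f"g{i}", "ACGT" * 5, [40] * 20) for i in range(90)]
        bad = [RawRead(f"b{i}", "ACGT" * 5, [12] * 20) for i in range(10)]
        mixed = good + bad
        rng.shuffle(mixed)
        out = quality_filter(mixed, min_mean_quality=20)
        assert sorted(r.identifier for r in out) == sorted(r.identifier for r in good)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,bounds,kept",
        [
            (17, (18, 30), False),  # informatic filter regime
            (24, (18, 30), True),
            (15, (15, 30), True),   # gel-purification regime
            (31, (15, 30), False),
        ],
    )
    def test_bounds(self, length, bounds, kept):
        reads = make_reads(["A" * length])
        out = length_filter(reads, *bounds)
        assert bool(out) is kept

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            length_filter([], 30, 18)

    @given(st.lists(seqs, max_size=30))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, sequences):
        reads = make_reads(sequences)
        once = length_filter(reads, 18, 30)
        assert length_filter(once, 18, 30) == once


class TestCollapse:
    def test_small_example(self):
        tags = collapse_reads(make_reads(["ACGT", "ACGT", "ACGA"]))
        assert [(t.sequence, t.read_count) for t in tags] == [("ACGT", 2), ("ACGA", 1)]

    def test_distinct_reads_each_count_one(self):
        tags = collapse_reads(make_reads(["AAAA", "CCCC", "GGGG"]))
        assert all(t.read_count == 1 for t in tags)

    @given(st.lists(seqs, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_read_count_conservation(self, sequences):
        tags = collapse_reads(make_reads(sequences))
        assert sum(t.read_count for t in tags) == len(sequences)
        assert len(tags) == len(set(sequences))

    def test_deterministic_order(self):
        reads = make_reads(["TTTT", "AAAA", "TTTT", "CCCC", "CCCC"])
        tags = collapse_reads(reads)
        assert [t.sequence for t in tags] == ["CCCC", "TTTT", "AAAA"]

    def test_recovers_simulator_multiplicities(self, small_pipeline_state):
        b = small_pipeline_state["bundle"]
        tags = {t.sequence: t.read_count for t in small_pipeline_state["tags"]}
        truth = b.truth.reads.groupby("sequence")["count"].sum()
        # polyA-heavy truth inserts are dropped by the cleaning stage
        checked = 0
        for seq, count in truth.items():
            if seq.count("A") / len(seq) >= 0.8 or seq.endswith("A" * 8):
                continue
            assert tags.get(seq, 0) == count
            checked += 1
        assert checked > 50


class TestLengthDistribution:
    def test_single_tag(self):
        tags = collapse_reads(make_reads(["ACGTACGTACGTACGTACGTA"] * 5))
        hist = length_distribution(tags)
        assert hist.fractions() == {21: 1.0}

    def test_counts_sum_to_total_reads(self, small_pipeline_state):
        tags = small_pipeline_state["tags"]
        hist = length_distribution(tags)
        assert hist.total_reads == sum(t.read_count for t in tags)

    def test_simulator_profile_mode_is_24(self, small_pipeline_state):
        hist = length_distribution(small_pipeline_state["tags"])
        assert hist.mode() == 24

    def test_empty_input_signals(self):
        with pytest.raises(ValueError):
            length_distribution([])


class TestPolyA:
    def test_high_a_content_dropped(self):
        tags = collapse_reads(make_reads(["AAAAAAAAAAAAAAAAAAGA", "ACGTACGTACGTACGTACGT"]))
        out = polya_filter(tags)
        assert [t.sequence for t in out] == ["ACGTACGTACGTACGTACGT"]

    def test_terminal_a_run_dropped(self):
        tags = collapse_reads(make_reads(["ACGTCGTACGTAAAAAAAAA"]))
        assert polya_filter(tags) == []
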