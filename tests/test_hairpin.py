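"""Folding engine, precursor windows, and hairpin adjudication."""

from __future__ import annotations

import random

import pytest

from vamir._util import InputError, revcomp
from vamir.annotate import GenomeLocus
from vamir.conserved import KnownMature
from vamir.hairpin import (
    CriteriaConfig,
    classify_novelty,
    evaluate_candidate,
    excise_precursor_windows,
    five_prime_composition,
    fold,
    select_best_candidate,
    star_sequence,
    structure_energy,
)

import oracles


def perfect_hairpin(arm="GCGTACGTTAGCCGATAGGCTAGCTTCGATCGTAGCTAGCTAAGG", loop="ATCGATCGATCG"):
    return arm + loop + revcomp(arm)


class TestFold:
    def test_unpairable_sequence_is_flat(self):
        r = fold("AAAAAAA")
        assert r.structure == "......." and r.mfe == 0.0 and r.pair_table == {}

    def test_gc_hairpin_with_minimal_loop(self):
        r = fold("GGGGAAACCCC")
        assert r.structure == "((((...))))"
        assert r.mfe == -5.0  # three stacked G:C pairs plus one loop penalty

    def test_mfe_zero_iff_no_pairs(self):
        rng = random.Random(9)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 30)))
            r = fold(seq)
            assert (r.mfe == 0.0) == (len(r.pair_table) == 0)

    def test_structure_is_consistent_with_reported_energy(self):
        rng = random.Random(10)
        for _ in range(40):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 60)))
            r = fold(seq)
            pairs = sorted((i, j) for i, j in r.pair_table.items() if i < j)
            assert len(r.structure) == len(seq)
            assert r.structure.count("(") == r.structure.count(")") == len(pairs)
            if pairs:
                assert abs(structure_energy(seq, pairs) - r.mfe) < 1e-9

    def test_equals_exhaustive_enumeration_oracle(self):
        rng = random.Random(12)
        for _ in range(40):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 16)))
            expected = min(0.0, oracles.brute_min_energy(seq))
            assert abs(fold(seq).mfe - expected) < 1e-9

    def test_non_acgt_rejected(self):
        with pytest.raises(InputError):
            fold("ACGTNACGT")


class TestWindows:
    GENOME = {"chr1": "A" * 5000}

    def test_interior_window_arithmetic(self):
        loc = GenomeLocus("chr1", 1000, 1021, "+")
        wins = excise_precursor_windows(loc, self.GENOME, max_flank=60, step=20)
        spans = {(w[0].start, w[0].end) for w in wins}
        assert (940, 1081) in spans

    def test_window_count_formula_for_interior_locus(self):
        loc = GenomeLocus("chr1", 1000, 1021, "+")
        wins = excise_precursor_windows(loc, self.GENOME, max_flank=60, step=20)
        assert len(wins) == (60 // 20 + 1) ** 2 - 1

    def test_upstream_clipped_at_chromosome_start(self):
        loc = GenomeLocus("chr1", 3, 24, "+")
        wins = excise_precursor_windows(loc, self.GENOME, max_flank=40, step=20)
        assert min(w[0].start for w in wins) == 1

    def test_minus_strand_window_is_reverse_complemented(self):
        rng = random.Random(4)
        genome = {"chr1": "".join(rng.choice("ACGT") for _ in range(300))}
        loc = GenomeLocus("chr1", 100, 121, "-")
        wins = excise_precursor_windows(loc, genome, max_flank=20, step=20)
        for wloc, wseq, off in wins:
            mature = revcomp(genome["chr1"][99:121])
            assert wseq[off : off + 22] == mature

    def test_locus_outside_genome_rejected(self):
        with pytest.raises(InputError):
            excise_precursor_windows(GenomeLocus("chr1", 4995, 5050, "+"), self.GENOME)


class TestStar:
    def test_perfect_duplex_star_is_offset_revcomp(self):
        pre = perfect_hairpin()
        arm_len = 45
        r = fold(pre)
        mature_span = (5, 26)  # 22-nt mature inside the 5p arm
        (lo, hi), star = star_sequence(r, mature_span)
        n = len(pre)
        # canonical geometry: partners of the mature shifted +2 at each end
        assert lo == (n - 1 - 26) + 2 and hi == (n - 1 - 5) + 2
        assert star == pre[lo : hi + 1]

    def test_star_of_star_roundtrip(self):
        pre = perfect_hairpin()
        r = fold(pre)
        span, star = star_sequence(r, (5, 26))
        span2, star2 = star_sequence(r, span)
        assert span2 == (5, 26)
        assert star2 == pre[5:27]

    def test_unpaired_mature_has_no_star(self):
        pre = perfect_hairpin()
        r = fold(pre)
        loop_start = 45
        assert star_sequence(r, (loop_start + 1, loop_start + 10)) is None


class TestEvaluate:
    def test_planted_hairpin_accepted_with_star_support(self):
        pre = perfect_hairpin()
        r = fold(pre)
        span, star = star_sequence(r, (5, 26))
        cand = evaluate_candidate(r, (5, 26), {star: 12}, CriteriaConfig(min_precursor_len=60))
        assert cand.accepted
        assert cand.arm == "5p"
        assert cand.star_reads == 12
        assert cand.criteria_flags["star_found"]

    def test_missing_star_is_not_a_gate(self):
        pre = perfect_hairpin()
        r = fold(pre)
        cand = evaluate_candidate(r, (5, 26), {}, CriteriaConfig(min_precursor_len=60))
        assert cand.accepted and not cand.criteria_flags["star_found"]

    def test_mfe_threshold_gates_acceptance(self):
        pre = perfect_hairpin()
        r = fold(pre)
        cand = evaluate_candidate(r, (5, 26), {}, CriteriaConfig(mfe_threshold=-500.0))
        assert not cand.criteria_flags["mfe"] and not cand.accepted

    def test_mature_in_terminal_loop_rejected(self):
        pre = perfect_hairpin()
        r = fold(pre)
        cand = evaluate_candidate(r, (40, 60), {}, CriteriaConfig(min_precursor_len=60))
        assert not cand.criteria_flags["single_arm"]

    def test_mature_span_outside_window_rejected(self):
        r = fold("GGGGAAACCCC")
        with pytest.raises(InputError):
            evaluate_candidate(r, (5, 30), {})

    def test_simulator_planted_hairpins_accepted(self, small_bundle):
        b = small_bundle
        lib = dict(zip(b.truth.reads.sequence, b.truth.reads["count"]))
        for _, r in b.truth.mirnas.head(5).iterrows():
            pre_fold = fold(r.precursor_seq)
            off = r.mature_start - r.precursor_start
            cand = evaluate_candidate(
                pre_fold, (off, off + len(r.mature_seq) - 1), lib, CriteriaConfig()
            )
            assert cand.accepted
            if r.star_reads > 0:
                assert cand.star_seq == r.star_seq
                assert cand.star_reads >= r.star_reads


class TestSelection:
    def test_lowest_mfe_wins_and_is_deterministic(self):
        pre = perfect_hairpin()
        r = fold(pre)
        strong = evaluate_candidate(r, (5, 26), {}, CriteriaConfig(min_precursor_len=60))
        weak_arm = "GCGTACGTTAGCCGATAGGCT"
        weak = fold(weak_arm + "AAAA" + revcomp(weak_arm))
        weak_cand = evaluate_candidate(weak, (0, 20), {}, CriteriaConfig(min_precursor_len=40))
        assert weak_cand.accepted and strong.fold.mfe < weak_cand.fold.mfe
        assert select_best_candidate([weak_cand, strong]) is strong
        assert select_best_candidate([strong, weak_cand]) is strong

    def test_no_accepted_candidates_returns_none(self):
        r = fold("GGGGAAACCCC")
        cand = evaluate_candidate(r, (0, 3), {}, CriteriaConfig())
        assert select_best_candidate([cand]) is None


class TestComposition:
    def test_all_t_start(self):
        assert five_prime_composition(["TAAA", "TCCC"])["T"] == 1.0

    def test_fractions_sum_to_one(self):
        comp = five_prime_composition(["TAAA", "CAAA", "GAAA", "AAAA", "TTTT"])
        assert abs(sum(comp.values()) - 1.0) < 1e-12


class TestNovelty:
    def test_three_way_classification(self):
        vitis = [KnownMature.from_header("vvi-miR001", "TGACAGAAGAGAGGGAGCAC")]
        other = [KnownMature.from_header("ath-miR002", "TTGGACTGAAGGGAGCTCCC")]

        def cand(seq):
            r = fold(perfect_hairpin())
            c = evaluate_candidate(r, (5, 26), {}, CriteriaConfig(min_precursor_len=60))
            c.mature_tag.sequence = seq
            return c

        out = classify_novelty(
            [cand("TGACAGAAGAGAGGGAGCAC"), cand("TTGGACTGAAGGGAGCTCCC"), cand("ACGCGCGATATCGCGGCTAT")],
            vitis,
            other,
        )
        assert out["TGACAGAAGAGAGGGAGCAC"] == "vitis_specific"
        assert out["TTGGACTGAAGGGAGCTCCC"] == "shared"
        assert out["ACGCGCGATATCGCGGCTAT"] == "species_specific"

    def test_empty_comparison_sets_all_species_specific(self):
        r = fold(perfect_hairpin())
        c = evaluate_candidate(r, (5, 26), {}, CriteriaConfig(min_precursor_len=60))
        assert classify_novelty([c], [], []) == {c.mature_tag.sequence: "species_specific"}
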