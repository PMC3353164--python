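"""miR-SNP / miR-LD calling and SNP-vs-duplex classification."""

from __future__ import annotations

import random

from hypothesis import given, settings, strategies as st

from vamir.conserved import ConservedAssignment, KnownMature
from vamir.sequence_io import SmallRNATag
from vamir.targets import align_duplex
from vamir.variants import (
    VariantCall,
    call_mir_ld,
    call_mir_snp,
    scan_variants,
    select_wildtype,
    snp_family_distribution,
    snp_vs_duplex,
)
from vamir._util import revcomp

import oracles

WT = "TGACAGAAGAGAGGGAGCAC"

seqs = st.text(alphabet="ACGT", min_size=18, max_size=24)


class TestSelectWildtype:
    def test_exact_known_sequence_wins_regardless_of_counts(self):
        exact = SmallRNATag(WT, 3)
        abundant = SmallRNATag(WT[:-1] + "T", 500)
        assert select_wildtype([abundant, exact], WT) is exact

    def test_highest_count_when_no_exact_match(self):
        a = SmallRNATag(WT[:-1] + "T", 50)
        b = SmallRNATag(WT[:-1] + "G", 3)
        assert select_wildtype([b, a], WT[:-2] + "AA") is a

    def test_single_tag_group(self):
        t = SmallRNATag(WT, 1)
        assert select_wildtype([t], "AAAA") is t

    def test_count_tie_breaks_lexicographically(self):
        a = SmallRNATag("A" + WT[1:], 5)
        c = SmallRNATag("C" + WT[1:], 5)
        assert select_wildtype([c, a], "nope") is a


class TestSnpCall:
    def test_single_substitution_called_with_position_and_bases(self):
        variant = WT[:8] + "C" + WT[9:]  # G>C at 1-based position 9
        call = call_mir_snp(WT, variant, 3, "vvi-miR156a")
        assert call.kind == "miR-SNP"
        assert (call.snp_position, call.ref_base, call.alt_base) == (9, "G", "C")

    def test_identical_sequences_no_call(self):
        assert call_mir_snp(WT, WT, 1) is None

    def test_two_substitutions_no_call(self):
        variant = "A" + WT[1:8] + "C" + WT[9:]
        assert call_mir_snp(WT, variant, 1) is None

    def test_length_difference_no_snp_call(self):
        assert call_mir_snp(WT, WT + "A", 1) is None


class TestLdCall:
    def test_five_prime_extension(self):
        call = call_mir_ld(WT, "T" + WT, 2)
        assert (call.kind, call.delta5, call.delta3) == ("miR-LD", 1, 0)

    def test_three_prime_truncation(self):
        call = call_mir_ld(WT, WT[:-2], 2)
        assert (call.delta5, call.delta3) == (0, -2)

    def test_shift_plus_substitution_is_no_ld_call(self):
        variant = "T" + WT[:10] + "C" + WT[11:]
        assert call_mir_ld(WT, variant) is None
        assert call_mir_snp(WT, variant, 1) is None

    def test_shift_beyond_cap_rejected(self):
        assert call_mir_ld(WT, "TTTTT" + WT, 1, max_total_shift=4) is None

    @given(seqs, seqs)
    @settings(max_examples=80, deadline=None)
    def test_snp_and_ld_mutually_exclusive(self, a, b):
        snp = call_mir_snp(a, b, 1)
        ld = call_mir_ld(a, b, 1)
        assert snp is None or ld is None


def _assignments(group_tags, kid="vvi-miR156a", kseq=WT):
    k = KnownMature.from_header(kid, kseq)
    return [ConservedAssignment(t, k, 0, 0, 0) for t in group_tags]


class TestScanVariants:
    def test_single_snp_variant_group(self):
        tags = [SmallRNATag(WT, 100), SmallRNATag(WT[:8] + "C" + WT[9:], 3)]
        scan = scan_variants(_assignments(tags))
        assert [c.kind for c in scan.calls] == ["miR-SNP"]
        assert scan.wildtypes["vvi-miR156a"].sequence == WT

    def test_shift_and_sub_lands_in_other_bucket(self):
        tags = [SmallRNATag(WT, 100), SmallRNATag("T" + WT[:10] + "C" + WT[11:], 2)]
        scan = scan_variants(_assignments(tags))
        assert scan.calls == []
        assert len(scan.other_variants) == 1

    def test_min_read_support_suppresses_singletons(self):
        tags = [SmallRNATag(WT, 100), SmallRNATag(WT[:8] + "C" + WT[9:], 1)]
        scan = scan_variants(_assignments(tags), min_read_support=2)
        assert scan.calls == []

    def test_planted_variants_fully_recovered(self, small_pipeline_state):
        """Closed loop: every planted miR-SNP/miR-LD is called; planted-clean
        miRNAs yield zero calls; wild types dominate their variants."""
        b = small_pipeline_state["bundle"]
        scan = scan_variants(small_pipeline_state["assignments"])
        m = b.truth.mirnas
        snp_called = {(c.wildtype_id, c.variant_seq) for c in scan.calls if c.kind == "miR-SNP"}
        ld_called = {(c.wildtype_id, c.variant_seq) for c in scan.calls if c.kind == "miR-LD"}
        for _, r in m.iterrows():
            if r.has_snp and r.snp_reads >= 1:
                assert (r.mirna_id, r.snp_variant_seq) in snp_called
            if r.has_ld and r.ld_reads >= 1:
                assert (r.mirna_id, r.ld_variant_seq) in ld_called
        clean = set(m[~m.has_snp & ~m.has_ld].mirna_id)
        assert not [c for c in scan.calls if c.wildtype_id in clean]
        for c in scan.calls:
            assert scan.wildtypes[c.wildtype_id].read_count > c.read_count


class TestSnpFamilyDistribution:
    def test_members_and_totals(self):
        calls = [
            VariantCall("miR-SNP", "vvi-miR160a", WT, WT, 1, 5, "A", "C"),
            VariantCall("miR-SNP", "vvi-miR160a", WT, WT, 1, 9, "G", "T"),
            VariantCall("miR-SNP", "vvi-miR160b", WT, WT, 1, 5, "A", "G"),
        ]
        df = snp_family_distribution(calls)
        row = df[df.family == "miR160"].iloc[0]
        assert (row.members_with_snp, row.snp_types) == (2, 3)

    def test_no_calls_gives_empty_distribution(self):
        assert snp_family_distribution([]).empty


class TestSnpVsDuplex:
    def _call(self, mirna, pos, alt):
        variant = mirna[: pos - 1] + alt + mirna[pos:]
        return call_mir_snp(mirna, variant, 1, "x-miR1")

    def test_new_mismatch_at_match_position(self):
        mirna = "TGACAGAAGAGAGGGAGCAC"
        duplex = align_duplex(mirna, revcomp(mirna))
        res = snp_vs_duplex(self._call(mirna, 5, "C"), duplex)  # A->C vs T
        assert res.category == "creates_new_mismatch"

    def test_snp_at_existing_mismatch_position(self):
        mirna = "TGACAGAAGAGAGGGAGCAC"
        site = list(revcomp(mirna))
        site[len(mirna) - 5] = "C"  # position 5 becomes A:C mismatch
        duplex = align_duplex(mirna, "".join(site))
        res = snp_vs_duplex(self._call(mirna, 5, "T"), duplex)
        assert res.category == "at_existing_mismatch"

    def test_pairing_gained_flag_when_alt_restores_pairing(self):
        mirna = "TGACAGAAGAGAGGGAGCAC"
        site = list(revcomp(mirna))
        site[len(mirna) - 5] = "C"  # A:C mismatch at position 5
        duplex = align_duplex(mirna, "".join(site))
        res = snp_vs_duplex(self._call(mirna, 5, "G"), duplex)  # G:C pairs again
        assert res.category == "at_existing_mismatch" and res.pairing_gained

    def test_position_outside_duplex(self):
        mirna = "TGACAGAAGAGAGGGAGCAC"
        duplex = align_duplex(mirna[:15], revcomp(mirna[:15]))
        res = snp_vs_duplex(self._call(mirna, 18, "A"), duplex)
        assert res.category == "outside_duplex"

    def test_truth_table_over_all_base_pairs(self):
        """Exhaustive: every (wild-type base, target base, alt base) combo
        classified consistently with an independent pairing table."""
        pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
        for ref in "ACGT":
            for target in "ACGT":
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    mirna = "CCCC" + ref + "CCCCCCCCCCCC"  # ref at position 5
                    site = list(revcomp(mirna))
                    site[len(mirna) - 5] = target
                    duplex = align_duplex(mirna, "".join(site))
                    res = snp_vs_duplex(self._call(mirna, 5, alt), duplex)
                    ref_pairs = (ref, target) in pairs
                    alt_pairs = (alt, target) in pairs
                    if not ref_pairs:
                        assert res.category == "at_existing_mismatch"
                        assert res.pairing_gained == alt_pairs
                    elif alt_pairs:
                        assert res.category == "pairing_retained"
                    else:
                        assert res.category == "creates_new_mismatch"
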