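"""miR-SNP and miR-LD variant calling against conserved wild types.

Within the group of tags assigned to one conserved miRNA, the wild type is
the tag equal to the known mature sequence (or, failing that, the most
abundant tag).  Every other tag is tested as a single-substitution variant
(miR-SNP: equal length, Hamming distance exactly 1) and then as a length
variant (miR-LD: substitution-free ungapped overlap with nonzero terminal
shifts).  A tag combining a shift and a substitution is neither — it goes
to an ``other_variant`` bucket uncounted by either statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from ._util import base_pairs
from .conserved import ConservedAssignment, parse_family
from .sequence_io import SmallRNATag

__all__ = [
    "VariantCall",
    "select_wildtype",
    "call_mir_snp",
    "call_mir_ld",
    "scan_variants",
    "snp_family_distribution",
    "snp_vs_duplex",
    "SnpDuplexResult",
]


@dataclass
class VariantCall:
    kind: Literal["miR-SNP", "miR-LD", "other_variant"]
    wildtype_id: str
    wildtype_seq: str
    variant_seq: str
    read_count: int
    # miR-SNP fields (1-based from the miRNA 5' end)
    snp_position: int | None = None
    ref_base: str | None = None
    alt_base: str | None = None
    # miR-LD fields (positive = extension relative to wild type)
    delta5: int | None = None
    delta3: int | None = None


def select_wildtype(group: Sequence[SmallRNATag], known_seq: str) -> SmallRNATag | None:
    """Wild type of a conserved group: the exact known mature sequence if
    sequenced, else the highest-read-count tag (ties: lexicographic)."""
    if not group:
        return None
    for tag in group:
        if tag.sequence == known_seq:
            return tag
    return min(group, key=lambda t: (-t.read_count, t.sequence))


def call_mir_snp(
    wildtype_seq: str, variant_seq: str, read_count: int = 1, wildtype_id: str = ""
) -> VariantCall | None:
    """Single-substitution variant: equal length, Hamming distance exactly 1."""
    if len(wildtype_seq) != len(variant_seq):
        return None
    diffs = [i for i, (a, b) in enumerate(zip(wildtype_seq, variant_seq)) if a != b]
    if len(diffs) != 1:
        return None
    i = diffs[0]
    return VariantCall(
        kind="miR-SNP",
        wildtype_id=wildtype_id,
        wildtype_seq=wildtype_seq,
        variant_seq=variant_seq,
        read_count=read_count,
        snp_position=i + 1,
        ref_base=wildtype_seq[i],
        alt_base=variant_seq[i],
    )


def call_mir_ld(
    wildtype_seq: str,
    variant_seq: str,
    read_count: int = 1,
    wildtype_id: str = "",
    max_total_shift: int = 4,
) -> VariantCall | None:
    """Length variant: ungapped alignment with a substitution-free overlap
    and nonzero terminal shifts, total |delta5|+|delta3| <= cap.

    delta5/delta3 are signed: positive = the variant extends beyond the
    wild-type end.  Among valid alignments the one with the longest
    substitution-free overlap (then smallest total shift) is taken.
    """
    if wildtype_seq == variant_seq:
        return None
    lw, lv = len(wildtype_seq), len(variant_seq)
    best = None  # key (-overlap, total_shift, delta5); value (delta5, delta3)
    for s in range(-(lw - 1), lv):
        # variant[i] aligns wildtype[i - s]; s = nt the variant adds at 5'
        start_v = max(0, s)
        end_v = min(lv, lw + s)
        overlap = end_v - start_v
        if overlap <= 0:
            continue
        if any(
            variant_seq[i] != wildtype_seq[i - s] for i in range(start_v, end_v)
        ):
            continue
        delta5 = s
        delta3 = (lv - end_v) - (lw - (end_v - s))
        if (delta5, delta3) == (0, 0):
            continue
        total = abs(delta5) + abs(delta3)
        if total > max_total_shift:
            continue
        key = (-overlap, total, delta5)
        if best is None or key < best[0]:
            best = (key, (delta5, delta3))
    if best is None:
        return None
    delta5, delta3 = best[1]
    return VariantCall(
        kind="miR-LD",
        wildtype_id=wildtype_id,
        wildtype_seq=wildtype_seq,
        variant_seq=variant_seq,
        read_count=read_count,
        delta5=delta5,
        delta3=delta3,
    )


@dataclass
class VariantScan:
    calls: list[VariantCall]
    other_variants: list[VariantCall]
    wildtypes: dict[str, SmallRNATag]

    def per_mirna_table(self) -> pd.DataFrame:
        counts: dict[str, dict[str, int]] = {}
        for wid, wt in self.wildtypes.items():
            counts[wid] = {"wildtype_reads": wt.read_count, "snp_types": 0, "ld_types": 0}
        for call in self.calls:
            key = "snp_types" if call.kind == "miR-SNP" else "ld_types"
            counts[call.wildtype_id][key] += 1
        return (
            pd.DataFrame.from_dict(counts, orient="index")
            .rename_axis("mirna")
            .sort_index()
        )


def scan_variants(
    assignments: Sequence[ConservedAssignment],
    min_read_support: int = 1,
) -> VariantScan:
    """Call variants within each conserved miRNA's tag group.

    Every non-wild-type tag is tested as miR-SNP, then miR-LD; a tag that
    qualifies as neither (shift plus substitution) is bucketed as
    ``other_variant``.  No (wildtype, variant) pair yields both call kinds.
    """
    groups: dict[str, list[SmallRNATag]] = {}
    known_seq: dict[str, str] = {}
    for a in assignments:
        groups.setdefault(a.known.id, []).append(a.tag)
        known_seq[a.known.id] = a.known.sequence
    calls: list[VariantCall] = []
    others: list[VariantCall] = []
    wildtypes: dict[str, SmallRNATag] = {}
    for wid in sorted(groups):
        group = groups[wid]
        wt = select_wildtype(group, known_seq[wid])
        wildtypes[wid] = wt
        for tag in sorted(group, key=lambda t: (-t.read_count, t.sequence)):
            if tag is wt or tag.read_count < min_read_support:
                continue
            call = call_mir_snp(wt.sequence, tag.sequence, tag.read_count, wid)
            if call is None:
                call = call_mir_ld(wt.sequence, tag.sequence, tag.read_count, wid)
            if call is None:
                others.append(
                    VariantCall(
                        kind="other_variant",
                        wildtype_id=wid,
                        wildtype_seq=wt.sequence,
                        variant_seq=tag.sequence,
                        read_count=tag.read_count,
                    )
                )
            else:
                calls.append(call)
    return VariantScan(calls, others, wildtypes)


def snp_family_distribution(calls: Sequence[VariantCall]) -> pd.DataFrame:
    """Per-family: members carrying >=1 SNP and total SNP types, sorted
    descending by total (ties: family label)."""
    members: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for call in calls:
        if call.kind != "miR-SNP":
            continue
        fam = parse_family(call.wildtype_id)
        members.setdefault(fam, set()).add(call.wildtype_id)
        totals[fam] = totals.get(fam, 0) + 1
    rows = [
        {"family": fam, "members_with_snp": len(members[fam]), "snp_types": totals[fam]}
        for fam in totals
    ]
    df = pd.DataFrame(rows, columns=["family", "members_with_snp", "snp_types"])
    return df.sort_values(
        ["snp_types", "family"], ascending=[False, True], ignore_index=True
    )


@dataclass
class SnpDuplexResult:
    category: Literal[
        "creates_new_mismatch", "at_existing_mismatch", "pairing_retained", "outside_duplex"
    ]
    pairing_gained: bool = False


def snp_vs_duplex(call: VariantCall, duplex) -> SnpDuplexResult:
    """Classify a miR-SNP site against a miRNA:target duplex alignment.

    ``duplex`` is a DuplexAlignment (targets module): per-miRNA-position
    pairing states with the opposing target base.  A SNP at a paired
    position (match or G:U) whose alt base no longer pairs creates a new
    mismatch; a SNP at an already-mismatched position sits at an existing
    mismatch (flagged ``pairing_gained`` when the alt base restores
    pairing); a SNP whose alt base still pairs at a paired position is
    ``pairing_retained``.
    """
    if call.snp_position is None:
        raise ValueError("snp_vs_duplex requires a miR-SNP call")
    state = duplex.state_at(call.snp_position)
    if state is None or state.state in {"bulge_mirna", "bulge_target"}:
        return SnpDuplexResult("outside_duplex")
    alt_pairs = base_pairs(call.alt_base, state.target_base)
    if state.state == "mismatch":
        return SnpDuplexResult("at_existing_mismatch", pairing_gained=alt_pairs)
    # wild-type position paired (match or G:U wobble)
    if alt_pairs:
        return SnpDuplexResult("pairing_retained")
    return SnpDuplexResult("creates_new_mismatch")
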