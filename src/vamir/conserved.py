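"""Conserved-miRNA assignment, family abundance, and ortholog divergence.

Tags are matched against a known mature set (miRBase-style FASTA) by
ungapped, mismatch-tolerant containment: the shorter sequence must lie
within the longer with a small total terminal overhang, and at most a
configured number of substitutions in the overlap (default 3, the usual
"0-3 mismatches" conservation rule).  Terminal shifts between orthologous
matures are quantified separately as 5'/3' divergence, not as mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._util import ConfigError, InputError, normalize_rna
from .sequence_io import SmallRNATag

__all__ = [
    "KnownMature",
    "ConservedAssignment",
    "OrthologDivergence",
    "read_mature_fasta",
    "parse_family",
    "match_known",
    "family_abundance",
    "terminal_divergence",
    "family_presence_matrix",
]

_FAMILY_RE = re.compile(r"(miR)[-]?(\d+)", re.IGNORECASE)


def parse_family(mirna_id: str) -> str:
    """Family label from an id stem: ``vvi-miR156a`` -> ``miR156``.

    The numeric stem defines the family; letter suffixes (members) and
    species prefixes are ignored.
    """
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        raise InputError(f"cannot parse miRNA family from id {mirna_id!r}")
    return f"miR{m.group(2)}"


@dataclass(frozen=True)
class KnownMature:
    id: str
    sequence: str
    species: str = ""
    family: str = ""

    @staticmethod
    def from_header(identifier: str, sequence: str) -> "KnownMature":
        species = identifier.split("-", 1)[0] if "-" in identifier else ""
        return KnownMature(
            id=identifier,
            sequence=normalize_rna(sequence),
            species=species,
            family=parse_family(identifier),
        )


@dataclass
class ConservedAssignment:
    tag: SmallRNATag
    known: KnownMature
    substitutions: int
    offset5: int
    offset3: int


@dataclass
class OrthologDivergence:
    id_a: str
    id_b: str
    d5: int
    d3: int
    internal_substitutions: int
    core_length: int

    @property
    def total_terminal(self) -> int:
        return self.d5 + self.d3


def read_mature_fasta(path: str | Path) -> list[KnownMature]:
    return [
        KnownMature.from_header(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def _align_contained(tag_seq: str, known_seq: str):
    """Enumerate ungapped containment alignments of the shorter in the longer.

    Yields (substitutions, offset5, offset3) where offsets are signed nt of
    the tag's 5'/3' ends relative to the known sequence ends (positive =
    tag extends beyond the known end).
    """
    lt, lk = len(tag_seq), len(known_seq)
    if lt <= lk:
        for s in range(lk - lt + 1):
            subs = sum(1 for a, b in zip(tag_seq, known_seq[s : s + lt]) if a != b)
            yield subs, -s, -(lk - lt - s)
    else:
        for s in range(lt - lk + 1):
            subs = sum(1 for a, b in zip(known_seq, tag_seq[s : s + lk]) if a != b)
            yield subs, s, lt - lk - s


def match_known(
    tags: Sequence[SmallRNATag],
    known_set: Sequence[KnownMature],
    max_substitutions: int = 3,
    terminal_slack: int = 3,
) -> list[ConservedAssignment]:
    """Best conserved assignment per tag, or none.

    Best = fewest substitutions in the overlap; ties broken by smallest
    |offset5|+|offset3|, then lexicographically smallest known id
    (deterministic).  Only tags with an assignment are returned.
    """
    if not known_set:
        raise ConfigError("empty known mature set")
    assignments = []
    for tag in tags:
        best = None  # (subs, slack, id, offset5, offset3, known)
        for known in known_set:
            for subs, off5, off3 in _align_contained(tag.sequence, known.sequence):
                slack = abs(off5) + abs(off3)
                if subs > max_substitutions or slack > terminal_slack:
                    continue
                key = (subs, slack, known.id)
                if best is None or key < best[:3]:
                    best = (subs, slack, known.id, off5, off3, known)
        if best is not None:
            assignments.append(
                ConservedAssignment(tag, best[5], best[0], best[3], best[4])
            )
    return assignments


def family_abundance(assignments: Sequence[ConservedAssignment]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-member and per-family read-count tables (deterministic order)."""
    rows = [
        {
            "member": a.known.id,
            "family": a.known.family,
            "reads": a.tag.read_count,
        }
        for a in assignments
    ]
    if not rows:
        empty_m = pd.DataFrame(columns=["member", "family", "reads"]).set_index("member")
        empty_f = pd.DataFrame(columns=["family", "reads"]).set_index("family")
        return empty_m, empty_f
    df = pd.DataFrame(rows)
    members = (
        df.groupby(["member", "family"], as_index=False)["reads"].sum().set_index("member").sort_index()
    )
    families = members.groupby("family")["reads"].sum().sort_index().to_frame()
    return members, families


def terminal_divergence(seq_a: str, seq_b: str) -> OrthologDivergence:
    """Terminal 5'/3' divergence between two mature sequences.

    Over all ungapped relative offsets, the alignment maximizing the number
    of matching core bases is chosen (ties: fewest internal substitutions,
    then smallest d5).  d5/d3 are the unmatched terminal lengths summed
    over both sequences at each end.
    """
    seq_a = normalize_rna(seq_a)
    seq_b = normalize_rna(seq_b)
    if not seq_a or not seq_b:
        raise InputError("empty sequence in terminal_divergence")
    la, lb = len(seq_a), len(seq_b)
    best = None  # key: (-matches, subs, d5); value: (d5, d3, subs, core)
    for s in range(-(lb - 1), la):
        # a[i] aligns b[i-s]
        start_a = max(0, s)
        end_a = min(la, lb + s)
        core = end_a - start_a
        if core <= 0:
            continue
        subs = sum(
            1 for i in range(start_a, end_a) if seq_a[i] != seq_b[i - s]
        )
        matches = core - subs
        d5 = abs(s)
        d3 = abs((la - end_a) - (lb - (end_a - s)))
        key = (-matches, subs, d5)
        if best is None or key < best[0]:
            best = (key, (d5, d3, subs, core))
    d5, d3, subs, core = best[1]
    return OrthologDivergence("a", "b", d5, d3, subs, core)


def divergence_table(pairs: Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    """Per-pair divergence table from (label, seq_a, seq_b) triples."""
    rows = []
    for label, a, b in pairs:
        d = terminal_divergence(a, b)
        rows.append(
            {
                "id": label,
                "seq_a": normalize_rna(a),
                "seq_b": normalize_rna(b),
                "d5": d.d5,
                "d3": d.d3,
                "subs": d.internal_substitutions,
                "total_terminal": d.total_terminal,
            }
        )
    return pd.DataFrame(rows)


def family_presence_matrix(
    families: Sequence[str], species_mature_sets: Mapping[str, Sequence[KnownMature]]
) -> pd.DataFrame:
    """Family x species presence matrix (True where the species' supplied
    mature set contains at least one member of the family)."""
    data = {}
    for species, matures in species_mature_sets.items():
        present = {parse_family(m.id) for m in matures}
        data[species] = [fam in present for fam in families]
    return pd.DataFrame(data, index=list(families))


def write_presence_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.replace({True: "+", False: "-"}).to_csv(path, sep="\t")
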