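"""Genome placement and annotation-category accounting for unique tags.

Tags are placed on the genome by exact, ungapped, full-length matching on
both strands, then partitioned into a single category each (rRNA, tRNA,
exon_sense, ... , unann) with unique/redundant count summaries.  Category
assignment is a strict precedence partition so that every mapped tag lands
in exactly one row and the column sums reproduce the library totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

from ._util import ConfigError, normalize_rna, percent, revcomp
from .sequence_io import SmallRNATag

__all__ = [
    "GenomeLocus",
    "AnnotationTrack",
    "CATEGORIES",
    "CATEGORY_PRECEDENCE",
    "load_genome",
    "map_to_genome",
    "read_gff3_tracks",
    "classify_tags",
    "summarize_categories",
]

# Controlled category vocabulary, in the conventional report row order.
CATEGORIES = [
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "miRNA",
    "rRNA",
    "repeat",
    "siRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "unann",
]

# Structural-RNA contamination must not be absorbed by gene-model
# categories; miRNA first because it is assigned by sequence matching.
CATEGORY_PRECEDENCE = [
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "repeat",
    "siRNA",
    "exon",
    "intron",
    "unann",
]


@dataclass(frozen=True)
class GenomeLocus:
    """1-based inclusive coordinates, strand + or -."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class AnnotationTrack:
    category: str
    features: list[GenomeLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in {"exon", "intron", "rRNA", "tRNA", "snRNA", "snoRNA", "repeat"}:
            raise ConfigError(f"unknown track category {self.category!r}")
        self.features.sort(key=lambda f: (f.chromosome, f.start))


def load_genome(path: str | Path) -> dict[str, str]:
    genome = {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise ConfigError(f"no sequences in genome file {path}")
    return genome


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def map_to_genome(tags: Sequence[SmallRNATag], genome: Mapping[str, str]) -> list[SmallRNATag]:
    """Record every exact full-length occurrence of each tag on both strands.

    Forward matches get strand +, reverse-complement matches strand -.
    Tags with zero occurrences keep an empty locus list (unmapped).
    Returns the same tag objects with ``loci`` populated.
    """
    if not genome:
        raise ConfigError("empty genome")
    chrom_names = sorted(genome)
    for tag in tags:
        loci = []
        rc = revcomp(tag.sequence)
        for chrom in chrom_names:
            seq = genome[chrom]
            for i in _find_all(seq, tag.sequence):
                loci.append(GenomeLocus(chrom, i + 1, i + tag.length, "+"))
            for i in _find_all(seq, rc):
                loci.append(GenomeLocus(chrom, i + 1, i + tag.length, "-"))
        tag.loci = loci
    return list(tags)


# GFF3 feature types folded into the track vocabulary.
DEFAULT_GFF_TYPE_MAP = {
    "exon": "exon",
    "intron": "intron",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "repeat": "repeat",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
}


def read_gff3_tracks(
    path: str | Path, type_map: Mapping[str, str] | None = None
) -> list[AnnotationTrack]:
    """Read annotation features from GFF3 (1-based inclusive, as native).

    ``type_map`` maps GFF3 feature types onto the track vocabulary;
    unmapped feature types are ignored.
    """
    type_map = dict(DEFAULT_GFF_TYPE_MAP if type_map is None else type_map)
    by_cat: dict[str, list[GenomeLocus]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                continue
            ftype = cols[2]
            if ftype not in type_map:
                continue
            cat = type_map[ftype]
            strand = cols[6] if cols[6] in {"+", "-"} else "+"
            by_cat.setdefault(cat, []).append(
                GenomeLocus(cols[0], int(cols[3]), int(cols[4]), strand)
            )
    return [AnnotationTrack(cat, feats) for cat, feats in sorted(by_cat.items())]


def _build_trees(tracks: Sequence[AnnotationTrack]) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for track in tracks:
        per_chrom = trees.setdefault(track.category, {})
        for feat in track.features:
            per_chrom.setdefault(feat.chromosome, IntervalTree()).addi(
                feat.start, feat.end + 1, feat.strand
            )
    return trees


def classify_tags(
    tags: Sequence[SmallRNATag],
    tracks: Sequence[AnnotationTrack],
    known_mirna_hits: set[str] | frozenset[str] = frozenset(),
    sirna_rule: bool = True,
) -> dict[str, str]:
    """Assign exactly one category per tag (keyed by tag sequence).

    Precedence: miRNA > rRNA > tRNA > snRNA > snoRNA > repeat > siRNA >
    exon > intron > unann.  The miRNA category is sequence-based (tags in
    ``known_mirna_hits``); exon/intron split into sense/antisense by tag
    strand vs feature strand; a multi-locus tag is classified once by the
    highest-precedence category over all its loci.  The siRNA category is
    a documented stand-in: a 21-24 nt tag whose locus overlaps, on the
    opposite strand, a locus of another mapped tag.
    """
    trees = _build_trees(tracks)

    # opposite-strand tag overlap index for the siRNA rule
    tag_trees: dict[str, IntervalTree] = {}
    if sirna_rule:
        for tag in tags:
            for loc in tag.loci:
                tag_trees.setdefault(loc.chromosome, IntervalTree()).addi(
                    loc.start, loc.end + 1, (tag.sequence, loc.strand)
                )

    def locus_categories(tag: SmallRNATag, loc: GenomeLocus) -> set[str]:
        cats = set()
        for cat, per_chrom in trees.items():
            tree = per_chrom.get(loc.chromosome)
            if tree is None:
                continue
            for iv in tree.overlap(loc.start, loc.end + 1):
                if cat in {"exon", "intron"}:
                    rel = "sense" if iv.data == loc.strand else "antisense"
                    cats.add(f"{cat}_{rel}")
                else:
                    cats.add(cat)
        if sirna_rule and 21 <= tag.length <= 24:
            tree = tag_trees.get(loc.chromosome)
            if tree is not None:
                for iv in tree.overlap(loc.start, loc.end + 1):
                    other_seq, other_strand = iv.data
                    if other_strand != loc.strand and other_seq != tag.sequence:
                        cats.add("siRNA")
                        break
        return cats

    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}

    def base(cat: str) -> str:
        return cat.split("_")[0]

    assignments: dict[str, str] = {}
    for tag in tags:
        if tag.sequence in known_mirna_hits:
            assignments[tag.sequence] = "miRNA"
            continue
        if not tag.loci:
            assignments[tag.sequence] = "unann"
            continue
        cats: set[str] = set()
        for loc in tag.loci:
            cats |= locus_categories(tag, loc)
        if not cats:
            assignments[tag.sequence] = "unann"
        else:
            # highest precedence; sense beats antisense only via precedence tie
            assignments[tag.sequence] = min(cats, key=lambda c: (rank[base(c)], c))
    return assignments


def summarize_categories(
    tags: Sequence[SmallRNATag], assignments: Mapping[str, str]
) -> pd.DataFrame:
    """Unique/redundant counts and 2-decimal percentages per category.

    Returns a DataFrame indexed by category (fixed row order) with a
    Total row; unique counts sum to the number of tags, redundant counts
    to the total read number.
    """
    unique: dict[str, int] = {c: 0 for c in CATEGORIES}
    redundant: dict[str, int] = {c: 0 for c in CATEGORIES}
    for tag in tags:
        cat = assignments[tag.sequence]
        unique[cat] += 1
        redundant[cat] += tag.read_count
    return summarize_category_counts(unique, redundant)


def summarize_category_counts(
    unique: Mapping[str, int], redundant: Mapping[str, int]
) -> pd.DataFrame:
    """Build the category summary table from raw per-category counts."""
    total_u = sum(unique.values())
    total_r = sum(redundant.values())
    rows = []
    for cat in CATEGORIES:
        u = unique.get(cat, 0)
        r = redundant.get(cat, 0)
        rows.append(
            {
                "category": cat,
                "unique_count": u,
                "unique_percent": percent(u, total_u) if total_u else 0.0,
                "redundant_count": r,
                "redundant_percent": percent(r, total_r) if total_r else 0.0,
            }
        )
    rows.append(
        {
            "category": "Total",
            "unique_count": total_u,
            "unique_percent": 100.0,
            "redundant_count": total_r,
            "redundant_percent": 100.0,
        }
    )
    return pd.DataFrame(rows).set_index("category")
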