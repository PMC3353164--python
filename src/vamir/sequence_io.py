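"""Raw small-RNA read handling: adapter trimming, filtering, collapsing.

A sequencing library is turned into *unique tags* — distinct insert
sequences, each carrying its redundant read count — which is the unit the
rest of the pipeline operates on.  The unique/redundant dichotomy mirrors
the standard small-RNA accounting (distinct sequences vs total reads).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._util import ConfigError, normalize_rna

__all__ = [
    "RawRead",
    "SmallRNATag",
    "LengthHistogram",
    "read_reads",
    "trim_adapters",
    "quality_filter",
    "length_filter",
    "polya_filter",
    "collapse_reads",
    "length_distribution",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
]

MIN_TAG_LEN = 15
MAX_TAG_LEN = 30


@dataclass
class RawRead:
    identifier: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for read {self.identifier!r}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"quality length mismatch for read {self.identifier!r}")


@dataclass
class SmallRNATag:
    """A collapsed unique sequence with its redundant count and genome placements."""

    sequence: str
    read_count: int
    loci: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LengthHistogram:
    """Read-count-weighted length distribution over 15-30 nt."""

    unique_counts: dict[int, int]
    redundant_counts: dict[int, int]

    @property
    def total_reads(self) -> int:
        return sum(self.redundant_counts.values())

    def fractions(self) -> dict[int, float]:
        total = self.total_reads
        if total == 0:
            return {}
        return {n: c / total for n, c in sorted(self.redundant_counts.items())}

    def mode(self) -> int:
        # deterministic: smallest length wins ties
        return min(self.redundant_counts, key=lambda n: (-self.redundant_counts[n], n))


def read_reads(path: str | Path) -> list[RawRead]:
    """Load FASTQ (phred+33) or FASTA reads, normalizing U->T."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality") if fmt == "fastq" else None
        reads.append(RawRead(rec.id, normalize_rna(str(rec.seq)), list(qual) if qual else None))
    return reads


def _best_prefix_overlap(seq: str, adapter: str, min_overlap: int, max_mismatch_rate: float) -> int | None:
    """Start index of the best occurrence of a prefix of ``adapter`` as a
    suffix-anchored block of ``seq`` (semi-global 3' adapter search).

    The adapter prefix may run past the read end.  Best = most matching
    bases; ties broken toward the leftmost (longest adapter, shortest
    insert) occurrence.  Returns None when nothing satisfies the overlap
    and mismatch-rate constraints.
    """
    best = None  # (score, start)
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, len(adapter))
        if overlap < min_overlap:
            break
        mism = sum(1 for a, b in zip(seq[start : start + overlap], adapter) if a != b)
        if mism > max_mismatch_rate * overlap:
            continue
        score = overlap - 2 * mism
        if best is None or score > best[0]:
            best = (score, start)
    return None if best is None else best[1]


def trim_adapters(
    reads: Iterable[RawRead],
    adapter3: str,
    adapter5: str = "",
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> list[RawRead]:
    """Remove 3' (and optionally 5') adapter sequence from each read.

    Reads in which no 3' adapter occurrence is found are discarded: without
    the adapter boundary the insert length is unknown (the insert may run
    past the read end).  Order is preserved.
    """
    if not adapter3:
        raise ConfigError("3' adapter must be non-empty")
    if min_overlap < 1:
        raise ConfigError("min_overlap must be >= 1")
    adapter3 = normalize_rna(adapter3)
    adapter5 = normalize_rna(adapter5)
    out: list[RawRead] = []
    for read in reads:
        start = _best_prefix_overlap(read.sequence, adapter3, min_overlap, max_mismatch_rate)
        if start is None:
            continue
        seq = read.sequence[:start]
        qual = read.quality[:start] if read.quality is not None else None
        if adapter5 and seq:
            # 5' adapter: a suffix of the adapter matching the read prefix
            cut = 0
            for overlap in range(min(len(seq), len(adapter5)), min_overlap - 1, -1):
                mism = sum(1 for a, b in zip(seq[:overlap], adapter5[-overlap:]) if a != b)
                if mism <= max_mismatch_rate * overlap:
                    cut = overlap
                    break
            seq = seq[cut:]
            qual = qual[cut:] if qual is not None else None
        if seq:
            out.append(RawRead(read.identifier, seq, qual))
        elif start == 0:
            # degenerate insert (read was pure adapter): keep an empty-marker
            # out of the stream; downstream length filters would drop it anyway
            continue
    return out


def quality_filter(
    reads: Iterable[RawRead],
    min_mean_quality: float = 20.0,
    max_n_fraction: float = 0.0,
) -> list[RawRead]:
    """Drop reads with low mean base quality or too many ambiguous bases.

    Reads without quality strings (FASTA input) are filtered on N content only.
    """
    out = []
    for read in reads:
        n_frac = read.sequence.count("N") / len(read.sequence)
        if n_frac > max_n_fraction:
            continue
        if read.quality is not None and sum(read.quality) / len(read.quality) < min_mean_quality:
            continue
        out.append(read)
    return out


def length_filter(items: Sequence, min_len: int = 18, max_len: int = 30) -> list:
    """Keep reads or tags whose sequence length is within [min_len, max_len]."""
    if min_len > max_len:
        raise ConfigError(f"min_len {min_len} > max_len {max_len}")
    return [x for x in items if min_len <= len(x.sequence) <= max_len]


def polya_filter(items: Sequence, max_a_fraction: float = 0.8, max_terminal_a_run: int = 8) -> list:
    """Drop poly-A artifacts: >=80% A content or a terminal run of >=8 A's."""
    out = []
    for x in items:
        seq = x.sequence
        if seq.count("A") / len(seq) >= max_a_fraction:
            continue
        run = len(seq) - len(seq.rstrip("A"))
        if run >= max_terminal_a_run:
            continue
        out.append(x)
    return out


def collapse_reads(reads: Iterable[RawRead]) -> list[SmallRNATag]:
    """Collapse reads into unique tags; counts conserve the total read number.

    Order is deterministic: descending read count, then lexicographic sequence.
    """
    counts = Counter(read.sequence for read in reads)
    return [
        SmallRNATag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def length_distribution(tags: Sequence[SmallRNATag]) -> LengthHistogram:
    if not tags:
        raise ValueError("length_distribution of an empty tag set")
    unique: Counter = Counter()
    redundant: Counter = Counter()
    for tag in tags:
        unique[tag.length] += 1
        redundant[tag.length] += tag.read_count
    return LengthHistogram(dict(unique), dict(redundant))


def write_collapsed_fasta(tags: Sequence[SmallRNATag], path: str | Path) -> None:
    """Write the common collapsed dialect: headers ``tag{serial}_x{count}``."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, 1):
            fh.write(f">tag{i}_x{tag.read_count}\n{tag.sequence}\n")


def read_collapsed_fasta(path: str | Path) -> list[SmallRNATag]:
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            try:
                count = int(rec.id.rsplit("_x", 1)[1])
            except ValueError:
                pass
        tags.append(SmallRNATag(normalize_rna(str(rec.seq)), count))
    return tags


def write_length_histogram(hist: LengthHistogram, path: str | Path) -> None:
    total = hist.total_reads
    with open(path, "w") as fh:
        fh.write("length\tunique_count\tredundant_count\tredundant_fraction\n")
        for n in sorted(hist.redundant_counts):
            fh.write(
                f"{n}\t{hist.unique_counts.get(n, 0)}\t{hist.redundant_counts[n]}"
                f"\t{hist.redundant_counts[n] / total:.6f}\n"
            )
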