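"""Novel miRNA discovery: precursor excision, folding, and adjudication.

Candidate matures (mapped, unannotated tags) have genomic windows excised
around them, folded into a minimum-energy nested secondary structure, and
judged against the standard hairpin criteria for plant miRNA annotation:
a sufficiently stable fold, the mature entirely on one arm of a single
stem-loop, few unpaired mature bases, a plausible precursor length, and
(as supporting evidence, not a gate) a sequenced miRNA* — the duplex
partner on the opposite arm with 2-nt 3' overhangs.

The built-in folding engine is a deliberately simple stacking-weighted
base-pair maximization (dynamic programming, nested structures only):
a pair stacked directly on another pair contributes -3 (G:C), -2 (A:U) or
-1 (G:U) kcal/mol, each hairpin loop costs +4, minimum loop 3 nt.  It is
not ViennaRNA-compatible and does not claim thermodynamic realism; an
external engine emitting dot-bracket + MFE can be plugged in.
"""

from __future__ import annotations

import subprocess
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from ._util import InputError, revcomp
from .annotate import GenomeLocus
from .conserved import KnownMature, _align_contained
from .sequence_io import SmallRNATag

__all__ = [
    "FoldResult",
    "HairpinCandidate",
    "CriteriaConfig",
    "fold",
    "structure_energy",
    "excise_precursor_windows",
    "evaluate_candidate",
    "select_best_candidate",
    "star_sequence",
    "five_prime_composition",
    "classify_novelty",
    "ExternalFoldEngine",
]

_INF = 1e9
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
MIN_LOOP = 3

# base-pair stacking weights, kcal/mol (indices per _ENC)
_PAIR_W = np.full((4, 4), 0.0)
_PAIRABLE = np.zeros((4, 4), dtype=np.bool_)
for _a, _b, _w in [("G", "C", -3.0), ("C", "G", -3.0), ("A", "T", -2.0), ("T", "A", -2.0), ("G", "T", -1.0), ("T", "G", -1.0)]:
    _PAIR_W[_ENC[_a], _ENC[_b]] = _w
    _PAIRABLE[_ENC[_a], _ENC[_b]] = True

HAIRPIN_LOOP_PENALTY = 4.0


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise InputError(f"non-ACGT character in fold input: {exc}") from None


@njit(cache=True)
def _fill(enc, pairable, pair_w):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    V = np.full((n, n), _INF)
    Wp = np.full((n, n), _INF)
    W = np.zeros((n, n))
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            # V: minimum energy with (i, j) paired
            if pairable[enc[i], enc[j]]:
                best = HAIRPIN_LOOP_PENALTY
                if V[i + 1, j - 1] < _INF:
                    cand = V[i + 1, j - 1] + pair_w[enc[i], enc[j]]
                    if cand < best:
                        best = cand
                if Wp[i + 1, j - 1] < best:
                    best = Wp[i + 1, j - 1]
                V[i, j] = best
            # Wp: minimum energy with at least one pair in i..j
            best = Wp[i, j - 1]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                if V[k, j] < _INF:
                    left = W[i, k - 1] if k > i else 0.0
                    cand = V[k, j] + left
                    if cand < best:
                        best = cand
            Wp[i, j] = best
            W[i, j] = best if best < 0.0 else 0.0
    return V, Wp, W


@dataclass
class FoldResult:
    sequence: str
    structure: str
    mfe: float
    pair_table: dict[int, int]  # 0-based position <-> partner, both directions

    def partner(self, i: int) -> int | None:
        return self.pair_table.get(i)


def structure_energy(sequence: str, pairs: Sequence[tuple[int, int]]) -> float:
    """Energy of an explicit nested structure under the built-in model.

    ``pairs`` are 0-based (i, j) with i < j.  A pair contributes its weight
    when the immediately inner (i+1, j-1) pair is also present (stacking);
    each hairpin loop (a pair enclosing no other pair) costs +4.
    """
    pair_set = set(pairs)
    energy = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pair_set:
            energy += _PAIR_W[_ENC[sequence[i]], _ENC[sequence[j]]]
        if not any(i < a and b < j for a, b in pair_set):
            energy += HAIRPIN_LOOP_PENALTY
    return energy


def _traceback(enc, V, Wp, W, pair_w, pairable):
    n = enc.shape[0]
    pairs: list[tuple[int, int]] = []

    def trace_W(i, j):
        if j - i < MIN_LOOP + 1:
            return
        if Wp[i, j] < 0.0:
            trace_Wp(i, j)

    def trace_Wp(i, j):
        while j - i >= MIN_LOOP + 1:
            if abs(Wp[i, j] - Wp[i, j - 1]) < 1e-9 and Wp[i, j - 1] < _INF:
                j -= 1
                continue
            target = Wp[i, j]
            for k in range(i, j - MIN_LOOP):
                if V[k, j] >= _INF:
                    continue
                left = W[i, k - 1] if k > i else 0.0
                if abs(V[k, j] + left - target) < 1e-9:
                    trace_V(k, j)
                    if k > i and W[i, k - 1] < 0.0:
                        trace_Wp(i, k - 1)
                    return
            return  # numerically unreachable
        return

    def trace_V(i, j):
        while True:
            pairs.append((i, j))
            stacked = (
                V[i + 1, j - 1] < _INF
                and abs(V[i + 1, j - 1] + pair_w[enc[i], enc[j]] - V[i, j]) < 1e-9
            )
            if stacked:
                i, j = i + 1, j - 1
                continue
            if Wp[i + 1, j - 1] < _INF and abs(Wp[i + 1, j - 1] - V[i, j]) < 1e-9:
                trace_Wp(i + 1, j - 1)
            return  # hairpin loop otherwise

    if n >= MIN_LOOP + 2 and Wp[0, n - 1] < 0.0:
        trace_Wp(0, n - 1)
    return pairs


def fold(sequence: str, engine=None) -> FoldResult:
    """Minimum-energy nested structure of ``sequence``.

    With the built-in engine the optimum over all nested structures under
    the stacking-weighted model is returned; an empty structure (mfe 0) is
    returned when no structure has negative energy.  ``engine`` may be an
    ExternalFoldEngine for tool-backed folding.
    """
    if engine is not None:
        return engine.fold(sequence)
    enc = _encode(sequence)
    n = len(sequence)
    if n < MIN_LOOP + 2:
        return FoldResult(sequence, "." * n, 0.0, {})
    V, Wp, W = _fill(enc, _PAIRABLE, _PAIR_W)
    if Wp[0, n - 1] >= 0.0:
        return FoldResult(sequence, "." * n, 0.0, {})
    pairs = _traceback(enc, V, Wp, W, _PAIR_W, _PAIRABLE)
    structure = ["."] * n
    table: dict[int, int] = {}
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
        table[i], table[j] = j, i
    return FoldResult(sequence, "".join(structure), float(Wp[0, n - 1]), table)


class ExternalFoldEngine:
    """Plug-in contract: an executable consuming FASTA on stdin and
    emitting ``sequence`` / ``dot-bracket (mfe)`` line pairs (the RNAfold
    output dialect)."""

    def __init__(self, command: Sequence[str]):
        self.command = list(command)

    def fold(self, sequence: str) -> FoldResult:
        proc = subprocess.run(
            self.command,
            input=f">q\n{sequence}\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = [ln.strip() for ln in proc.stdout.splitlines() if ln.strip() and not ln.startswith(">")]
        if len(lines) < 2:
            raise InputError(f"unparseable fold engine output: {proc.stdout!r}")
        struct_line = lines[1]
        structure = struct_line.split()[0]
        mfe = float(struct_line[struct_line.rfind("(") + 1 : struct_line.rfind(")")])
        table: dict[int, int] = {}
        stack = []
        for i, c in enumerate(structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return FoldResult(sequence, structure, mfe, table)


def excise_precursor_windows(
    tag_locus: GenomeLocus,
    genome: Mapping[str, str],
    max_flank: int = 280,
    step: int = 20,
) -> list[tuple[GenomeLocus, str, int]]:
    """Candidate precursor windows around a mapped mature locus.

    Windows extend the mature's 5' side by ``up`` and 3' side by ``down``
    nt for up, down in {0, step, 2*step, ..., max_flank}, excluding the
    bare (0, 0) window; strand-aware (minus-strand windows are
    reverse-complemented) and clipped at chromosome ends.  Returns
    (window locus, window sequence in mature orientation, 0-based mature
    offset within the window).
    """
    chrom_seq = genome.get(tag_locus.chromosome)
    if chrom_seq is None:
        raise InputError(f"chromosome {tag_locus.chromosome!r} not in genome")
    if tag_locus.end > len(chrom_seq):
        raise InputError("locus outside chromosome")
    windows = []
    steps = range(0, max_flank + 1, step)
    for up in steps:
        for down in steps:
            if up == 0 and down == 0:
                continue
            if tag_locus.strand == "+":
                gstart = max(1, tag_locus.start - up)
                gend = min(len(chrom_seq), tag_locus.end + down)
            else:
                gstart = max(1, tag_locus.start - down)
                gend = min(len(chrom_seq), tag_locus.end + up)
            seq = chrom_seq[gstart - 1 : gend]
            if tag_locus.strand == "+":
                offset = tag_locus.start - gstart
            else:
                seq = revcomp(seq)
                offset = gend - tag_locus.end
            windows.append(
                (GenomeLocus(tag_locus.chromosome, gstart, gend, tag_locus.strand), seq, offset)
            )
    # distinct clipped windows only, deterministic order
    seen = set()
    out = []
    for loc, seq, off in windows:
        key = (loc.start, loc.end)
        if key not in seen:
            seen.add(key)
            out.append((loc, seq, off))
    return out


@dataclass
class CriteriaConfig:
    mfe_threshold: float = -18.0
    min_precursor_len: int = 60
    max_precursor_len: int = 320
    max_mature_unpaired: int = 4
    # the miRNA:miRNA* duplex must be contiguous up to small asymmetric
    # bulges: the span of the mature's pairing partners may exceed the
    # mature span by at most this many nt
    max_duplex_bulge: int = 4


@dataclass
class HairpinCandidate:
    mature_tag: SmallRNATag
    precursor_locus: GenomeLocus
    precursor_seq: str
    fold: FoldResult
    arm: str  # "5p" | "3p" | "?"
    star_seq: str | None
    star_reads: int
    criteria_flags: dict[str, bool]
    stem_loop_length: int = 0

    def __post_init__(self) -> None:
        self.stem_loop_length = len(self.precursor_seq)

    @property
    def accepted(self) -> bool:
        mandatory = ("mfe", "single_arm", "mature_pairing", "duplex_compact", "precursor_length")
        return all(self.criteria_flags[k] for k in mandatory)


def _mature_arm(fold_result: FoldResult, mature_span: tuple[int, int]) -> tuple[str, bool]:
    """Arm of the mature ('5p'/'3p'/'?') and whether it sits cleanly on a
    single stem-loop: no base inside a terminal (hairpin) loop, all paired
    bases pointing the same direction, and the region between the mature
    and its partner arm self-contained (no pair exits it — otherwise the
    mature sits in a multiloop, not a single stem-loop)."""
    m0, m1 = mature_span
    directions = set()
    partners = []
    for i in range(m0, m1 + 1):
        j = fold_result.partner(i)
        if j is not None:
            directions.add("5p" if j > i else "3p")
            partners.append(j)
    if len(directions) != 1:
        return "?", False
    arm = directions.pop()
    # terminal loops: pairs enclosing no other pair
    pairs = sorted((i, j) for i, j in fold_result.pair_table.items() if i < j)
    for i, j in pairs:
        inner = any(i < a and b < j for a, b in pairs)
        if not inner:
            # loop region i+1..j-1
            if not (m1 < i + 1 or m0 > j - 1):
                return arm, False
    # gap between mature and partner arm must be self-contained
    if arm == "5p":
        g0, g1 = m1 + 1, min(partners) - 1
    else:
        g0, g1 = max(partners) + 1, m0 - 1
    for p in range(g0, g1 + 1):
        q = fold_result.partner(p)
        if q is not None and not (g0 <= q <= g1):
            return arm, False
    return arm, True


def star_sequence(
    fold_result: FoldResult, mature_span: tuple[int, int]
) -> tuple[tuple[int, int], str] | None:
    """miRNA* span and sequence for a mature on one arm of the fold.

    The star is the duplex partner on the opposite arm, shifted to give
    the canonical 2-nt 3' overhang on each strand; bulges are absorbed by
    following the pair table (nearest paired mature base at each end).
    Requires >= 60% of mature bases paired; returns None otherwise.
    """
    m0, m1 = mature_span
    length = m1 - m0 + 1
    paired = [i for i in range(m0, m1 + 1) if fold_result.partner(i) is not None]
    if len(paired) < 0.6 * length:
        return None
    # nearest paired mature position at each end
    p5 = next((i for i in range(m0, m1 + 1) if fold_result.partner(i) is not None), None)
    p3 = next((i for i in range(m1, m0 - 1, -1) if fold_result.partner(i) is not None), None)
    if p5 is None or p3 is None:
        return None
    a = fold_result.partner(p3) + (p3 - m1) + 2  # pairs mature 3' end, +2 overhang shift
    b = fold_result.partner(p5) + (m0 - p5) + 2
    lo, hi = min(a, b), max(a, b)
    lo = max(0, lo)
    hi = min(len(fold_result.sequence) - 1, hi)
    if hi <= lo:
        return None
    return (lo, hi), fold_result.sequence[lo : hi + 1]


def evaluate_candidate(
    window_fold: FoldResult,
    mature_span: tuple[int, int],
    tag_library: Mapping[str, int],
    criteria: CriteriaConfig | None = None,
    mature_tag: SmallRNATag | None = None,
    locus: GenomeLocus | None = None,
) -> HairpinCandidate:
    """Adjudicate one folded window against the annotation criteria.

    Flags: ``mfe`` (fold energy under threshold), ``single_arm`` (mature
    on one arm, outside the terminal loop), ``mature_pairing`` (few
    unpaired mature bases), ``precursor_length``; ``star_found`` is
    recorded as supporting evidence only (star read count looked up by
    exact sequence in ``tag_library``).
    """
    criteria = criteria or CriteriaConfig()
    m0, m1 = mature_span
    n = len(window_fold.sequence)
    if not (0 <= m0 <= m1 < n):
        raise InputError("mature span outside window")
    arm, single = _mature_arm(window_fold, mature_span)
    unpaired = sum(1 for i in range(m0, m1 + 1) if window_fold.partner(i) is None)
    partners = [window_fold.partner(i) for i in range(m0, m1 + 1) if window_fold.partner(i) is not None]
    if partners:
        span = max(partners) - min(partners) + 1
        compact = span <= (m1 - m0 + 1) + criteria.max_duplex_bulge
    else:
        compact = False
    star = star_sequence(window_fold, mature_span)
    star_seq = star[1] if star else None
    star_reads = tag_library.get(star_seq, 0) if star_seq else 0
    flags = {
        "mfe": window_fold.mfe <= criteria.mfe_threshold,
        "single_arm": single,
        "mature_pairing": unpaired <= criteria.max_mature_unpaired,
        "duplex_compact": compact,
        "precursor_length": criteria.min_precursor_len <= n <= criteria.max_precursor_len,
        "star_found": star_reads > 0,
    }
    if mature_tag is None:
        mature_tag = SmallRNATag(window_fold.sequence[m0 : m1 + 1], 1)
    if locus is None:
        locus = GenomeLocus("?", 1, n, "+")
    return HairpinCandidate(
        mature_tag=mature_tag,
        precursor_locus=locus,
        precursor_seq=window_fold.sequence,
        fold=window_fold,
        arm=arm,
        star_seq=star_seq,
        star_reads=star_reads,
        criteria_flags=flags,
    )


def select_best_candidate(candidates: Sequence[HairpinCandidate]) -> HairpinCandidate | None:
    """Best accepted candidate: lowest MFE, then shortest precursor, then
    smallest window start (deterministic)."""
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        return None
    return min(
        accepted,
        key=lambda c: (c.fold.mfe, c.stem_loop_length, c.precursor_locus.start),
    )


def five_prime_composition(candidates: Sequence[HairpinCandidate] | Sequence[str]) -> dict[str, float]:
    """Fraction of candidate matures starting with each nucleotide."""
    seqs = [
        c if isinstance(c, str) else c.mature_tag.sequence for c in candidates
    ]
    if not seqs:
        raise ValueError("empty candidate set")
    counts = Counter(s[0] for s in seqs)
    total = len(seqs)
    return {base: counts.get(base, 0) / total for base in "ACGT"}


def classify_novelty(
    candidates: Sequence[HairpinCandidate],
    vitis_known: Sequence[KnownMature],
    other_species_known: Sequence[KnownMature],
    max_mismatches: int = 2,
) -> dict[str, str]:
    """Partition candidates into species_specific / vitis_specific / shared.

    A candidate is *shared* when its mature matches a supplied non-vitis
    sequence within ``max_mismatches`` substitutions (ungapped containment),
    *vitis_specific* when it matches only the vitis set, else
    *species_specific*.  Keyed by mature sequence.
    """

    def matches(seq: str, known: Sequence[KnownMature]) -> bool:
        for k in known:
            for subs, off5, off3 in _align_contained(seq, k.sequence):
                if subs <= max_mismatches and abs(off5) + abs(off3) <= 3:
                    return True
        return False

    out = {}
    for cand in candidates:
        seq = cand.mature_tag.sequence
        if matches(seq, other_species_known):
            out[seq] = "shared"
        elif matches(seq, vitis_known):
            out[seq] = "vitis_specific"
        else:
            out[seq] = "species_specific"
    return out
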