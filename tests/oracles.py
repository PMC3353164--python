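"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by enumeration or naive
search, independent of the production code paths they check.
"""

from __future__ import annotations

import itertools

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
PAIR_WEIGHT = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def enumerate_structures(seq: str, min_loop: int = 3):
    """All nested pair sets (no pseudoknots, loop >= min_loop)."""

    def rec(positions: tuple):
        if not positions:
            yield []
            return
        i = positions[0]
        rest = positions[1:]
        yield from rec(rest)  # i unpaired
        for j in rest:
            if j - i - 1 < min_loop or (seq[i], seq[j]) not in PAIRABLE:
                continue
            inside = tuple(p for p in rest if i < p < j)
            outside = tuple(p for p in rest if p > j)
            for s1 in rec(inside):
                for s2 in rec(outside):
                    yield [(i, j)] + s1 + s2

    yield from rec(tuple(range(len(seq))))


def brute_energy(seq: str, pairs) -> float:
    """Energy of a structure under the stacking-weighted model, computed
    directly from the definition."""
    pair_set = set(pairs)
    e = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pair_set:
            e += PAIR_WEIGHT[(seq[i], seq[j])]
        if not any(i < a and b < j for a, b in pair_set):
            e += 4.0
    return e


def brute_min_energy(seq: str) -> float:
    """MFE by full enumeration (empty structure = 0 is always available)."""
    return min(brute_energy(seq, s) for s in enumerate_structures(seq))


def naive_map(tag: str, genome: dict) -> list:
    """All exact occurrences of tag on both strands: O(n*m) scan."""
    hits = []
    rc = revcomp(tag)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for i in range(len(seq) - len(tag) + 1):
            window = seq[i : i + len(tag)]
            if window == tag:
                hits.append((chrom, i + 1, i + len(tag), "+"))
            if window == rc:
                hits.append((chrom, i + 1, i + len(tag), "-"))
    return hits


def brute_match(tag: str, known_list, max_subs: int = 3, slack: int = 3):
    """Best known-mature assignment by exhaustive offset enumeration.

    known_list: (id, sequence) pairs.  Returns (subs, total_overhang, id)
    or None.  Mirrors the ranking contract: fewest substitutions, then
    smallest total terminal overhang, then smallest id.
    """
    best = None
    for kid, kseq in known_list:
        a, b = (tag, kseq) if len(tag) <= len(kseq) else (kseq, tag)
        for s in range(len(b) - len(a) + 1):
            subs = sum(1 for x, y in zip(a, b[s : s + len(a)]) if x != y)
            overhang = len(b) - len(a)
            if subs > max_subs or overhang > slack:
                continue
            key = (subs, overhang, kid)
            if best is None or key < best:
                best = key
    return best


def brute_best_adapter_start(seq: str, adapter: str, min_overlap: int, max_rate: float):
    """Best-scoring 3' adapter occurrence by scanning every offset."""
    best = None
    for start in range(len(seq)):
        overlap = min(len(seq) - start, len(adapter))
        if overlap < min_overlap:
            continue
        mism = sum(1 for a, b in zip(seq[start : start + overlap], adapter) if a != b)
        if mism > max_rate * overlap:
            continue
        score = overlap - 2 * mism
        if best is None or score > best[0]:
            best = (score, start)
    return None if best is None else best[1]


def allen_penalty(mirna_base: str, target_base: str, position: int) -> float:
    """Penalty of one duplex position from the printed rule table."""
    weight = 2.0 if 2 <= position <= 13 else 1.0
    if (mirna_base, target_base) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
        return 0.0
    if (mirna_base, target_base) in {("G", "T"), ("T", "G")}:
        return 0.5 * weight
    return 1.0 * weight
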