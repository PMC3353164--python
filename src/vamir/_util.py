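"""Shared helpers: alphabet handling, percentages, errors."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConfigError(ValueError):
    """Invalid configuration (bad thresholds, empty adapters, unknown keys)."""


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and convert RNA (U) to the DNA alphabet used internally."""
    return seq.strip().upper().replace("U", "T")


def percent(count: float, total: float, decimals: int = 2) -> float:
    """100*count/total, rounded half-up to ``decimals`` places.

    Half-up (not banker's) rounding so printed 2-decimal percentages are
    reproduced deterministically.
    """
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    scale = 10**decimals
    x = 100.0 * count / total
    return int(x * scale + (0.5 if x >= 0 else -0.5)) / scale


def pairs_watson_crick(a: str, b: str) -> bool:
    return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def pairs_wobble(a: str, b: str) -> bool:
    """G:U wobble in the duplex sense (DNA alphabet: G with T)."""
    return (a, b) in {("G", "T"), ("T", "G")}


def base_pairs(a: str, b: str) -> bool:
    return pairs_watson_crick(a, b) or pairs_wobble(a, b)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InputError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
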