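"""miRNA target scanning with Allen-style duplex penalties.

Plant miRNA targets are near-perfect complements of the miRNA, so target
search is an exhaustive complementarity scan over transcript windows: each
miRNA:window duplex is scored by summing penalties (mismatch 1.0, G:U
wobble 0.5, bulged position 1.0), doubled at miRNA positions 2-13 (the
5'-proximal region critical for cleavage).  Hits at or under the score
cutoff (default 4.0) are reported, with the expected slicer cleavage site
mapped to the transcript base pairing miRNA nucleotide 10 (or 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import InputError, pairs_watson_crick, pairs_wobble, revcomp

__all__ = [
    "PositionState",
    "DuplexAlignment",
    "TargetHit",
    "CleavagePrediction",
    "score_duplex",
    "align_duplex",
    "scan_transcripts",
    "predict_cleavage",
    "annotate_region",
    "format_duplex",
]

CORE_START, CORE_END = 2, 13  # inclusive, miRNA positions with doubled penalties
MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
BULGE_PENALTY = 1.0


@dataclass(frozen=True)
class PositionState:
    mirna_pos: int | None  # 1-based from miRNA 5'; None only for bulge_target
    state: str  # match | mismatch | GU | bulge_mirna | bulge_target
    mirna_base: str | None
    target_base: str | None
    target_pos: int | None  # 1-based transcript coordinate


@dataclass
class DuplexAlignment:
    """miRNA:target-site duplex; states ordered along the miRNA 5'->3'.

    The duplex is antiparallel: miRNA position 1 pairs the 3'-most base of
    the target site.
    """

    mirna_seq: str
    target_site_seq: str  # 5'->3' on the transcript
    states: list[PositionState]

    def state_at(self, mirna_pos: int) -> PositionState | None:
        for st in self.states:
            if st.mirna_pos == mirna_pos and st.state != "bulge_target":
                return st
        return None


def _pair_state(mirna_base: str, target_base: str) -> str:
    if pairs_watson_crick(mirna_base, target_base):
        return "match"
    if pairs_wobble(mirna_base, target_base):
        return "GU"
    return "mismatch"


def _position_weight(pos: int | None) -> float:
    return 2.0 if pos is not None and CORE_START <= pos <= CORE_END else 1.0


def score_duplex(alignment: DuplexAlignment) -> float:
    """Allen penalty of a duplex: mismatch 1.0, G:U 0.5, bulge 1.0, all
    doubled at miRNA positions 2-13.  0.5 granularity, >= 0."""
    score = 0.0
    for st in alignment.states:
        if st.state == "match":
            continue
        if st.state == "mismatch":
            pen = MISMATCH_PENALTY
        elif st.state == "GU":
            pen = GU_PENALTY
        elif st.state in {"bulge_mirna", "bulge_target"}:
            pen = BULGE_PENALTY
        else:
            raise InputError(f"malformed duplex state {st.state!r}")
        score += pen * _position_weight(st.mirna_pos)
    return score


def align_duplex(
    mirna: str,
    site: str,
    site_start: int = 1,
    target_bulge_after: int | None = None,
    mirna_bulge_pos: int | None = None,
) -> DuplexAlignment:
    """Build the duplex state vector for a miRNA against a target window.

    Ungapped when both bulge arguments are None (requires equal lengths).
    ``target_bulge_after`` = miRNA position after which one extra target
    base is bulged (site one base longer); ``mirna_bulge_pos`` = unpaired
    miRNA position (site one base shorter).  ``site_start`` is the 1-based
    transcript coordinate of the window's first base.
    """
    L = len(mirna)
    states: list[PositionState] = []
    if target_bulge_after is None and mirna_bulge_pos is None:
        if len(site) != L:
            raise InputError("ungapped duplex requires equal lengths")
        for p in range(1, L + 1):
            t_idx = L - p  # 0-based within site
            states.append(
                PositionState(
                    p,
                    _pair_state(mirna[p - 1], site[t_idx]),
                    mirna[p - 1],
                    site[t_idx],
                    site_start + t_idx,
                )
            )
    elif target_bulge_after is not None:
        if len(site) != L + 1:
            raise InputError("target bulge requires site length |mirna|+1")
        t = len(site) - 1  # walk site 3'->5'
        for p in range(1, L + 1):
            states.append(
                PositionState(
                    p,
                    _pair_state(mirna[p - 1], site[t]),
                    mirna[p - 1],
                    site[t],
                    site_start + t,
                )
            )
            t -= 1
            if p == target_bulge_after:
                states.append(
                    PositionState(p, "bulge_target", None, site[t], site_start + t)
                )
                t -= 1
    else:
        if len(site) != L - 1:
            raise InputError("miRNA bulge requires site length |mirna|-1")
        t = len(site) - 1
        for p in range(1, L + 1):
            if p == mirna_bulge_pos:
                states.append(PositionState(p, "bulge_mirna", mirna[p - 1], None, None))
                continue
            states.append(
                PositionState(
                    p,
                    _pair_state(mirna[p - 1], site[t]),
                    mirna[p - 1],
                    site[t],
                    site_start + t,
                )
            )
            t -= 1
    return DuplexAlignment(mirna, site, states)


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive on the transcript
    end: int
    alignment: DuplexAlignment
    score: float
    mismatches: int
    gu_count: int
    region: str = "unknown"

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CleavagePrediction:
    transcript_position: int
    anchor: int
    anchor_paired: bool


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_WC = np.zeros((5, 5), dtype=bool)
_GU = np.zeros((5, 5), dtype=bool)
for _a, _b in [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]:
    _WC[_ENC[_a], _ENC[_b]] = True
for _a, _b in [("G", "T"), ("T", "G")]:
    _GU[_ENC[_a], _ENC[_b]] = True


def _window_scores(mirna: str, t_enc: np.ndarray, win_len: int, column_map: list, extra: float):
    """Scores of all length-``win_len`` windows of an encoded transcript.

    ``column_map[j]`` is the miRNA position (1-based) paired with window
    column j, or None for a bulged target column; ``extra`` is a constant
    penalty (e.g. a bulge) added to every window.
    """
    n_win = len(t_enc) - win_len + 1
    if n_win <= 0:
        return np.empty((0,)), np.empty((0,)), np.empty((0,))
    # per-column penalty lookup tables over the 5-letter alphabet
    P = np.zeros((win_len, 5))
    M = np.zeros((win_len, 5))  # raw mismatch indicator
    G = np.zeros((win_len, 5))
    for j, pos in enumerate(column_map):
        if pos is None:
            continue
        m_enc = _ENC[mirna[pos - 1]]
        w = _position_weight(pos)
        for b in range(5):
            if _WC[m_enc, b]:
                continue
            if _GU[m_enc, b]:
                P[j, b] = GU_PENALTY * w
                G[j, b] = 1
            else:
                P[j, b] = MISMATCH_PENALTY * w
                M[j, b] = 1
    windows = np.lib.stride_tricks.sliding_window_view(t_enc, win_len)
    cols = np.arange(win_len)
    scores = P[cols, windows].sum(axis=1) + extra
    mism = M[cols, windows].sum(axis=1)
    gu = G[cols, windows].sum(axis=1)
    return scores, mism, gu


def scan_transcripts(
    mirna_seq: str,
    mirna_id: str,
    transcripts: Mapping[str, str],
    max_score: float = 4.0,
    max_bulges: int = 1,
    max_mismatches: int | None = None,
) -> list[TargetHit]:
    """All target sites of one miRNA across a transcript set.

    Every window (|miRNA| +- allowed bulge widths) whose best duplex
    scores <= ``max_score`` (and, optionally, has < ``max_mismatches``
    raw mismatches) is collected; overlapping windows are reduced to the
    best-scoring site per overlap cluster (ties: 5'-most).  Hits sorted by
    score, then transcript id and coordinate.
    """
    if not transcripts:
        return []
    L = len(mirna_seq)
    raw: list[TargetHit] = []
    for tid in sorted(transcripts):
        t_seq = transcripts[tid]
        t_enc = np.array([_ENC.get(c, 4) for c in t_seq], dtype=np.int64)
        variants: list[tuple[int, list, float, dict]] = []
        # ungapped: window column j pairs miRNA position L-j
        variants.append((L, [L - j for j in range(L)], 0.0, {}))
        if max_bulges >= 1:
            for b in range(1, L):  # target bulge after miRNA position b
                # build right-to-left: rightmost column pairs position 1
                cmap = [None] * (L + 1)
                p = 1
                j = L
                while j >= 0:
                    cmap[j] = p
                    p += 1
                    j -= 1
                    if p == b + 1 and j >= 0:
                        cmap[j] = None  # bulged target base
                        j -= 1
                variants.append(
                    (L + 1, cmap, BULGE_PENALTY * _position_weight(b), {"target_bulge_after": b})
                )
            for b in range(2, L):  # bulged (unpaired) miRNA position b
                cmap = [0] * (L - 1)
                p = 1
                j = L - 2
                while j >= 0:
                    if p == b:
                        p += 1
                    cmap[j] = p
                    p += 1
                    j -= 1
                variants.append(
                    (L - 1, cmap, BULGE_PENALTY * _position_weight(b), {"mirna_bulge_pos": b})
                )
        best_per_window: dict[tuple[int, int], tuple[float, float, float, dict]] = {}
        for win_len, cmap, extra, kwargs in variants:
            scores, mism, gu = _window_scores(mirna_seq, t_enc, win_len, cmap, extra)
            ok = scores <= max_score
            if max_mismatches is not None:
                ok &= mism < max_mismatches
            for idx in np.nonzero(ok)[0]:
                key = (int(idx) + 1, int(idx) + win_len)
                val = (float(scores[idx]), float(mism[idx]), float(gu[idx]), kwargs)
                prev = best_per_window.get(key)
                if prev is None or val[0] < prev[0]:
                    best_per_window[key] = val
        for (start, end), (score, mism_n, gu_n, kwargs) in sorted(best_per_window.items()):
            site = t_seq[start - 1 : end]
            aln = align_duplex(mirna_seq, site, site_start=start, **kwargs)
            raw.append(
                TargetHit(
                    mirna_id,
                    tid,
                    start,
                    end,
                    aln,
                    score,
                    int(mism_n),
                    int(gu_n),
                )
            )
    # reduce overlap clusters: best score wins, ties -> 5'-most
    hits: list[TargetHit] = []
    for tid in sorted({h.transcript_id for h in raw}):
        t_hits = sorted(
            (h for h in raw if h.transcript_id == tid), key=lambda h: h.start
        )
        cluster: list[TargetHit] = []
        cluster_end = -1
        for h in t_hits:
            if cluster and h.start > cluster_end:
                hits.append(min(cluster, key=lambda x: (x.score, x.start)))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            hits.append(min(cluster, key=lambda x: (x.score, x.start)))
    hits.sort(key=lambda h: (h.score, h.transcript_id, h.start))
    return hits


def predict_cleavage(hit: TargetHit, anchor: int = 10) -> CleavagePrediction:
    """Transcript coordinate of the expected cleavage: the base pairing
    miRNA nucleotide ``anchor`` (10 or 9), following the state vector
    across bulges.  The returned position is the predicted 5' end of the
    3' cleavage fragment."""
    if anchor > len(hit.alignment.mirna_seq):
        raise InputError("anchor beyond miRNA length")
    st = hit.alignment.state_at(anchor)
    if st is None or st.target_pos is None:
        raise InputError(f"miRNA position {anchor} is bulged; no paired transcript base")
    return CleavagePrediction(st.target_pos, anchor, st.state in {"match", "GU"})


def annotate_region(hit: TargetHit, cds_span: tuple[int, int] | None) -> str:
    """5UTR/CDS/3UTR label from the site midpoint vs the CDS span;
    ``unknown`` when no transcript model is provided."""
    if cds_span is None:
        return "unknown"
    cds_start, cds_end = cds_span
    mid = hit.midpoint
    if mid < cds_start:
        return "5UTR"
    if mid > cds_end:
        return "3UTR"
    return "CDS"


_SYMBOL = {"match": "|", "GU": "o", "mismatch": "X", "bulge_mirna": " ", "bulge_target": " "}


def format_duplex(alignment: DuplexAlignment) -> str:
    """Pretty-print a duplex: target 5'->3' on top, miRNA 3'->5' below,
    with | (Watson-Crick), o (G:U wobble) and X (mismatch) marks."""
    top, marks, bottom = [], [], []
    for st in reversed(alignment.states):  # target 5'->3' = miRNA 3'->5'
        top.append(st.target_base or "-")
        bottom.append(st.mirna_base or "-")
        marks.append(_SYMBOL[st.state])
    return (
        f"5' {''.join(top)} 3'  (target)\n"
        f"   {''.join(marks)}\n"
        f"3' {''.join(bottom)} 5'  (miRNA)"
    )
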