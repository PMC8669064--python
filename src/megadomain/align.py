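"""Affine-gap local alignment for long-read consensus matching.

The aligner is a banded Smith-Waterman/Gotoh dynamic program compiled
with numba. For sequence pairs small enough the band spans the whole
matrix, so the result is the exact optimal local alignment; for long
reads the band is placed around exact k-mer seed diagonals, which at
HiFi-scale error rates contains the optimum while keeping the run cost
linear in read length.

Raw scores are converted to bit scores via S' = (lambda * S - ln K)/ln 2
with Karlin-Altschul-style constants fixed per scoring scheme, so
competing alignments (consensus vs masked reference) are compared on a
common scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["Scoring", "AlignmentResult", "local_align", "revcomp", "encode_seq"]

_IUPAC = set("ACGTURYSWKMBDHVN")
_COMP = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                      "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")


@dataclass(frozen=True)
class Scoring:
    """Affine local-alignment scoring and bit-score constants.

    Gap penalties are positive: a gap of length L costs
    ``gap_open + gap_extend * (L - 1)``.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    lam: float = 1.28   # Karlin-Altschul lambda for the +1/-2 scheme
    k: float = 0.46

    def bits(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2.0)


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a target."""

    score: int
    q_start: int   # 0-based half-open span on the query
    q_end: int
    t_start: int   # 0-based half-open span on the target
    t_end: int
    matched_length: int  # target positions aligned to query bases (no gaps)
    strand: str = "+"

    def bits(self, scoring: Scoring) -> float:
        return scoring.bits(self.score)


def encode_seq(seq: str) -> np.ndarray:
    """Encode to uint8: ACGT(U) -> 0..3, IUPAC ambiguity codes -> 4
    (never matching anything); non-IUPAC characters are rejected."""
    up = seq.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    table = np.full(256, 4, dtype=np.uint8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
    table[ord("U")] = 3
    return table[np.frombuffer(up.encode(), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@njit(cache=True)
def _sw_banded(q, t, dlo, width, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    """Banded affine local DP. Band: target_pos - query_pos (1-based DP
    indices) in [dlo, dlo + width). Returns (score, q_start, q_end,
    t_start, t_end, matched)."""
    n, m = q.shape[0], t.shape[0]
    NEG = np.int64(-(10 ** 12))
    H_prev = np.zeros(width, dtype=np.int64)
    F_prev = np.full(width, NEG, dtype=np.int64)
    H_cur = np.zeros(width, dtype=np.int64)
    F_cur = np.full(width, NEG, dtype=np.int64)
    ptrH = np.zeros((n + 1, width), dtype=np.uint8)
    ptrE = np.zeros((n + 1, width), dtype=np.uint8)
    ptrF = np.zeros((n + 1, width), dtype=np.uint8)

    best = np.int64(0)
    best_i = 0
    best_o = 0
    for i in range(1, n + 1):
        for o in range(width):
            H_cur[o] = 0
            F_cur[o] = NEG
        e_run = NEG
        jlo = i + dlo
        for o in range(width):
            j = jlo + o
            if j < 1:
                e_run = NEG
                continue
            if j > m:
                break
            # diagonal
            if j == 1 or i == 1:
                diag_base = np.int64(0)
            else:
                diag_base = H_prev[o]
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            diag = diag_base + s
            # E: gap consuming target, same row
            if o == 0 or j == 1:
                e_open = NEG
            else:
                e_open = H_cur[o - 1] - gap_open
            e_ext = e_run - gap_ext
            if e_ext > e_open:
                e_val = e_ext
                ptrE[i, o] = 1
            else:
                e_val = e_open
                ptrE[i, o] = 0
            e_run = e_val
            # F: gap consuming query, same column
            if o + 1 < width and i > 1:
                f_open = H_prev[o + 1] - gap_open
                f_ext = F_prev[o + 1] - gap_ext
            else:
                f_open = NEG if i > 1 else np.int64(0) - gap_open
                f_ext = NEG
            if f_ext > f_open:
                f_val = f_ext
                ptrF[i, o] = 1
            else:
                f_val = f_open
                ptrF[i, o] = 0
            # H
            h = np.int64(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = 1
            if e_val > h:
                h = e_val
                p = 2
            if f_val > h:
                h = f_val
                p = 3
            H_cur[o] = h
            F_cur[o] = f_val
            ptrH[i, o] = p
            if h > best:
                best = h
                best_i = i
                best_o = o
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev

    if best == 0:
        return 0, 0, 0, 0, 0, 0
    # traceback
    i = best_i
    o = best_o
    j = i + dlo + o
    q_end = i
    t_end = j
    matched = 0
    while ptrH[i, o] != 0:
        p = ptrH[i, o]
        if p == 1:
            matched += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                opened = ptrE[i, o] == 0
                j -= 1
                o -= 1
                if opened:
                    break
        else:
            while True:
                opened = ptrF[i, o] == 0
                i -= 1
                o += 1
                if opened:
                    break
        if i == 0 or j == 0:
            break
    return int(best), i, q_end, j, t_end, matched


def _seed_diagonals(q: np.ndarray, t_index: dict, k: int) -> np.ndarray:
    """Diagonals (t_pos - q_pos) of exact k-mer matches."""
    diags = []
    qb = q.tobytes()
    for qpos in range(0, len(q) - k + 1):
        kmer = qb[qpos : qpos + k]
        hits = t_index.get(kmer)
        if hits is not None:
            for tpos in hits:
                diags.append(tpos - qpos)
    return np.array(sorted(diags), dtype=np.int64)


def build_kmer_index(t: np.ndarray, k: int = 13) -> dict:
    """Target k-mer positions keyed by encoded k-mer bytes; k-mers
    containing ambiguity codes are skipped."""
    index: dict = {}
    tb = t.tobytes()
    for pos in range(0, len(t) - k + 1):
        if t[pos : pos + k].max() >= 4:
            continue
        index.setdefault(tb[pos : pos + k], []).append(pos)
    return index


def _band_from_seeds(
    diags: np.ndarray, cluster_width: int = 500, pad: int = 100
) -> tuple[int, int] | None:
    """Band covering the densest diagonal cluster of seeds, padded for
    indels."""
    if diags.size == 0:
        return None
    best_lo, best_n = 0, 0
    j = 0
    for i in range(diags.size):
        while diags[i] - diags[j] > cluster_width:
            j += 1
        if i - j + 1 > best_n:
            best_n = i - j + 1
            best_lo = j
    sel = diags[(diags >= diags[best_lo]) & (diags <= diags[best_lo] + cluster_width)]
    return int(sel.min() - pad), int(sel.max() + pad)


_FULL_DP_CELL_LIMIT = 4_000_000


def _align_one_strand(
    q: np.ndarray,
    t: np.ndarray,
    scoring: Scoring,
    t_index: dict | None,
    seed_k: int,
) -> tuple | None:
    n, m = len(q), len(t)
    if n == 0 or m == 0:
        return None
    if n * m <= _FULL_DP_CELL_LIMIT:
        dlo, width = 1 - n, n + m - 1
    else:
        if t_index is None:
            t_index = build_kmer_index(t, seed_k)
        band = _band_from_seeds(_seed_diagonals(q, t_index, seed_k))
        if band is None:
            return None
        dlo, dhi = band
        dlo = max(dlo, 1 - n)
        dhi = min(dhi, m - 1)
        if dhi < dlo:
            return None
        width = dhi - dlo + 1
    return _sw_banded(
        q, t, dlo, width,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )


def local_align(
    query: str,
    target: str,
    scoring: Scoring = Scoring(),
    both_strands: bool = False,
    target_index: dict | None = None,
    seed_k: int = 13,
) -> AlignmentResult | None:
    """Best affine-gap local alignment of ``query`` against ``target``.

    With ``both_strands`` the reverse complement of the query is also
    tried and the better-scoring strand returned (spans are reported on
    the forward target in both cases). Returns None when no alignment
    with positive score is found (for long pairs: when no seed cluster
    exists).
    """
    qf = encode_seq(query)
    t = encode_seq(target)
    results = []
    fwd = _align_one_strand(qf, t, scoring, target_index, seed_k)
    if fwd is not None and fwd[0] > 0:
        results.append((fwd, "+", len(query)))
    if both_strands:
        qr = encode_seq(revcomp(query))
        rev = _align_one_strand(qr, t, scoring, target_index, seed_k)
        if rev is not None and rev[0] > 0:
            results.append((rev, "-", len(query)))
    if not results:
        return None
    (score, qs, qe, ts, te, matched), strand, qlen = max(
        results, key=lambda r: r[0][0]
    )
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs
    return AlignmentResult(score, qs, qe, ts, te, matched, strand)
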