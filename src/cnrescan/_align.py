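"""Numba kernels for query-global / subject-local ("glocal") alignment.

The motif (query) is aligned end-to-end; the genome (subject) contributes a
contiguous local region, i.e. leading and trailing subject bases are free.
Affine gap model: a gap of length L costs ``gap_open + L * gap_extend``
(both non-positive).  Bases are encoded A=0, C=1, G=2, T=3, N=4; N never
matches anything, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**8))

_CODES = np.full(256, 5, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def encode(bases: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0..T=3, N=4)."""
    arr = _CODES[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 4:
        bad = chr(np.frombuffer(bases.encode("ascii"), dtype=np.uint8)[arr > 4][0])
        raise ValueError(f"invalid nucleotide character {bad!r}")
    return arr.copy()


@njit(cache=True)
def glocal_score_multi(subject, queries_t, match, mismatch, gap_open, gap_extend):
    """Best glocal score of every query column in ``queries_t`` (m x nq)
    against one subject.  Score-only; vectorized across queries so that the
    innermost loop is SIMD-friendly."""
    n = subject.shape[0]
    m, nq = queries_t.shape
    goe = gap_open + gap_extend
    H = np.empty((m + 1, nq), dtype=np.int32)
    E = np.empty((m + 1, nq), dtype=np.int32)
    F = np.empty((m + 1, nq), dtype=np.int32)
    diag = np.empty(nq, dtype=np.int32)
    best = np.empty(nq, dtype=np.int32)
    for q in range(nq):
        H[0, q] = 0
        E[0, q] = NEG_INF
        F[0, q] = NEG_INF
    for j in range(1, m + 1):
        v = gap_open + j * gap_extend
        for q in range(nq):
            H[j, q] = v
            E[j, q] = v
            F[j, q] = NEG_INF
    for q in range(nq):
        best[q] = H[m, q]
    for i in range(1, n + 1):
        si = subject[i - 1]
        for q in range(nq):
            diag[q] = H[0, q]
            H[0, q] = 0
        for j in range(1, m + 1):
            qj = j - 1
            for q in range(nq):
                fo = H[j, q] + goe
                fe = F[j, q] + gap_extend
                f = fo if fo > fe else fe
                F[j, q] = f
                eo = H[j - 1, q] + goe
                ee = E[j - 1, q] + gap_extend
                e = eo if eo > ee else ee
                E[j, q] = e
                sc = match if (si == queries_t[qj, q] and si < 4) else mismatch
                s = diag[q] + sc
                if e > s:
                    s = e
                if f > s:
                    s = f
                diag[q] = H[j, q]
                H[j, q] = s
        for q in range(nq):
            if H[m, q] > best[q]:
                best[q] = H[m, q]
    return best


@njit(cache=True)
def glocal_best(subject, query, match, mismatch, gap_open, gap_extend):
    """Best glocal score of one query against one subject, with the 0-based
    half-open subject span of one optimal placement.

    Ties are broken toward the smallest subject start, then the smallest
    subject end (shortest span).  Start positions are propagated through the
    DP: on equal-score predecessors the smaller start wins, so every cell
    carries the minimum start over all optimal alignments reaching it.
    """
    n = subject.shape[0]
    m = query.shape[0]
    goe = gap_open + gap_extend
    H = np.empty(m + 1, dtype=np.int32)
    E = np.empty(m + 1, dtype=np.int32)
    F = np.empty(m + 1, dtype=np.int32)
    SH = np.empty(m + 1, dtype=np.int32)  # start carried by H cells
    SE = np.empty(m + 1, dtype=np.int32)
    SF = np.empty(m + 1, dtype=np.int32)
    H[0] = 0
    E[0] = NEG_INF
    F[0] = NEG_INF
    SH[0] = 0
    SE[0] = 0
    SF[0] = 0
    for j in range(1, m + 1):
        H[j] = gap_open + j * gap_extend
        E[j] = H[j]
        F[j] = NEG_INF
        SH[j] = 0
        SE[j] = 0
        SF[j] = 0
    best = H[m]
    best_start = 0
    best_end = 0
    for i in range(1, n + 1):
        si = subject[i - 1]
        diag = H[0]
        sdiag = SH[0]
        H[0] = 0
        SH[0] = i  # a region may begin after subject position i
        for j in range(1, m + 1):
            fo = H[j] + goe
            fe = F[j] + gap_extend
            if fo > fe or (fo == fe and SH[j] < SF[j]):
                F[j] = fo
                SF[j] = SH[j]
            else:
                F[j] = fe
            eo = H[j - 1] + goe
            ee = E[j - 1] + gap_extend
            if eo > ee or (eo == ee and SH[j - 1] < SE[j - 1]):
                E[j] = eo
                SE[j] = SH[j - 1]
            else:
                E[j] = E[j - 1] + gap_extend
                SE[j] = SE[j - 1]
            sc = match if (si == query[j - 1] and si < 4) else mismatch
            s = diag + sc
            st = sdiag
            if E[j] > s or (E[j] == s and SE[j] < st):
                s = E[j]
                st = SE[j]
            if F[j] > s or (F[j] == s and SF[j] < st):
                s = F[j]
                st = SF[j]
            diag = H[j]
            sdiag = SH[j]
            H[j] = s
            SH[j] = st
        if H[m] > best or (H[m] == best and SH[m] < best_start):
            best = H[m]
            best_start = SH[m]
            best_end = i
    if best_end < best_start:  # query aligned entirely to gaps
        best_end = best_start
    return best, best_start, best_end
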