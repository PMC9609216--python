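"""Needleman-Wunsch global alignment with affine gaps (Gotoh), JIT-compiled.

State matrices: M (residue-residue), U ("up": query residue against a gap,
consumes the query), L ("left": gap against a reference residue).  A gap of
length k costs open + (k-1)*extend; end gaps are penalized.  All ties are
resolved M > U > L, i.e. diagonal > up > left, so the traceback is
deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def _gotoh_fill(a, b, score, open_, ext):
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), NEG)
    U = np.full((m + 1, n + 1), NEG)
    L = np.full((m + 1, n + 1), NEG)
    # predecessor state per cell per state: 0=M, 1=U, 2=L, -1=start
    PM = np.full((m + 1, n + 1), -1, dtype=np.int8)
    PU = np.full((m + 1, n + 1), -1, dtype=np.int8)
    PL = np.full((m + 1, n + 1), -1, dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        U[i, 0] = -(open_ + (i - 1) * ext)
        PU[i, 0] = 0 if i == 1 else 1
    for j in range(1, n + 1):
        L[0, j] = -(open_ + (j - 1) * ext)
        PL[0, j] = 0 if j == 1 else 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = score[ai, b[j - 1]]
            # M: diagonal predecessor, tie order M > U > L
            best = M[i - 1, j - 1]
            ptr = 0
            if U[i - 1, j - 1] > best:
                best = U[i - 1, j - 1]
                ptr = 1
            if L[i - 1, j - 1] > best:
                best = L[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            PM[i, j] = ptr
            # U: from row above
            best = M[i - 1, j] - open_
            ptr = 0
            if U[i - 1, j] - ext > best:
                best = U[i - 1, j] - ext
                ptr = 1
            if L[i - 1, j] - open_ > best:
                best = L[i - 1, j] - open_
                ptr = 2
            U[i, j] = best
            PU[i, j] = ptr
            # L: from column left
            best = M[i, j - 1] - open_
            ptr = 0
            if U[i, j - 1] - open_ > best:
                best = U[i, j - 1] - open_
                ptr = 1
            if L[i, j - 1] - ext > best:
                best = L[i, j - 1] - ext
                ptr = 2
            L[i, j] = best
            PL[i, j] = ptr
    return M, U, L, PM, PU, PL


@njit(cache=True)
def _traceback(M, U, L, PM, PU, PL, m, n):
    # moves: 0 = diagonal, 1 = up, 2 = left; returned newest-first
    score = M[m, n]
    state = 0
    if U[m, n] > score:
        score = U[m, n]
        state = 1
    if L[m, n] > score:
        score = L[m, n]
        state = 2
    moves = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        moves[k] = state
        if state == 0:
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = PU[i, j]
            i -= 1
        else:
            state = PL[i, j]
            j -= 1
        k += 1
    return score, moves[:k]


def align_codes(a: np.ndarray, b: np.ndarray, score: np.ndarray,
                gap_open: float, gap_extend: float):
    """Align integer-coded sequences; returns (score, moves oldest-first)."""
    M, U, L, PM, PU, PL = _gotoh_fill(
        a.astype(np.int64), b.astype(np.int64), score.astype(np.float64),
        float(gap_open), float(gap_extend),
    )
    s, moves = _traceback(M, U, L, PM, PU, PL, len(a), len(b))
    return float(s), moves[::-1]
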