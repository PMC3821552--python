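"""Numerical kernels (numba-compiled) behind the banded and full aligners.

Sequences arrive as uint8 letter-index arrays; substitution scores as a
dense (A, A) float64 table.  The banded kernels store cell (i, j) of the
diagonal stripe |i - j| <= beta at row i, column j - i + beta, so each
row has width 2*beta + 1 and no cell outside the band is ever touched.
"""

from __future__ import annotations

import numpy as np
from numba import njit

COUNT_INF = np.int64(1) << 40
SCORE_NEG = -1.0e30


@njit(cache=True)
def fill_count_band(t, x, beta):  # pragma: no cover - exercised via core
    n = t.shape[0]
    m = x.shape[0]
    imax = min(n, m + beta)
    width = 2 * beta + 1
    G = np.full((imax + 1, width), COUNT_INF, dtype=np.int64)
    H = np.zeros((imax + 1, width), dtype=np.int64)
    ncells = 0

    G[0, beta] = 0
    jtop = min(m, beta)
    for j in range(1, jtop + 1):
        G[0, j + beta] = 0  # leading gap in the text: x[1..j] against stars
        H[0, j + beta] = j
        ncells += 1

    for i in range(1, imax + 1):
        jlo = max(0, i - beta)
        jhi = min(m, i + beta)
        for j in range(jlo, jhi + 1):
            d = j - i + beta
            ncells += 1
            if j == 0:
                G[i, d] = 0  # leading gap in the pattern: t[1..i] against stars
                H[i, d] = i
                continue
            diag = G[i - 1, d] + (0 if t[i - 1] == x[j - 1] else 1)
            if i == j:
                G[i, d] = diag
            elif i > j:
                jump = G[j, beta]  # diagonal cell (j, j), then gap in pattern
                if diag <= jump:
                    G[i, d] = diag
                else:
                    G[i, d] = jump
                    H[i, d] = i - j
            else:
                jump = G[i, beta]  # diagonal cell (i, i), then gap in text
                if diag <= jump:
                    G[i, d] = diag
                else:
                    G[i, d] = jump
                    H[i, d] = j - i
    return G, H, ncells


@njit(cache=True)
def fill_score_band(t, x, submat, gap_open, gap_extend, beta):  # pragma: no cover
    n = t.shape[0]
    m = x.shape[0]
    imax = min(n, m + beta)
    width = 2 * beta + 1
    S = np.full((imax + 1, width), SCORE_NEG, dtype=np.float64)
    H = np.zeros((imax + 1, width), dtype=np.int64)
    ncells = 0

    S[0, beta] = 0.0
    jtop = min(m, beta)
    for j in range(1, jtop + 1):
        S[0, j + beta] = -(gap_open + (j - 1) * gap_extend)
        H[0, j + beta] = j
        ncells += 1

    for i in range(1, imax + 1):
        jlo = max(0, i - beta)
        jhi = min(m, i + beta)
        for j in range(jlo, jhi + 1):
            d = j - i + beta
            ncells += 1
            if j == 0:
                S[i, d] = -(gap_open + (i - 1) * gap_extend)
                H[i, d] = i
                continue
            diag = S[i - 1, d] + submat[t[i - 1], x[j - 1]]
            if i == j:
                S[i, d] = diag
            elif i > j:
                jump = S[j, beta] - (gap_open + (i - j - 1) * gap_extend)
                if diag >= jump:
                    S[i, d] = diag
                else:
                    S[i, d] = jump
                    H[i, d] = i - j
            else:
                jump = S[i, beta] - (gap_open + (j - i - 1) * gap_extend)
                if diag >= jump:
                    S[i, d] = diag
                else:
                    S[i, d] = jump
                    H[i, d] = j - i
    return S, H, ncells


@njit(cache=True)
def gotoh_fill(t, x, submat, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap DP (three-state Gotoh) with free end gaps on both sequences.

    State M aligns t[i] with x[j]; Ix puts t[i] against a gap (gap in the
    pattern); Iy puts x[j] against a gap (gap in the text).  Leading gaps
    are free via the Ix/Iy borders; trailing gaps are freed by taking the
    optimum over the last row and column.
    """
    n = t.shape[0]
    m = x.shape[0]
    M = np.full((n + 1, m + 1), SCORE_NEG, dtype=np.float64)
    Ix = np.full((n + 1, m + 1), SCORE_NEG, dtype=np.float64)
    Iy = np.full((n + 1, m + 1), SCORE_NEG, dtype=np.float64)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = 0.0
    for j in range(1, m + 1):
        Iy[0, j] = 0.0
    for i in range(1, n + 1):
        ti = t[i - 1]
        for j in range(1, m + 1):
            s = submat[ti, x[j - 1]]
            best = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
            M[i, j] = s + best

            a = M[i - 1, j] - gap_open
            b = Ix[i - 1, j] - gap_extend
            c = Iy[i - 1, j] - gap_open
            Ix[i, j] = max(a, b, c)

            a = M[i, j - 1] - gap_open
            b = Iy[i, j - 1] - gap_extend
            c = Ix[i, j - 1] - gap_open
            Iy[i, j] = max(a, b, c)
    return M, Ix, Iy
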