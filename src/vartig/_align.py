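"""Numba dynamic-programming kernels shared by the profile machinery.

Two kernels: Smith-Waterman local alignment of a PSSM against an encoded
sequence, and Gotoh global alignment over a precomputed column-pair score
matrix (used for profile-profile merging). Both use affine gap costs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=False)
def sw_pssm(pssm, seq, gap_open, gap_ext):
    """Local alignment of a position-specific score matrix to a sequence.

    pssm: (Lq, 20) float64; seq: int8 indices (<0 scores 0).
    Returns (score, qs, qe, ts, te) with 0-based inclusive footprints;
    qs == -1 if the best score is 0 (no positive-scoring alignment).
    """
    lq = pssm.shape[0]
    lt = seq.shape[0]
    H = np.zeros((lq + 1, lt + 1))
    E = np.zeros((lq + 1, lt + 1))
    F = np.zeros((lq + 1, lt + 1))
    best = 0.0
    bi = -1
    bj = -1
    for i in range(1, lq + 1):
        for j in range(1, lt + 1):
            c = seq[j - 1]
            s = pssm[i - 1, c] if c >= 0 else 0.0
            e = H[i, j - 1] - gap_open
            if E[i, j - 1] - gap_ext > e:
                e = E[i, j - 1] - gap_ext
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            if F[i - 1, j] - gap_ext > f:
                f = F[i - 1, j] - gap_ext
            F[i, j] = f
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if bi < 0:
        return 0.0, -1, -1, -1, -1
    # traceback from the best cell to the first zero-scoring H cell
    i = bi
    j = bj
    state = 0  # 0=H, 1=E (gap in profile), 2=F (gap in target)
    eps = 1e-9
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] <= eps:
                break
            c = seq[j - 1]
            s = pssm[i - 1, c] if c >= 0 else 0.0
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
                i -= 1
                j -= 1
            elif abs(H[i, j] - E[i, j]) < eps:
                state = 1
            else:
                state = 2
        elif state == 1:
            if abs(E[i, j] - (H[i, j - 1] - gap_open)) < eps:
                state = 0
                j -= 1
            else:
                j -= 1
        else:
            if abs(F[i, j] - (H[i - 1, j] - gap_open)) < eps:
                state = 0
                i -= 1
            else:
                i -= 1
    return best, i, bi - 1, j, bj - 1


@njit(cache=False)
def gotoh_global(scores, gap_open, gap_ext):
    """Global affine-gap alignment over a (La, Lb) score matrix.

    Returns (n, apath, bpath): the first n entries of apath/bpath give, per
    output column, the 0-based row/column index consumed or -1 for a gap.
    """
    la = scores.shape[0]
    lb = scores.shape[1]
    M = np.full((la + 1, lb + 1), NEG_INF)
    X = np.full((la + 1, lb + 1), NEG_INF)  # gap in b (consume a)
    Y = np.full((la + 1, lb + 1), NEG_INF)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_ext
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_ext
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            d = M[i - 1, j - 1]
            if X[i - 1, j - 1] > d:
                d = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > d:
                d = Y[i - 1, j - 1]
            M[i, j] = d + scores[i - 1, j - 1]
            x = M[i - 1, j] - gap_open
            if X[i - 1, j] - gap_ext > x:
                x = X[i - 1, j] - gap_ext
            X[i, j] = x
            y = M[i, j - 1] - gap_open
            if Y[i, j - 1] - gap_ext > y:
                y = Y[i, j - 1] - gap_ext
            Y[i, j] = y
    apath = np.empty(la + lb, dtype=np.int64)
    bpath = np.empty(la + lb, dtype=np.int64)
    n = 0
    i = la
    j = lb
    if M[i, j] >= X[i, j] and M[i, j] >= Y[i, j]:
        state = 0
    elif X[i, j] >= Y[i, j]:
        state = 1
    else:
        state = 2
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            apath[n] = i - 1
            bpath[n] = j - 1
            n += 1
            d = M[i, j] - scores[i - 1, j - 1]
            if abs(d - M[i - 1, j - 1]) < eps:
                state = 0
            elif abs(d - X[i - 1, j - 1]) < eps:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif (state == 1 and i > 0) or (state == 0 and j == 0):
            apath[n] = i - 1
            bpath[n] = -1
            n += 1
            if i > 1 or j > 0:
                if abs(X[i, j] - (M[i - 1, j] - gap_open)) < eps:
                    state = 0
                else:
                    state = 1
            i -= 1
        else:
            apath[n] = -1
            bpath[n] = j - 1
            n += 1
            if j > 1 or i > 0:
                if abs(Y[i, j] - (M[i, j - 1] - gap_open)) < eps:
                    state = 0
                else:
                    state = 2
            j -= 1
    # reverse in place
    for k in range(n // 2):
        apath[k], apath[n - 1 - k] = apath[n - 1 - k], apath[k]
        bpath[k], bpath[n - 1 - k] = bpath[n - 1 - k], bpath[k]
    return n, apath, bpath
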