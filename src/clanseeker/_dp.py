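"""Gotoh local dynamic programming kernel (numba-jitted).

Three-state affine-gap Smith-Waterman over a precomputed column-pair score
matrix.  States: M (aligned pair), X (gap in target, consumes query column,
"up"), Y (gap in query, consumes target column, "left").  Gap-to-gap
transitions between X and Y are allowed, each opening its own gap, which
matches the enumeration oracle used in the tests.

Tie-breaking is fixed: when scores tie, M prefers diagonal (M) over X over Y
over restart; X and Y prefer M over their own extension.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

# pointer codes
P_STOP = 0
P_M = 1
P_X = 2
P_Y = 3


@njit(cache=True)
def gotoh_local(S, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = S.shape
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = NEG
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: align columns i,j; previous state or fresh start
            v = M[i - 1, j - 1]
            p = P_M
            if X[i - 1, j - 1] > v:
                v = X[i - 1, j - 1]
                p = P_X
            if Y[i - 1, j - 1] > v:
                v = Y[i - 1, j - 1]
                p = P_Y
            if 0.0 > v:
                v = 0.0
                p = P_STOP
            M[i, j] = S[i - 1, j - 1] + v
            pM[i, j] = p

            # X: gap in target (consume query column i)
            v = M[i - 1, j] + gap_open
            p = P_M
            if X[i - 1, j] + gap_extend > v:
                v = X[i - 1, j] + gap_extend
                p = P_X
            if Y[i - 1, j] + gap_open > v:
                v = Y[i - 1, j] + gap_open
                p = P_Y
            X[i, j] = v
            pX[i, j] = p

            # Y: gap in query (consume target column j)
            v = M[i, j - 1] + gap_open
            p = P_M
            if X[i, j - 1] + gap_open > v:
                v = X[i, j - 1] + gap_open
                p = P_X
            if Y[i, j - 1] + gap_extend > v:
                v = Y[i, j - 1] + gap_extend
                p = P_Y
            Y[i, j] = v
            pY[i, j] = p

            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    return best, bi, bj, pM, pX, pY


def traceback(bi: int, bj: int, pM, pX, pY) -> list[tuple[int, int]]:
    """Follow pointers from the best M cell back to the local start.

    Returns aligned (query_col, target_col) pairs, 1-based, ascending.
    """
    pairs = []
    i, j = bi, bj
    state = P_M
    while i > 0 and j > 0:
        if state == P_M:
            pairs.append((i, j))
            nxt = pM[i, j]
            i -= 1
            j -= 1
            if nxt == P_STOP:
                break
            state = nxt
        elif state == P_X:
            nxt = pX[i, j]
            i -= 1
            state = nxt
        else:  # P_Y
            nxt = pY[i, j]
            j -= 1
            state = nxt
    pairs.reverse()
    return pairs
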