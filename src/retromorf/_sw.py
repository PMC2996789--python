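"""Numba kernels for Smith–Waterman local alignment with affine gaps.

Gap convention (BLAST-style): a gap of length L costs
``gap_open + L * gap_extend``, i.e. the first gap residue costs
``gap_open + gap_extend`` and each further residue ``gap_extend``.

Sequences arrive as int64 code arrays indexing into the substitution
matrix.  ``sw_score`` / ``sw_score_batch`` are the score-only fast path
used for shuffle decoys; ``sw_matrices`` returns the full H/E/F dynamic
programming matrices for traceback.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=True)
def sw_score(a, b, sub, gap_open, gap_extend):
    """Optimal local alignment score (two-row Gotoh)."""
    n, m = a.shape[0], b.shape[0]
    open_cost = gap_open + gap_extend
    h_prev = np.zeros(m + 1)
    f_prev = np.full(m + 1, NEG_INF)
    h_cur = np.zeros(m + 1)
    f_cur = np.full(m + 1, NEG_INF)
    best = 0.0
    for i in range(1, n + 1):
        h_cur[0] = 0.0
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - open_cost, e - gap_extend)
            f = max(h_prev[j] - open_cost, f_prev[j] - gap_extend)
            f_cur[j] = f
            h = h_prev[j - 1] + sub[ai, b[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best


@njit(cache=True)
def sw_score_batch(queries, b, sub, gap_open, gap_extend):
    """Scores of many equal-length queries against one target."""
    out = np.empty(queries.shape[0])
    for k in range(queries.shape[0]):
        out[k] = sw_score(queries[k], b, sub, gap_open, gap_extend)
    return out


@njit(cache=True)
def sw_matrices(a, b, sub, gap_open, gap_extend):
    """Full Gotoh matrices H, E, F ((n+1) x (m+1)) for traceback.

    E holds gaps in the first sequence (horizontal moves), F gaps in the
    second (vertical moves).
    """
    n, m = a.shape[0], b.shape[0]
    open_cost = gap_open + gap_extend
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - open_cost, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - open_cost, F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            if F[i, j] > h:
                h = F[i, j]
            if E[i, j] > h:
                h = E[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F
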