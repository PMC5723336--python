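"""Dynamic-programming alignment kernels (numba-compiled).

Conventions shared by both kernels:

* sequences are integer-encoded (indices into the 20-residue alphabet;
  unknown residues such as X encode as -1 and score ``UNK_SCORE``),
* an affine gap of length L costs ``open + ext * L``,
* traceback ties prefer diagonal > up (gap in reference / consume query)
  > left (gap in query / consume reference), and among equal-scoring end
  cells the smallest (query index, reference index) wins.
"""

from __future__ import annotations

import numpy as np
from numba import njit

UNK_SCORE = -1.0

OP_MATCH = 0  # consume query + reference
OP_INS = 1    # consume query only (gap in reference)
OP_DEL = 2    # consume reference only (gap in query)

NEG = -1e30


@njit(cache=True, fastmath=True)
def sw_score(q, r, mat, gap_open, gap_ext):
    """Optimal local alignment score (affine gaps), score only.

    Single-row formulation: H holds the current row in place, ``diag``
    carries the previous row's H[j-1]."""
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros(n + 1)
    F = np.full(n + 1, NEG)
    best = 0.0
    go_ge = gap_open + gap_ext
    for i in range(m):
        qi = q[i]
        diag = H[0]
        e = NEG
        if qi >= 0:
            row = mat[qi]
            for j in range(1, n + 1):
                up = H[j]
                rj = r[j - 1]
                s = row[rj] if rj >= 0 else UNK_SCORE
                e_open = H[j - 1] - go_ge
                e = e - gap_ext
                if e_open > e:
                    e = e_open
                f = F[j] - gap_ext
                f_open = up - go_ge
                if f_open > f:
                    f = f_open
                F[j] = f
                h = diag + s
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0.0:
                    h = 0.0
                diag = up
                H[j] = h
                if h > best:
                    best = h
        else:
            for j in range(1, n + 1):
                up = H[j]
                e_open = H[j - 1] - go_ge
                e = e - gap_ext
                if e_open > e:
                    e = e_open
                f = F[j] - gap_ext
                f_open = up - go_ge
                if f_open > f:
                    f = f_open
                F[j] = f
                h = diag + UNK_SCORE
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0.0:
                    h = 0.0
                diag = up
                H[j] = h
                if h > best:
                    best = h
    return best


PAD_CODE = 20  # padding/unknown residue index in the extended 21x21 matrix


@njit(cache=True, fastmath=True)
def sw_batch(QT, r, mat21, gap_open, gap_ext):
    """Local-alignment scores of many queries against one reference.

    ``QT`` is (query_len, n_queries), column-major per query, padded at the
    end with PAD_CODE; ``mat21`` is the score matrix extended with a
    PAD_CODE row/column scoring UNK_SCORE against everything (padding can
    only lower an alignment's score, so padded maxima equal unpadded ones).
    Vectorizes across queries. Returns best score per query.
    """
    m, R = QT.shape
    n = r.shape[0]
    H = np.zeros((n + 1, R))
    F = np.full((n + 1, R), NEG)
    diag = np.zeros(R)
    e = np.empty(R)
    best = np.zeros(R)
    go_ge = gap_open + gap_ext
    for i in range(m):
        qrow = QT[i]
        for t in range(R):
            e[t] = NEG
            diag[t] = H[0, t]
        for j in range(1, n + 1):
            col = mat21[:, r[j - 1]]
            Hj = H[j]
            Hj1 = H[j - 1]
            Fj = F[j]
            for t in range(R):
                up = Hj[t]
                sc = col[qrow[t]]
                e_open = Hj1[t] - go_ge
                ev = e[t] - gap_ext
                if e_open > ev:
                    ev = e_open
                e[t] = ev
                f = Fj[t] - gap_ext
                f_open = up - go_ge
                if f_open > f:
                    f = f_open
                Fj[t] = f
                h = diag[t] + sc
                if ev > h:
                    h = ev
                if f > h:
                    h = f
                if h < 0.0:
                    h = 0.0
                diag[t] = up
                Hj[t] = h
                if h > best[t]:
                    best[t] = h
    return best


@njit(cache=True)
def sw_scores_vs_db(q, db, offsets, mat, gap_open, gap_ext):
    """Local-alignment scores of ``q`` against each sequence in a
    concatenated database (``offsets`` has n_refs+1 entries)."""
    nref = offsets.shape[0] - 1
    out = np.zeros(nref)
    for k in range(nref):
        out[k] = sw_score(q, db[offsets[k] : offsets[k + 1]], mat, gap_open, gap_ext)
    return out


@njit(cache=True)
def sw_traceback(q, r, mat, gap_open, gap_ext):
    """Full local alignment with traceback.

    Returns (score, q_start, q_end, r_start, r_end, ops, n_ops) with
    0-based half-open intervals; ops codes: 0 match, 1 gap-in-reference
    (consume query), 2 gap-in-query (consume reference), in alignment
    order.
    """
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop,1 diag,2 up,3 left
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            rj = r[j - 1]
            if qi < 0 or rj < 0:
                s = UNK_SCORE
            else:
                s = mat[qi, rj]
            e_open = H[i, j - 1] - gap_open - gap_ext
            e_ext = E[i, j - 1] - gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - gap_open - gap_ext
            f_ext = F[i - 1, j] - gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = 0
            if diag >= h and diag >= F[i, j] and diag >= E[i, j]:
                h = diag
                p = 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h = F[i, j]
                p = 2
            elif E[i, j] >= h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    ops = np.zeros(m + n, dtype=np.uint8)
    nops = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops[nops] = OP_MATCH
                nops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 2:
            opened = ptrF[i, j] == 1
            ops[nops] = OP_INS
            nops += 1
            i -= 1
            if opened:
                state = 0
        else:
            opened = ptrE[i, j] == 1
            ops[nops] = OP_DEL
            nops += 1
            j -= 1
            if opened:
                state = 0
    # reverse ops
    for k in range(nops // 2):
        tmp = ops[k]
        ops[k] = ops[nops - 1 - k]
        ops[nops - 1 - k] = tmp
    return best, i, bi, j, bj, ops, nops


@njit(cache=True)
def profile_align(q, colscore, del_open, del_ext, ins_open, ins_ext):
    """Global-in-query / local-in-profile affine alignment.

    ``colscore[j, a]`` is the emission score of residue ``a`` at profile
    column ``j``; unknown residues (code < 0) emit 0. ``del_open/del_ext`` are
    per-column costs for skipping a profile column (occupancy-scaled, so
    all-gap columns are free to skip). Returns (score, cols) where
    ``cols[i]`` is the profile column aligned to query residue ``i`` or
    -1 for an insertion relative to the profile.
    """
    m = q.shape[0]
    n = colscore.shape[0]
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)  # gap in query: consume column
    F = np.full((m + 1, n + 1), NEG)  # insertion: consume query residue
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for j in range(n + 1):
        H[0, j] = 0.0  # free leading profile columns
    for i in range(1, m + 1):
        H[i, 0] = -(ins_open + ins_ext * i)
        F[i, 0] = H[i, 0]
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            emit = colscore[j - 1, qi] if qi >= 0 else 0.0
            e_open = H[i, j - 1] - del_open[j - 1] - del_ext[j - 1]
            e_ext = E[i, j - 1] - del_ext[j - 1]
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] - ins_open - ins_ext
            f_ext = F[i - 1, j] - ins_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + emit
            if diag >= F[i, j] and diag >= E[i, j]:
                H[i, j] = diag
                ptrH[i, j] = 1
            elif F[i, j] >= E[i, j]:
                H[i, j] = F[i, j]
                ptrH[i, j] = 2
            else:
                H[i, j] = E[i, j]
                ptrH[i, j] = 3
    # free trailing profile columns: best over H[m, j]
    best = H[m, 0]
    bj = 0
    for j in range(1, n + 1):
        if H[m, j] > best:
            best = H[m, j]
            bj = j
    cols = np.full(m, -1, dtype=np.int64)
    i = m
    j = bj
    state = 0
    while i > 0:
        if j == 0:
            i -= 1  # leading query residues are insertions
            continue
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                cols[i - 1] = j - 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 2:
            opened = ptrF[i, j] == 1
            i -= 1  # insertion: query residue gets no column
            if opened:
                state = 0
        else:
            opened = ptrE[i, j] == 1
            j -= 1
            if opened:
                state = 0
    return best, cols
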