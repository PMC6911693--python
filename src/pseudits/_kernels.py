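"""Numba-compiled dynamic-programming kernels.

Hot loops only: affine-gap global alignment (Gotoh), profile-profile
alignment for the progressive MSA, and the nested secondary-structure
minimum-free-energy fill.  All functions operate on small integer /
float arrays; the user-facing wrappers live in :mod:`pseudits.seqio`
and :mod:`pseudits.pseudogene_screen`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e18
POS_INF = 1.0e18

# residue encoding shared across kernels: A=0 C=1 G=2 T/U=3 N=4 gap=5
ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4, "-": 5}
DECODE = "ACGTN-"


def encode_seq(residues: str) -> np.ndarray:
    return np.array([ENCODE[c] for c in residues], dtype=np.int8)


def decode_seq(arr) -> str:
    return "".join(DECODE[int(x)] for x in arr)


@njit(cache=True)
def _subst(x, y, match, mismatch):
    # N never counts as a match
    if x == y and x < 4:
        return match
    return mismatch


@njit(cache=True)
def gotoh_align(a, b, match, mismatch, gap_open, gap_extend):
    """Affine-gap global alignment of encoded sequences.

    A gap of length L costs gap_open + (L-1)*gap_extend.  Tie-breaking
    prefers diagonal moves, then gaps in b (consuming a), then gaps in a.
    Returns (score, ops) where ops[k] in {0: diagonal, 1: gap-in-b,
    2: gap-in-a} read left to right.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b: consumes a
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a: consumes b
    # pointers: state-from for each state cell (0=M,1=X,2=Y)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _subst(a[i - 1], b[j - 1], match, mismatch)
            # M: diagonal from best of three, priority M > X > Y
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: gap in b, consume a[i-1]
            best = M[i - 1, j] + gap_open
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            # Y: gap in a, consume b[j-1]
            best = M[i, j - 1] + gap_open
            ptr = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    # terminal state, priority M > X > Y
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            j -= 1
    return score, ops[k:]


@njit(cache=True)
def profile_align(pa, pb, match, mismatch, gap_open, gap_extend):
    """Affine-gap alignment of two column profiles.

    pa, pb are (L, 6) count matrices over A,C,G,T,N,-.  Column score is
    the expected pairwise substitution score; gap symbols score 0.
    Returns ops coded as in gotoh_align (1: column from pa only).
    """
    n, m = pa.shape[0], pb.shape[0]
    ta = pa.sum(axis=1)
    tb = pb.sum(axis=1)
    col = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            s = 0.0
            for x in range(5):
                if pa[i, x] == 0:
                    continue
                for y in range(5):
                    if pb[j, y] == 0:
                        continue
                    s += pa[i, x] * pb[j, y] * _subst(x, y, match, mismatch)
            col[i, j] = s / (ta[i] * tb[j])
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = col[i - 1, j - 1]
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            best = M[i - 1, j] + gap_open
            ptr = 0
            if X[i - 1, j] + gap_extend > best:
                best = X[i - 1, j] + gap_extend
                ptr = 1
            if Y[i - 1, j] + gap_open > best:
                best = Y[i - 1, j] + gap_open
                ptr = 2
            X[i, j] = best
            pX[i, j] = ptr
            best = M[i, j - 1] + gap_open
            ptr = 0
            if X[i, j - 1] + gap_open > best:
                best = X[i, j - 1] + gap_open
                ptr = 1
            if Y[i, j - 1] + gap_extend > best:
                best = Y[i, j - 1] + gap_extend
                ptr = 2
            Y[i, j] = best
            pY[i, j] = ptr
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = pY[i, j]
            j -= 1
    return score, ops[k:]


@njit(cache=True)
def fold_fill(seq, pair_type, stack, hairpin_penalty):
    """Fill the folding matrices for the simplified stacking model.

    seq: encoded RNA (T already read as U, i.e. code 3).
    pair_type: 5x5 int matrix, >=0 for an allowed pair else -1.
    stack: (n_pair_types, n_pair_types) stacking energies (outer, inner).
    Energy of a structure = sum of stacking terms over adjacent nested
    pairs + hairpin_penalty per hairpin-closing pair; everything else 0.
    Hairpin loops need >= 3 unpaired bases, so any pair spans >= 4.

    Returns (V, Y, YX):
      V[i,j]  best energy on [i,j] given i pairs with j (POS_INF if i-j
              cannot pair),
      Y[i,j]  best energy over structures on [i,j] with >= 1 pair,
      YX[i,j] same but with i and j not paired to each other.
    """
    n = len(seq)
    V = np.full((n, n), POS_INF)
    Y = np.full((n, n), POS_INF)
    YX = np.full((n, n), POS_INF)
    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            # YX(i,j)
            best = POS_INF
            if Y[i + 1, j] < best:
                best = Y[i + 1, j]
            for k in range(i + 4, j):
                if V[i, k] >= POS_INF:
                    continue
                rest = 0.0
                if k + 1 < j and Y[k + 1, j] < 0.0:
                    rest = Y[k + 1, j]
                if V[i, k] + rest < best:
                    best = V[i, k] + rest
            YX[i, j] = best
            # V(i,j)
            pt = pair_type[seq[i], seq[j]]
            if pt >= 0:
                v = hairpin_penalty
                if span >= 6:
                    pt_in = pair_type[seq[i + 1], seq[j - 1]]
                    if pt_in >= 0 and V[i + 1, j - 1] < POS_INF:
                        cand = stack[pt, pt_in] + V[i + 1, j - 1]
                        if cand < v:
                            v = cand
                    if YX[i + 1, j - 1] < v:
                        v = YX[i + 1, j - 1]
                V[i, j] = v
            # Y(i,j)
            y = YX[i, j]
            if V[i, j] < y:
                y = V[i, j]
            Y[i, j] = y
    return V, Y, YX
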