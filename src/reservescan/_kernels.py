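"""Numba dynamic-programming kernels for alignment and profile scoring.

Three kernels:

* :func:`identity_dp` — global alignment objective for percent identity:
  maximise the number of matched columns, and among alignments with maximal
  matches minimise the number of gap columns.  Both quantities are packed
  into one integer score ``K * matches - gap_columns`` with ``K`` larger than
  any possible gap count, so the optimum determines (matches, gaps) uniquely
  and the resulting identity is symmetric in its arguments.

* :func:`nw_path` — Needleman-Wunsch over an arbitrary position-score matrix
  with a linear gap penalty, returning the edit path (used for pairwise and
  sequence-to-profile steps of progressive alignment).

* :func:`viterbi_local` — best local log-odds alignment of a protein against
  a profile model (match/insert/delete states, free begin into any match
  state, free end from any match state), with start/end coordinates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def identity_dp(a, b, K):  # pragma: no cover - exercised via pairwise_identity
    """Return max over global alignments of ``K*matches - gap_columns``."""
    la = a.shape[0]
    lb = b.shape[0]
    prev = np.empty(lb + 1, np.int64)
    cur = np.empty(lb + 1, np.int64)
    for j in range(lb + 1):
        prev[j] = -j
    for i in range(1, la + 1):
        cur[0] = -i
        for j in range(1, lb + 1):
            diag = prev[j - 1]
            if a[i - 1] == b[j - 1]:
                diag += K
            best = diag
            up = prev[j] - 1
            if up > best:
                best = up
            left = cur[j - 1] - 1
            if left > best:
                best = left
            cur[j] = best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[lb]


@njit(cache=True)
def nw_path(S, gap):  # pragma: no cover - exercised via build_msa
    """Global alignment over score matrix ``S`` (n x m) with linear ``gap``.

    Returns an int8 op array along the alignment: 0 = pair (i,j), 1 = row
    element unpaired (gap in the column axis), 2 = column element unpaired.
    Ties prefer pairing, then consuming the row element.
    """
    n, m = S.shape
    F = np.empty((n + 1, m + 1), np.float64)
    T = np.zeros((n + 1, m + 1), np.int8)
    F[0, 0] = 0.0
    for j in range(1, m + 1):
        F[0, j] = F[0, j - 1] + gap
        T[0, j] = 2
    for i in range(1, n + 1):
        F[i, 0] = F[i - 1, 0] + gap
        T[i, 0] = 1
        for j in range(1, m + 1):
            best = F[i - 1, j - 1] + S[i - 1, j - 1]
            t = 0
            up = F[i - 1, j] + gap
            if up > best:
                best = up
                t = 1
            left = F[i, j - 1] + gap
            if left > best:
                best = left
                t = 2
            F[i, j] = best
            T[i, j] = t
    ops = np.empty(n + m, np.int8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        t = T[i, j]
        ops[k] = t
        k += 1
        if t == 0:
            i -= 1
            j -= 1
        elif t == 1:
            i -= 1
        else:
            j -= 1
    return ops[:k][::-1].copy()


@njit(cache=True)
def viterbi_local(em, ins, lMM, lMI, lMD, lIM, lII, lDM, lDD, entry):  # pragma: no cover
    """Best local alignment log-odds score of a protein against a profile.

    Parameters
    ----------
    em : (L, m) float64
        Match-emission log-odds of target residue t emitted by match state k.
    ins : (L,) float64
        Insert-emission log-odds of target residue t (0 when inserts emit
        background).
    lMM..lDD : (m,) float64
        Log transition scores out of state index k into the k+1 / same-index
        successor (M->M, M->I, M->D, I->M, I->I, D->M, D->D); index m-1 unused.
    entry : float64
        Log score of entering any match state from the begin state.

    Returns
    -------
    (score, t0, t1, k0, k1) : best score and inclusive start/end coordinates
    of the maximising path over target positions (t) and match states (k),
    both 0-based.  Paths start and end on a match state.
    """
    L, m = em.shape
    VM = np.full(m, NEG_INF)
    VI = np.full(m, NEG_INF)
    VD = np.full(m, NEG_INF)
    # start coordinates (target, state) carried along each path
    Mt = np.zeros(m, np.int32)
    Mk = np.zeros(m, np.int32)
    It = np.zeros(m, np.int32)
    Ik = np.zeros(m, np.int32)
    Dt = np.zeros(m, np.int32)
    Dk = np.zeros(m, np.int32)
    nMt = np.zeros(m, np.int32)
    nMk = np.zeros(m, np.int32)
    nIt = np.zeros(m, np.int32)
    nIk = np.zeros(m, np.int32)
    nDt = np.zeros(m, np.int32)
    nDk = np.zeros(m, np.int32)
    nVM = np.empty(m)
    nVI = np.empty(m)
    nVD = np.empty(m)

    best = NEG_INF
    bt0 = 0
    bt1 = 0
    bk0 = 0
    bk1 = 0

    for t in range(L):
        for k in range(m):
            # --- match state k, consuming residue t
            s = entry
            st = t
            sk = k
            if k > 0:
                v = VM[k - 1] + lMM[k - 1]
                if v > s:
                    s = v
                    st = Mt[k - 1]
                    sk = Mk[k - 1]
                v = VI[k - 1] + lIM[k - 1]
                if v > s:
                    s = v
                    st = It[k - 1]
                    sk = Ik[k - 1]
                v = VD[k - 1] + lDM[k - 1]
                if v > s:
                    s = v
                    st = Dt[k - 1]
                    sk = Dk[k - 1]
            vm = em[t, k] + s
            nVM[k] = vm
            nMt[k] = st
            nMk[k] = sk
            if vm > best:
                best = vm
                bt0 = st
                bt1 = t
                bk0 = sk
                bk1 = k
            # --- insert state k (between match k and k+1), consuming residue t
            s = VM[k] + lMI[k]
            st = Mt[k]
            sk = Mk[k]
            v = VI[k] + lII[k]
            if v > s:
                s = v
                st = It[k]
                sk = Ik[k]
            nVI[k] = ins[t] + s
            nIt[k] = st
            nIk[k] = sk
            # --- delete state k, same row (consumes no residue)
            if k > 0:
                s = nVM[k - 1] + lMD[k - 1]
                st = nMt[k - 1]
                sk = nMk[k - 1]
                v = nVD[k - 1] + lDD[k - 1]
                if v > s:
                    s = v
                    st = nDt[k - 1]
                    sk = nDk[k - 1]
                nVD[k] = s
                nDt[k] = st
                nDk[k] = sk
            else:
                nVD[k] = NEG_INF
                nDt[k] = t
                nDk[k] = k
        for k in range(m):
            VM[k] = nVM[k]
            VI[k] = nVI[k]
            VD[k] = nVD[k]
            Mt[k] = nMt[k]
            Mk[k] = nMk[k]
            It[k] = nIt[k]
            Ik[k] = nIk[k]
            Dt[k] = nDt[k]
            Dk[k] = nDk[k]
    return best, bt0, bt1, bk0, bk1
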