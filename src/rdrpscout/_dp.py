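"""Numba kernels for local profile-HMM dynamic programming.

All scores are base-2 log-odds against an i.i.d. background over the
residues consumed by the alignment.  The model is a plan7-style local
profile: uniform entry into any match state (probability 1/M), free exit
after any match state, insert emissions tied to the background (log-odds
0), and deletes consuming no residue.

State recurrence, with VM[i][k] the best score of a path ending in match
state k having consumed i residues::

    VM[i][k] = lo[k][s_i] + max(entry, VM[i-1][k-1]+tMM, VI[i-1][k-1]+tIM,
                                VD[i-1][k-1]+tDM)
    VI[i][k] = max(VM[i-1][k]+tMI, VI[i-1][k]+tII)
    VD[i][k] = max(VM[i][k-1]+tMD, VD[i][k-1]+tDD)      (same row: no emission)

Viterbi is the maximum of VM over all cells; Forward replaces max with
log-sum-exp everywhere, summing odds ratios over all local paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def _lse2(a: float, b: float) -> float:
    """log2(2^a + 2^b), safe against -inf sentinels."""
    if a < b:
        a, b = b, a
    if a <= NEG_INF / 2:
        return NEG_INF
    d = b - a
    if d < -60.0:
        return a
    return a + np.log2(1.0 + 2.0**d)


@njit(cache=True)
def viterbi_score(lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq, entry):
    """Best local log-odds bit score (no traceback)."""
    M = lo.shape[0]
    L = seq.shape[0]
    vm_prev = np.full(M, NEG_INF)
    vi_prev = np.full(M, NEG_INF)
    vd_prev = np.full(M, NEG_INF)
    vm = np.empty(M)
    vi = np.empty(M)
    vd = np.empty(M)
    best = NEG_INF
    for i in range(1, L + 1):
        s = seq[i - 1]
        for k in range(M):
            cand = entry
            if k > 0:
                x = vm_prev[k - 1] + tmm[k - 1]
                if x > cand:
                    cand = x
                x = vi_prev[k - 1] + tim[k - 1]
                if x > cand:
                    cand = x
                x = vd_prev[k - 1] + tdm[k - 1]
                if x > cand:
                    cand = x
            vm[k] = lo[k, s] + cand
            if vm[k] > best:
                best = vm[k]
            a = vm_prev[k] + tmi[k]
            b = vi_prev[k] + tii[k]
            vi[k] = a if a > b else b
            if k > 0:
                a = vm[k - 1] + tmd[k - 1]
                b = vd[k - 1] + tdd[k - 1]
                vd[k] = a if a > b else b
            else:
                vd[k] = NEG_INF
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
    return best


@njit(cache=True)
def viterbi_batch(lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seqs, entry):
    """Viterbi scores for a matrix of equal-length integer sequences."""
    n = seqs.shape[0]
    out = np.empty(n)
    for j in range(n):
        out[j] = viterbi_score(lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seqs[j], entry)
    return out


@njit(cache=True)
def viterbi_align(lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq, entry):
    """Full Viterbi with traceback.

    Returns (score, seq_from, seq_to, prof_from, prof_to, match_seq_pos,
    match_prof_col); the last two are parallel 1-based arrays giving the
    residue/column of every match state on the optimal path.
    """
    M = lo.shape[0]
    L = seq.shape[0]
    vm = np.full((L + 1, M), NEG_INF)
    vi = np.full((L + 1, M), NEG_INF)
    vd = np.full((L + 1, M), NEG_INF)
    # pointers: 0 entry, 1 from M, 2 from I, 3 from D
    pm = np.zeros((L + 1, M), dtype=np.int8)
    pi = np.zeros((L + 1, M), dtype=np.int8)
    pd = np.zeros((L + 1, M), dtype=np.int8)
    best = NEG_INF
    bi = -1
    bk = -1
    for i in range(1, L + 1):
        s = seq[i - 1]
        for k in range(M):
            cand = entry
            ptr = 0
            if k > 0:
                x = vm[i - 1, k - 1] + tmm[k - 1]
                if x > cand:
                    cand, ptr = x, 1
                x = vi[i - 1, k - 1] + tim[k - 1]
                if x > cand:
                    cand, ptr = x, 2
                x = vd[i - 1, k - 1] + tdm[k - 1]
                if x > cand:
                    cand, ptr = x, 3
            vm[i, k] = lo[k, s] + cand
            pm[i, k] = ptr
            if vm[i, k] > best:
                best = vm[i, k]
                bi, bk = i, k
            a = vm[i - 1, k] + tmi[k]
            b = vi[i - 1, k] + tii[k]
            if a >= b:
                vi[i, k] = a
                pi[i, k] = 1
            else:
                vi[i, k] = b
                pi[i, k] = 2
            if k > 0:
                a = vm[i, k - 1] + tmd[k - 1]
                b = vd[i, k - 1] + tdd[k - 1]
                if a >= b:
                    vd[i, k] = a
                    pd[i, k] = 1
                else:
                    vd[i, k] = b
                    pd[i, k] = 3

    # traceback from the best match cell
    match_i = np.empty(L + M, dtype=np.int64)
    match_k = np.empty(L + M, dtype=np.int64)
    nm = 0
    state = 1  # 1=M, 2=I, 3=D
    i, k = bi, bk
    while True:
        if state == 1:
            match_i[nm] = i
            match_k[nm] = k + 1
            nm += 1
            ptr = pm[i, k]
            if ptr == 0:
                break
            i -= 1
            k -= 1
            state = ptr
        elif state == 2:
            ptr = pi[i, k]
            i -= 1
            state = ptr
        else:  # delete
            ptr = pd[i, k]
            k -= 1
            state = ptr
    out_i = match_i[:nm][::-1].copy()
    out_k = match_k[:nm][::-1].copy()
    return best, out_i[0], bi, out_k[0], bk + 1, out_i, out_k


@njit(cache=True)
def forward_score(lo, tmm, tmi, tmd, tim, tii, tdm, tdd, seq, entry):
    """Forward bit score: log2 of the summed odds ratio over all local paths."""
    M = lo.shape[0]
    L = seq.shape[0]
    fm_prev = np.full(M, NEG_INF)
    fi_prev = np.full(M, NEG_INF)
    fd_prev = np.full(M, NEG_INF)
    fm = np.empty(M)
    fi = np.empty(M)
    fd = np.empty(M)
    total = NEG_INF
    for i in range(1, L + 1):
        s = seq[i - 1]
        for k in range(M):
            acc = entry
            if k > 0:
                acc = _lse2(acc, fm_prev[k - 1] + tmm[k - 1])
                acc = _lse2(acc, fi_prev[k - 1] + tim[k - 1])
                acc = _lse2(acc, fd_prev[k - 1] + tdm[k - 1])
            fm[k] = lo[k, s] + acc
            total = _lse2(total, fm[k])
            fi[k] = _lse2(fm_prev[k] + tmi[k], fi_prev[k] + tii[k])
            if k > 0:
                fd[k] = _lse2(fm[k - 1] + tmd[k - 1], fd[k - 1] + tdd[k - 1])
            else:
                fd[k] = NEG_INF
        fm_prev, fm = fm, fm_prev
        fi_prev, fi = fi, fi_prev
        fd_prev, fd = fd, fd_prev
    return total
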