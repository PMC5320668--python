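"""Numba kernel for the constrained epigenotype Viterbi.

The epigenotype chain of a haplotype chain is the maximizer of
(log-likelihood + log genotype prior) subject to strand-compatibility:
a methylated C must be paired with a methylated G on its CpG partner
position (and, in NOMe mode, a GpC pair may be methylated as meG-meC).
The pairing constraints are first-order, so the maximizer is found by a
Viterbi pass over an 8-state expansion of the six logical states:

    0..3  A, C, G, T
    4     meC that pairs with a meG on its right (CpG)
    5     meC paired to its left (NOMe GpC) or lone where permitted
    6     meG that pairs with a meC on its right (NOMe GpC)
    7     meG paired to its left (CpG) or lone where permitted

``enforce[j]`` marks positions where pairing is mandatory (everywhere in
WGBS mode; only isolated CpG/GpC positions in NOMe mode).  ``allow_gpc``
enables state 6 (NOMe mode only).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18

#: logical 6-state index for each of the 8 machine states
EMIS_MAP = (0, 1, 2, 3, 4, 4, 5, 5)

_FREE = (0, 1, 2, 3, 5, 7)  # states that place no demand on their successor


@njit(cache=True)
def chain_viterbi(P, M, mc, B, bo, lo, hi, enforce, allow_gpc, path, want_path):
    """Max score (and optionally the argmax path) of a chain over [lo, hi).

    Per-position 6-state scores are assembled on the fly as
    ``P[j] + M[j-mc] + B[j-bo]`` (each addend only where its array covers
    position j): P is the window-wide genotype-prior matrix, M a cached
    chain score matrix, B an optional extra read block.  All coordinates
    are window-relative.  ``path`` receives logical 6-state codes.
    """
    L = hi - lo
    v = np.full(8, NEG)
    nv = np.empty(8)
    bp = np.zeros((L, 8), dtype=np.int8)
    e = np.empty(6)
    nM = M.shape[0]
    nB = B.shape[0]
    for j0 in range(L):
        j = lo + j0
        for s in range(6):
            x = P[j, s]
            if mc <= j < mc + nM:
                x += M[j - mc, s]
            if bo <= j < bo + nB:
                x += B[j - bo, s]
            e[s] = x
        if j0 == 0:
            for s in range(8):
                v[s] = NEG
            for s in range(4):
                v[s] = e[s]
            v[4] = e[4]
            if allow_gpc:
                v[6] = e[5]
            if enforce[j] == 0:
                v[5] = e[4]
                v[7] = e[5]
            continue
        bestf = NEG
        argf = 0
        for s in _FREE:
            if v[s] > bestf:
                bestf = v[s]
                argf = s
        for b in range(8):
            nv[b] = NEG
        for b in range(4):
            nv[b] = bestf + e[b]
            bp[j0, b] = argf
        nv[4] = bestf + e[4]
        bp[j0, 4] = argf
        if allow_gpc:
            nv[6] = bestf + e[5]
            bp[j0, 6] = argf
        # meC paired-left (from a right-pairing meG) or lone
        sc = v[6]
        arg = 6
        if enforce[j] == 0 and bestf > sc:
            sc = bestf
            arg = argf
        nv[5] = sc + e[4]
        bp[j0, 5] = arg
        # meG paired-left (from a right-pairing meC) or lone
        sc = v[4]
        arg = 4
        if enforce[j] == 0 and bestf > sc:
            sc = bestf
            arg = argf
        nv[7] = sc + e[5]
        bp[j0, 7] = arg
        for s in range(8):
            v[s] = nv[s]
    best = NEG
    args = 0
    for s in _FREE:
        if v[s] > best:
            best = v[s]
            args = s
    if want_path:
        s = args
        for j0 in range(L - 1, -1, -1):
            if s == 4 or s == 5:
                path[j0] = 4
            elif s == 6 or s == 7:
                path[j0] = 5
            else:
                path[j0] = s
            s = bp[j0, s]
    return best


_EMPTY = np.zeros((0, 6), dtype=np.float64)


def empty_block() -> np.ndarray:
    return _EMPTY
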