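"""Numba kernels for local (Smith-Waterman/Gotoh) nucleotide alignment.

Sequences are encoded as uint8 arrays (A=0, C=1, G=2, T=3, N/other=4,
masked=255).  A masked or ambiguous base never matches anything, including
itself.  Gap costs are affine: the first gap column in a run costs
``gap_open``, each further column ``gap_extend`` (both negative).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _LUT[_c] = _i
    _LUT[_c + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string for the kernels."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def sw_align(a, b, match, mismatch, gap_open, gap_extend, band):  # pragma: no cover - jit
    """Local alignment of encoded sequences ``a`` (query) and ``b`` (subject).

    Returns (score, a_start, a_end, b_start, b_end, matches, columns),
    end coordinates exclusive.  ``band`` < 0 disables banding; otherwise
    only cells with |i - j| <= band are filled (both sequences indexed
    from their starts, suitable for near-global homologues).
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)
    # pointers: 0 stop, 1 diag, 2 from E, 3 from F
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 if E extends E
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = 1
        jhi = m
        if band >= 0:
            jlo = i - band
            if jlo < 1:
                jlo = 1
            jhi = i + band
            if jhi > m:
                jhi = m
        for j in range(jlo, jhi + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if ee > eo:
                E[i, j] = ee
                PE[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fe > fo:
                F[i, j] = fe
                PF[i, j] = 1
            else:
                F[i, j] = fo
            ca = a[i - 1]
            cb = b[j - 1]
            if ca == cb and ca < 4:
                sub = match
            else:
                sub = mismatch
            d = H[i - 1, j - 1] + sub
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            P[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0 in H, 2 in E, 3 in F
    while i > 0 and j > 0:
        if state == 0:
            p = P[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            columns += 1
            if PE[i, j] == 0:
                state = 0
            j -= 1
        else:
            columns += 1
            if PF[i, j] == 0:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, columns
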