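"""Dynamic-programming kernels: banded affine local alignment and
profile-profile global alignment.

Both are written as plain-Python/numpy functions and JIT-compiled with
numba when it is importable; the fallback path has identical semantics,
so numba is an accelerator, never a correctness dependency.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_ENCODE_TABLE = np.full(256, 4, dtype=np.int8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to int8 codes (A=0..T=3, N=4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _banded_sw_impl(q, s, lo, hi, match, mismatch, gap_open, gap_extend):
    """Banded affine-gap Smith-Waterman restricted to j - i in [lo, hi].

    Returns an int64 vector
    [score, q_start, q_end, s_start, s_end, matches, mismatches, columns]
    for the best local alignment (all coordinates 0-based half-open).
    N never matches anything, including N.
    """
    m = q.shape[0]
    n = s.shape[0]
    w = hi - lo + 1
    NEG = -(10 ** 9)

    H = np.full((m + 1, w), NEG, dtype=np.int64)
    E = np.full((m + 1, w), NEG, dtype=np.int64)
    F = np.full((m + 1, w), NEG, dtype=np.int64)
    pH = np.zeros((m + 1, w), dtype=np.int8)   # 0 stop, 1 diag, 2 E, 3 F
    pE = np.zeros((m + 1, w), dtype=np.int8)   # 1 open, 2 extend
    pF = np.zeros((m + 1, w), dtype=np.int8)

    best = 0
    bi = 0
    bd = 0
    for i in range(m + 1):
        for d in range(w):
            j = i + lo + d
            if j < 0 or j > n:
                continue
            if i == 0 or j == 0:
                H[i, d] = 0
                continue
            qa = q[i - 1]
            sa = s[j - 1]
            if qa == sa and qa != 4:
                sub = match
            else:
                sub = mismatch
            # diagonal predecessor (i-1, j-1) sits at the same band column
            diag = H[i - 1, d] + sub if H[i - 1, d] > NEG else NEG
            # E: gap in query, predecessor (i, j-1) = band column d-1
            e = NEG
            if d - 1 >= 0:
                e_open = H[i, d - 1] + gap_open if H[i, d - 1] > NEG else NEG
                e_ext = E[i, d - 1] + gap_extend if E[i, d - 1] > NEG else NEG
                if e_open >= e_ext:
                    e = e_open
                    pE[i, d] = 1
                else:
                    e = e_ext
                    pE[i, d] = 2
            E[i, d] = e
            # F: gap in subject, predecessor (i-1, j) = band column d+1
            f = NEG
            if d + 1 < w:
                f_open = H[i - 1, d + 1] + gap_open if H[i - 1, d + 1] > NEG else NEG
                f_ext = F[i - 1, d + 1] + gap_extend if F[i - 1, d + 1] > NEG else NEG
                if f_open >= f_ext:
                    f = f_open
                    pF[i, d] = 1
                else:
                    f = f_ext
                    pF[i, d] = 2
            F[i, d] = f

            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, d] = h
            pH[i, d] = p
            if h > best:
                best = h
                bi = i
                bd = d

    out = np.zeros(8, dtype=np.int64)
    if best <= 0:
        return out

    # traceback
    i = bi
    d = bd
    qe = bi
    je = bi + lo + bd
    matches = 0
    mismatches = 0
    cols = 0
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = pH[i, d]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if q[i - 1] == s[i + lo + d - 1] and q[i - 1] != 4:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            cols += 1
            p = pE[i, d]
            d -= 1
            if p == 1:
                state = 0
        else:
            cols += 1
            p = pF[i, d]
            i -= 1
            d += 1
            if p == 1:
                state = 0

    out[0] = best
    out[1] = i
    out[2] = qe
    out[3] = i + lo + d
    out[4] = je
    out[5] = matches
    out[6] = mismatches
    out[7] = cols
    return out


def _nw_profile_impl(S, gap_a, gap_b):
    """Global alignment over a precomputed column-pair score matrix.

    S[i, j] scores aligning column i of profile A with column j of B;
    gap_a[i] / gap_b[j] score aligning a column against an all-gap column.
    Returns (n_ops, ops) where ops holds, 3'-to-5', 0=diag, 1=up (consume
    A), 2=left (consume B).
    """
    la = S.shape[0]
    lb = S.shape[1]
    D = np.zeros((la + 1, lb + 1), dtype=np.float64)
    P = np.zeros((la + 1, lb + 1), dtype=np.int8)
    for i in range(1, la + 1):
        D[i, 0] = D[i - 1, 0] + gap_a[i - 1]
        P[i, 0] = 1
    for j in range(1, lb + 1):
        D[0, j] = D[0, j - 1] + gap_b[j - 1]
        P[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = D[i - 1, j - 1] + S[i - 1, j - 1]
            up = D[i - 1, j] + gap_a[i - 1]
            left = D[i, j - 1] + gap_b[j - 1]
            best = diag
            p = 0
            if up > best:
                best = up
                p = 1
            if left > best:
                best = left
                p = 2
            D[i, j] = best
            P[i, j] = p

    ops = np.zeros(la + lb, dtype=np.int8)
    k = 0
    i = la
    j = lb
    while i > 0 or j > 0:
        p = P[i, j]
        ops[k] = p
        k += 1
        if p == 0:
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return k, ops


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    banded_sw = njit(cache=False)(_banded_sw_impl)
    nw_profile = njit(cache=False)(_nw_profile_impl)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    banded_sw = _banded_sw_impl
    nw_profile = _nw_profile_impl
    HAVE_NUMBA = False
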