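"""Pairwise global alignment helpers.

``needleman_wunsch_affine`` is the package's own Gotoh implementation with
the fixed scoring used for core-block MSAs (match 1, mismatch -1, gap open
-4, gap extend -1).  ``edlib_identity`` wraps python-edlib for fast
edit-distance identity of short sequences (junction signatures, LTR pairs).
"""

from __future__ import annotations

import numpy as np

try:
    import edlib
except ImportError:          # pragma: no cover
    edlib = None

from ._seq import as_array, decode
from .errors import InputError

_MAX_CELLS = 30_000_000


def needleman_wunsch_affine(a, b, match: int = 1, mismatch: int = -1,
                            gap_open: int = -4, gap_extend: int = -1):
    """Global affine-gap alignment; returns (aligned_a, aligned_b) strings
    with '-' gaps.  Gap open cost applies to the first gap column."""
    a = as_array(a)
    b = as_array(b)
    if a.size == 0 or b.size == 0:
        raise InputError("alignment requires nonempty sequences")
    n, m = a.size, b.size
    if (n + 1) * (m + 1) > _MAX_CELLS:
        raise InputError(f"alignment too large ({n}x{m})")
    NEG = -10 ** 9
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)   # match/mismatch state
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)   # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)   # gap in a (consume b)
    # traceback: bit 0/1 of tb[s] stores predecessor state per cell
    tbM = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbX = np.zeros((n + 1, m + 1), dtype=np.int8)
    tbY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    X[1:, 0] = gap_open + gap_extend * np.arange(n)
    Y[0, 1:] = gap_open + gap_extend * np.arange(m)
    tbX[2:, 0] = 1
    tbY[0, 2:] = 2
    sub_row = np.empty(m, dtype=np.int32)
    for i in range(1, n + 1):
        sub_row[:] = np.where(b == a[i - 1], match, mismatch)
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        # X: gap in b, vertical move
        openx = np.maximum(prevM, prevY) + gap_open + gap_extend
        extx = prevX + gap_extend
        X[i] = np.maximum(openx, extx)
        tbX[i] = np.where(extx >= openx, 1,
                          np.where(prevM >= prevY, 0, 2))
        # M and Y need a left-to-right scan (Y depends on current row)
        Mi, Yi = M[i], Y[i]
        tMi, tYi = tbM[i], tbY[i]
        diagM, diagX, diagY = prevM[:-1], prevX[:-1], prevY[:-1]
        best_diag = np.maximum(np.maximum(diagM, diagX), diagY)
        src = np.where(diagM >= np.maximum(diagX, diagY), 0,
                       np.where(diagX >= diagY, 1, 2))
        cand = best_diag + sub_row
        for j in range(1, m + 1):
            Mi[j] = cand[j - 1]
            tMi[j] = src[j - 1]
            open_y = max(Mi[j - 1], X[i, j - 1]) + gap_open + gap_extend
            ext_y = Yi[j - 1] + gap_extend
            if ext_y >= open_y:
                Yi[j] = ext_y
                tYi[j] = 2
            else:
                Yi[j] = open_y
                tYi[j] = 0 if Mi[j - 1] >= X[i, j - 1] else 1
    # traceback
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    out_a, out_b = [], []
    while i > 0 or j > 0:
        if state == 0:
            prev = tbM[i, j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            prev = tbX[i, j]
            out_a.append(a[i - 1])
            out_b.append(4)
            i -= 1
        else:
            prev = tbY[i, j]
            out_a.append(4)
            out_b.append(b[j - 1])
            j -= 1
        state = int(prev)
    gap = ord("-")
    conv = np.array([65, 67, 71, 84, gap], dtype=np.uint8)
    sa = conv[np.array(out_a[::-1], dtype=np.uint8)].tobytes().decode()
    sb = conv[np.array(out_b[::-1], dtype=np.uint8)].tobytes().decode()
    return sa, sb


def edlib_global(a, b, max_dist: int = -1):
    """Global (NW) edit-distance alignment via edlib.

    Returns (distance, aligned_columns, substitutions) using the extended
    cigar; distance -1 means the ``max_dist`` cutoff was exceeded.
    """
    if edlib is None:                    # pragma: no cover
        raise InputError("edlib is not available")
    if isinstance(a, np.ndarray):
        a = decode(a)
    if isinstance(b, np.ndarray):
        b = decode(b)
    res = edlib.align(a, b, mode="NW", task="path", k=max_dist)
    if res["editDistance"] < 0:
        return -1, 0, 0
    cols = subs = 0
    import re
    for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"] or ""):
        num = int(num)
        cols += num
        if op == "X":
            subs += num
    return res["editDistance"], cols, subs
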