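"""Global (Needleman-Wunsch) alignment kernel.

Linear gap penalty, full traceback, deterministic tie-breaking: on equal
scores the diagonal move is preferred, then the vertical (gap in the second
sequence), then the horizontal. Implemented with numba for speed; the pointer
matrix is uint8 so pairs of ~15 kbp stay within a few hundred MB.
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np
from numba import njit

GAP_BYTE = 45  # ord('-')


@njit(cache=True)
def _nw_kernel(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    ptr = np.empty((n + 1, m + 1), np.uint8)
    prev = np.empty(m + 1, np.int64)
    cur = np.empty(m + 1, np.int64)
    ptr[0, 0] = 0
    prev[0] = 0
    for j in range(1, m + 1):
        prev[j] = gap * j
        ptr[0, j] = 2
    for i in range(1, n + 1):
        cur[0] = gap * i
        ptr[i, 0] = 1
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            d = prev[j - 1] + s
            u = prev[j] + gap
            left = cur[j - 1] + gap
            if d >= u and d >= left:
                cur[j] = d
                ptr[i, j] = 0
            elif u >= left:
                cur[j] = u
                ptr[i, j] = 1
            else:
                cur[j] = left
                ptr[i, j] = 2
        tmp = prev
        prev = cur
        cur = tmp
    score = prev[m]
    out1 = np.empty(n + m, np.uint8)
    out2 = np.empty(n + m, np.uint8)
    i = n
    j = m
    p = n + m
    while i > 0 or j > 0:
        p -= 1
        t = ptr[i, j]
        if t == 0:
            out1[p] = a[i - 1]
            out2[p] = b[j - 1]
            i -= 1
            j -= 1
        elif t == 1:
            out1[p] = a[i - 1]
            out2[p] = GAP_BYTE
            i -= 1
        else:
            out1[p] = GAP_BYTE
            out2[p] = b[j - 1]
            j -= 1
    return score, out1[p:], out2[p:]


def _as_bytes(seq: Union[str, bytes, np.ndarray]) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return np.frombuffer(seq, dtype=np.uint8).copy()


def needleman_wunsch(
    seq1: Union[str, bytes, np.ndarray],
    seq2: Union[str, bytes, np.ndarray],
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Tuple[int, np.ndarray, np.ndarray]:
    """Align two sequences globally.

    Returns ``(score, aln1, aln2)`` where the alignments are uint8 arrays of
    equal length with ``GAP_BYTE`` marking gap columns.
    """
    a = _as_bytes(seq1)
    b = _as_bytes(seq2)
    score, o1, o2 = _nw_kernel(a, b, match, mismatch, gap)
    return int(score), o1, o2
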