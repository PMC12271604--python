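"""Minimizer-anchored alignment for very long, highly similar sequence pairs.

Direct global alignment of two >10 kbp sequences is quadratic in both time
and memory. For such pairs — typically two representations of one large
insertion — the sequences are sketched with window minimizers (default
k = 15, w = 10), hash-matched minimizers are chained colinearly, and only the
short segments between consecutive anchors are aligned. Anchor spans count as
exact matches; the concatenated alignment is scored with the same
relief-factor formula as the direct path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from numba import njit

from ._nw import GAP_BYTE, needleman_wunsch
from .config import MatchConfig
from .match_criteria import alignment_stats, relief_score

#: direct-alignment fallback is allowed up to this many DP cells
_NW_FALLBACK_CELL_CAP = 250_000_000

_BASE_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i


@dataclass(frozen=True)
class MinimizerSketch:
    """Ordered (hash, offset) pairs of the window-minimal k-mers."""

    hashes: np.ndarray  # uint64
    offsets: np.ndarray  # int64, strictly increasing
    k: int
    w: int

    def __len__(self) -> int:
        return int(self.hashes.shape[0])


@dataclass(frozen=True)
class AnchoredResult:
    score: float
    no_anchor: bool = False
    fallback_nw: bool = False
    n_anchors: int = 0


@njit(cache=True)
def _mix64(x):  # pragma: no cover - numba
    # splitmix64 finaliser: invertible integer mix, fixed seed 0
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return x ^ (x >> np.uint64(31))


@njit(cache=True)
def _sketch_kernel(codes, k, w):  # pragma: no cover - numba
    n = codes.shape[0]
    nk = n - k + 1
    if nk <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    hashes = np.empty(nk, np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1) if 2 * k < 64 else np.uint64(0xFFFFFFFFFFFFFFFF)
    kmer = np.uint64(0)
    for i in range(k):
        kmer = ((kmer << np.uint64(2)) | np.uint64(codes[i])) & mask
    hashes[0] = _mix64(kmer)
    for i in range(1, nk):
        kmer = ((kmer << np.uint64(2)) | np.uint64(codes[i + k - 1])) & mask
        hashes[i] = _mix64(kmer)
    n_windows = nk - w + 1
    if n_windows < 1:
        n_windows = 1
        w_eff = nk
    else:
        w_eff = w
    out_h = np.empty(n_windows, np.uint64)
    out_o = np.empty(n_windows, np.int64)
    count = 0
    last = -1
    for s in range(n_windows):
        best = s
        for j in range(s + 1, s + w_eff):
            if hashes[j] < hashes[best]:
                best = j
        if best != last:
            out_h[count] = hashes[best]
            out_o[count] = best
            count += 1
            last = best
    return out_h[:count], out_o[:count]


def minimizer_sketch(seq: str, k: int, w: int) -> MinimizerSketch:
    """Sketch a sequence: in every window of ``w`` consecutive k-mers keep the
    k-mer of minimal hash (leftmost on ties); consecutive duplicates are
    deduplicated. Sequences shorter than ``k`` yield an empty sketch."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    hashes, offsets = _sketch_kernel(codes, k, w)
    return MinimizerSketch(hashes=hashes, offsets=offsets, k=k, w=w)


def _unique_hash_map(sketch: MinimizerSketch) -> dict:
    """hash -> offset for hashes occurring exactly once in the sketch;
    repeated hashes (repeats in the sequence) are unreliable anchors."""
    counts: dict = {}
    for h in sketch.hashes:
        counts[int(h)] = counts.get(int(h), 0) + 1
    return {
        int(h): int(o)
        for h, o in zip(sketch.hashes, sketch.offsets)
        if counts[int(h)] == 1
    }


def _longest_increasing_chain(pairs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates; ``pairs`` must
    be sorted by the first coordinate. Ties prefer the smaller second
    coordinate (patience sorting on posB)."""
    import bisect

    tails: List[int] = []
    tails_idx: List[int] = []
    parent = [-1] * len(pairs)
    for i, (_, pb) in enumerate(pairs):
        j = bisect.bisect_left(tails, pb)
        if j == len(tails):
            tails.append(pb)
            tails_idx.append(i)
        elif pb < tails[j]:
            tails[j] = pb
            tails_idx[j] = i
        else:
            continue
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    if not tails_idx:
        return []
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(pairs[i])
        i = parent[i]
    chain.reverse()
    return chain


def _chain_anchors(s1: str, s2: str, config: MatchConfig) -> List[Tuple[int, int]]:
    k, w = config.kmer_k, config.minimizer_w
    sk1 = minimizer_sketch(s1, k, w)
    sk2 = minimizer_sketch(s2, k, w)
    if len(sk1) == 0 or len(sk2) == 0:
        return []
    map2 = _unique_hash_map(sk2)
    counts1: dict = {}
    for h in sk1.hashes:
        counts1[int(h)] = counts1.get(int(h), 0) + 1
    pairs = [
        (int(o), map2[int(h)])
        for h, o in zip(sk1.hashes, sk1.offsets)
        if counts1[int(h)] == 1 and int(h) in map2
    ]
    pairs.sort()
    chain = _longest_increasing_chain(pairs)
    # trim overlapping anchor spans so each contributes k disjoint columns
    trimmed: List[Tuple[int, int]] = []
    k_ = config.kmer_k
    for pa, pb in chain:
        if not trimmed or (pa >= trimmed[-1][0] + k_ and pb >= trimmed[-1][1] + k_):
            trimmed.append((pa, pb))
    return trimmed


def anchored_similarity(s1: str, s2: str, config: MatchConfig) -> AnchoredResult:
    """Relief-factor similarity of two long sequences via anchor chaining.

    When no colinear anchors are found the pair falls back to direct global
    alignment if its size permits, else the score is 0 with ``no_anchor``
    set.
    """
    anchors = _chain_anchors(s1, s2, config)
    # a chain of one anchor in sequences this long is almost surely a chance
    # k-mer hit (e.g. a palindrome); genuinely similar pairs yield dense chains
    if len(anchors) < 2:
        if len(s1) * len(s2) <= _NW_FALLBACK_CELL_CAP:
            from .match_criteria import aligned_pair_score

            return AnchoredResult(
                score=aligned_pair_score(s1, s2, config), no_anchor=True, fallback_nw=True
            )
        return AnchoredResult(score=0.0, no_anchor=True, fallback_nw=False)
    k = config.kmer_k
    pieces1: List[np.ndarray] = []
    pieces2: List[np.ndarray] = []
    prev1 = prev2 = 0
    for pa, pb in anchors:
        _align_segment(s1[prev1:pa], s2[prev2:pb], config, pieces1, pieces2)
        anchor_bytes = np.frombuffer(s1[pa : pa + k].encode("ascii"), dtype=np.uint8)
        pieces1.append(anchor_bytes)
        pieces2.append(anchor_bytes)
        prev1, prev2 = pa + k, pb + k
    _align_segment(s1[prev1:], s2[prev2:], config, pieces1, pieces2)
    aln1 = np.concatenate(pieces1) if pieces1 else np.empty(0, np.uint8)
    aln2 = np.concatenate(pieces2) if pieces2 else np.empty(0, np.uint8)
    stats = alignment_stats(aln1, aln2, config.gap_run_min)
    return AnchoredResult(
        score=relief_score(stats, config.relief_factor),
        n_anchors=len(anchors),
    )


def _align_segment(
    seg1: str, seg2: str, config: MatchConfig, out1: List[np.ndarray], out2: List[np.ndarray]
) -> None:
    if not seg1 and not seg2:
        return
    if not seg1:
        b = np.frombuffer(seg2.encode("ascii"), dtype=np.uint8)
        out1.append(np.full(len(seg2), GAP_BYTE, np.uint8))
        out2.append(b)
        return
    if not seg2:
        a = np.frombuffer(seg1.encode("ascii"), dtype=np.uint8)
        out1.append(a)
        out2.append(np.full(len(seg1), GAP_BYTE, np.uint8))
        return
    _, a1, a2 = needleman_wunsch(
        seg1, seg2, match=config.nw_match, mismatch=config.nw_mismatch, gap=config.nw_gap
    )
    out1.append(a1)
    out2.append(a2)
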