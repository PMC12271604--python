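"""The five pairwise matching criteria.

Two SVs are considered the same event when they agree on (1) type, (2)
breakpoint distance, (3) span overlap after length-dependent extension,
(4) size similarity and (5) sequence similarity. The sequence criterion uses
a relief-factor score over a global alignment: gap characters that belong to
long gap runs — the typical footprint of two representations of one event —
are partially credited instead of fully penalised:

    score = (M + G * RF) / alignment_length

with M the matched columns, G the gap characters in runs of at least
``gap_run_min`` columns, and RF the relief factor in [0, 1]. The score is
evaluated both on the raw variant sequences and on shared-context haplotypes
built from the reference around the two variants; the maximum of the two is
reported, which absorbs placement shifts and incidental SNVs near the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._nw import GAP_BYTE, needleman_wunsch
from .config import MatchConfig
from .sv_io import Reference, SVRecord


@dataclass(frozen=True)
class AlignmentStats:
    """Column statistics of one pairwise alignment."""

    matches: int  # matching base columns (M)
    relieved_gaps: int  # gap characters in runs of length >= gap_run_min (G)
    aln_len: int


@dataclass(frozen=True)
class MatchEvaluation:
    """Outcome of the five criteria for one (query, benchmark) pair.

    ``seq_sim`` is ``None`` when either allele is symbolic; the sequence
    criterion then passes vacuously provided the other four hold.
    """

    type_ok: bool
    distance_ok: bool
    overlap_ok: bool
    size_sim: float
    size_ok: bool
    seq_sim: Optional[float]
    seq_ok: bool
    all_pass: bool


def extend_length(length: int) -> int:
    """Breakpoint extension for spanned variants: 200 bp for SVs up to
    100 bp, 1 kbp above."""
    if length <= 0:
        raise ValueError("length must be positive")
    return 200 if length <= 100 else 1000


def type_compatible(t1: str, t2: str, mode: str = "strict") -> bool:
    """Type criterion. ``loose`` additionally accepts INS/DUP pairs, since
    duplications are frequently reported as insertions."""
    if t1 == t2:
        return True
    return mode == "loose" and {t1, t2} == {"INS", "DUP"}


def _extended_interval(rec: SVRecord, config: MatchConfig) -> Tuple[int, int]:
    if rec.svtype == "INS":
        ext = config.fixed_ins_overlap_ext
    else:
        ext = extend_length(rec.length)
    return rec.pos - ext, rec.end + ext


def overlap_status(a: SVRecord, b: SVRecord, config: MatchConfig) -> bool:
    """Overlap criterion on length-extended spans; insertions, which have no
    physical span, get a fixed 100 bp extension instead."""
    if a.chrom != b.chrom:
        return False
    s1, e1 = _extended_interval(a, config)
    s2, e2 = _extended_interval(b, config)
    return max(s1, s2) <= min(e1, e2)


def size_similarity(a: SVRecord, b: SVRecord) -> float:
    """min(L1, L2) / max(L1, L2); 1.0 iff the lengths agree."""
    l1, l2 = a.length, b.length
    return min(l1, l2) / max(l1, l2)


# ---------------------------------------------------------------------------
# relief-factor alignment scoring


def alignment_stats(aln1: np.ndarray, aln2: np.ndarray, gap_run_min: int) -> AlignmentStats:
    """M / G / length statistics of an alignment given as two equal-length
    uint8 arrays with GAP_BYTE in gap columns. Gap runs are maximal stretches
    of consecutive gap columns within each sequence, counted per sequence."""
    if aln1.shape != aln2.shape:
        raise ValueError("aligned sequences must have equal length")
    n = int(aln1.shape[0])
    if n == 0:
        return AlignmentStats(0, 0, 0)
    g1 = aln1 == GAP_BYTE
    g2 = aln2 == GAP_BYTE
    matches = int(np.count_nonzero((aln1 == aln2) & ~g1))
    relieved = _relieved_gap_count(g1, gap_run_min) + _relieved_gap_count(g2, gap_run_min)
    return AlignmentStats(matches, relieved, n)


def _relieved_gap_count(is_gap: np.ndarray, gap_run_min: int) -> int:
    if not is_gap.any():
        return 0
    padded = np.concatenate(([False], is_gap, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[0::2]
    return int(run_lengths[run_lengths >= gap_run_min].sum())


def relief_score(stats: AlignmentStats, relief_factor: float) -> float:
    if stats.aln_len == 0:
        return 1.0
    score = (stats.matches + stats.relieved_gaps * relief_factor) / stats.aln_len
    return float(min(1.0, max(0.0, score)))


def aligned_pair_score(seq1: str, seq2: str, config: MatchConfig) -> float:
    """Relief-factor similarity of two sequences under direct global
    alignment."""
    if not seq1 and not seq2:
        return 1.0
    _, a1, a2 = needleman_wunsch(
        seq1, seq2, match=config.nw_match, mismatch=config.nw_mismatch, gap=config.nw_gap
    )
    return relief_score(alignment_stats(a1, a2, config.gap_run_min), config.relief_factor)


def _pair_score(seq1: str, seq2: str, config: MatchConfig) -> float:
    """Direct alignment score; very long pairs go through the anchored path."""
    if min(len(seq1), len(seq2)) > config.large_sv_threshold:
        from . import large_sv  # local import: large_sv uses this module's scoring

        return large_sv.anchored_similarity(seq1, seq2, config).score
    return aligned_pair_score(seq1, seq2, config)


# ---------------------------------------------------------------------------
# sequence similarity with shared context


def _shared_context(a: SVRecord, b: SVRecord, ref: Reference) -> Optional[Tuple[str, str]]:
    """Build the two shared-context sequences: the reference window from the
    upstream-most start to the downstream-most end with each variant's own
    sequence embedded at its position."""
    if a.chrom != b.chrom or a.chrom not in ref:
        return None
    start = min(a.pos, b.pos)
    if a.svtype in ("DUP", "INV") or b.svtype in ("DUP", "INV"):
        stop = max(a.end, b.end)
    else:
        stop = max(a.ref_footprint_end, b.ref_footprint_end)
    out = []
    for rec in (a, b):
        embedded = rec.variant_sequence()
        prefix = ref.fetch(rec.chrom, start, rec.pos - 1)
        suffix = ref.fetch(rec.chrom, rec.ref_footprint_end + 1, stop)
        out.append(prefix + embedded + suffix)
    return out[0], out[1]


def sequence_similarity(
    a: SVRecord,
    b: SVRecord,
    ref: Optional[Reference],
    config: MatchConfig,
) -> Optional[float]:
    """Relief-factor sequence similarity in [0, 1], or ``None`` when either
    allele is symbolic (no resolved sequence to compare).

    The reported value is the maximum of the raw variant-sequence score and
    the shared-context score; when the reference window is unavailable only
    the raw score is used.
    """
    if a.symbolic or b.symbolic:
        return None
    v1, v2 = a.variant_sequence(), b.variant_sequence()
    if not v1 or not v2:
        return None
    score = _pair_score(v1, v2, config)
    if ref is not None:
        ctx = _shared_context(a, b, ref)
        if ctx is not None:
            score = max(score, _pair_score(ctx[0], ctx[1], config))
    return float(min(1.0, max(0.0, score)))


def evaluate_pair(
    a: SVRecord,
    b: SVRecord,
    ref: Optional[Reference],
    config: MatchConfig,
    skip_seq_if_failed: bool = True,
) -> MatchEvaluation:
    """Evaluate all five criteria for a (query, benchmark) pair.

    The distance criterion requires the start positions to lie within the
    length-dependent extension of the larger variant. The expensive sequence
    alignment is skipped when a cheaper criterion already failed (the
    returned seq_sim is then ``None`` and ``all_pass`` is False).
    """
    type_ok = type_compatible(a.svtype, b.svtype, config.match_mode)
    same_chrom = a.chrom == b.chrom
    distance_ok = same_chrom and abs(a.pos - b.pos) <= extend_length(max(a.length, b.length))
    overlap_ok = overlap_status(a, b, config)
    size_sim = size_similarity(a, b)
    size_ok = size_sim >= config.size_sim_threshold
    cheap_pass = type_ok and distance_ok and overlap_ok and size_ok
    seq_sim: Optional[float] = None
    if a.symbolic or b.symbolic:
        seq_ok = True  # criterion vacuous without resolved sequences
    elif cheap_pass or not skip_seq_if_failed:
        seq_sim = sequence_similarity(a, b, ref, config)
        seq_ok = seq_sim is None or seq_sim >= config.seq_sim_threshold
    else:
        seq_ok = False
    return MatchEvaluation(
        type_ok=type_ok,
        distance_ok=distance_ok,
        overlap_ok=overlap_ok,
        size_sim=size_sim,
        size_ok=size_ok,
        seq_sim=seq_sim,
        seq_ok=seq_ok,
        all_pass=cheap_pass and seq_ok,
    )
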