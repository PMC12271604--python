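"""First-pass classification: indexed candidate search and allele-aware
best-match selection.

The benchmark set is indexed per chromosome by sorted position. Each query is
compared against candidates in a narrow window (scaled to 1e-5 of the
chromosome length, clamped to [200, 1000] bp); queries of at least 100 bp
whose initial window is empty retry in a 1 kbp window with type and
size-ratio pre-filters, absorbing placement differences between aligners.
Among all candidates passing the five criteria the one with the highest
sequence similarity wins (size similarity for symbolic pairs), so two calls
can legitimately match the two allelic benchmark records at one site. Each
benchmark record is consumed by at most one query and vice versa; queries are
processed in genomic order, which makes the outcome deterministic and
independent of the thread count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .config import MatchConfig
from .match_criteria import MatchEvaluation, evaluate_pair, type_compatible
from .sv_io import Reference, SVRecord, chrom_sort_key, record_sort_key

#: search-window fraction of the chromosome length
_WINDOW_CHROM_FRACTION = 1e-5


class BenchmarkIndex:
    """Per-chromosome position-sorted arrays of benchmark records."""

    def __init__(self, records: Sequence[SVRecord], reference: Optional[Reference] = None):
        by_chrom: Dict[str, List[SVRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._records: Dict[str, List[SVRecord]] = {}
        self._positions: Dict[str, np.ndarray] = {}
        self.chrom_lengths: Dict[str, int] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=record_sort_key)
            self._records[chrom] = recs
            self._positions[chrom] = np.array([r.pos for r in recs], dtype=np.int64)
            inferred = max(max(r.end, r.ref_footprint_end) for r in recs)
            if reference is not None and chrom in reference:
                inferred = reference.chrom_length(chrom)
            self.chrom_lengths[chrom] = inferred
        self.n_records = len(records)

    def chroms(self) -> List[str]:
        return sorted(self._records, key=chrom_sort_key)

    def records(self, chrom: str) -> List[SVRecord]:
        return self._records.get(chrom, [])

    def window(self, chrom: str, lo: int, hi: int) -> List[SVRecord]:
        """Benchmark records with pos in [lo, hi]."""
        if chrom not in self._records:
            return []
        pos = self._positions[chrom]
        i = int(np.searchsorted(pos, lo, side="left"))
        j = int(np.searchsorted(pos, hi, side="right"))
        return self._records[chrom][i:j]


@dataclass(frozen=True)
class MatchResult:
    """An accepted query/benchmark match with its deviation metrics.

    ``d`` is the signed start-position difference (query minus benchmark) and
    ``r`` the span ratio (query span over benchmark span). Matches produced
    by joint merge validation set ``via_merge`` and carry the merged members
    and the merged representation's length.
    """

    query: SVRecord
    benchmark: SVRecord
    evaluation: Optional[MatchEvaluation]
    d: int
    r: float
    seq_sim: Optional[float]
    via_merge: bool = False
    merge_members: Tuple[SVRecord, ...] = ()
    merged_length: Optional[int] = None


@dataclass
class Classification:
    """Full TP/FP/FN/LP assignment of one callset against one benchmark.

    ``tp_benchmark`` and ``fn_benchmark`` partition the filtered benchmark
    set; matched calls, ``fp_calls`` and ``lp_calls`` partition the filtered
    callset.
    """

    source: str
    tp_benchmark: List[SVRecord] = field(default_factory=list)
    tp_matches: List[MatchResult] = field(default_factory=list)
    fp_calls: List[SVRecord] = field(default_factory=list)
    fn_benchmark: List[SVRecord] = field(default_factory=list)
    lp_calls: List[SVRecord] = field(default_factory=list)
    call_exclusions: Counter = field(default_factory=Counter)
    benchmark_exclusions: Counter = field(default_factory=Counter)
    n_benchmark: int = 0
    n_calls: int = 0
    benchmark_fingerprint: Tuple = ()
    # best sequence similarity seen per unmatched call, used to break ties in
    # the supercluster allele filter
    best_seq_sim: Dict[Tuple, float] = field(default_factory=dict)

    def check_invariants(self) -> None:
        assert len(self.tp_benchmark) + len(self.fn_benchmark) == self.n_benchmark
        n_matched_calls = sum(1 for m in self.tp_matches if not m.via_merge)
        assert n_matched_calls + len(self.fp_calls) + len(self.lp_calls) == self.n_calls
        keys = [r.key for r in self.tp_benchmark + self.fn_benchmark]
        assert len(set(keys)) == len(keys)


def candidate_search(
    query: SVRecord,
    index: BenchmarkIndex,
    config: MatchConfig,
    exclude: Optional[Set[Tuple]] = None,
) -> List[SVRecord]:
    """Two-stage targeted search for benchmark candidates near a query.

    Stage 1 scans |pos - query.pos| <= w0 with w0 = clamp(chrom_len * 1e-5,
    small_window, expanded_window). For queries >= 100 bp with an empty stage
    1, stage 2 widens to the expanded window and pre-filters candidates by
    type compatibility and a query/candidate length ratio inside the
    configured band.
    """
    if query.chrom not in index.chrom_lengths:
        return []
    chrom_len = index.chrom_lengths[query.chrom]
    w0 = int(chrom_len * _WINDOW_CHROM_FRACTION)
    w0 = max(config.small_window, min(config.expanded_window, w0))
    cands = index.window(query.chrom, query.pos - w0, query.pos + w0)
    if exclude:
        cands = [c for c in cands if c.key not in exclude]
    if cands or query.length < 100:
        return cands
    lo, hi = config.size_ratio_band
    wide = index.window(
        query.chrom, query.pos - config.expanded_window, query.pos + config.expanded_window
    )
    out = []
    for c in wide:
        if exclude and c.key in exclude:
            continue
        if not type_compatible(query.svtype, c.svtype, config.match_mode):
            continue
        ratio = query.length / c.length
        if lo <= ratio <= hi:
            out.append(c)
    return out


def match_one(
    query: SVRecord,
    candidates: Sequence[SVRecord],
    ref: Optional[Reference],
    config: MatchConfig,
) -> Tuple[Optional[MatchResult], float]:
    """Pick the best-matching candidate for one query.

    Returns ``(match, best_seq_sim_seen)``; the match is ``None`` when no
    candidate passes all five criteria. Ranking among passing candidates:
    highest sequence similarity (size similarity when the pair is symbolic),
    then smallest |d|, then smallest benchmark position.
    """
    best: Optional[Tuple[Tuple, MatchResult]] = None
    best_seen = -1.0
    for cand in candidates:
        ev = evaluate_pair(query, cand, ref, config)
        if ev.seq_sim is not None and ev.seq_sim > best_seen:
            best_seen = ev.seq_sim
        if not ev.all_pass:
            continue
        d = query.pos - cand.pos
        r = query.span / cand.span
        primary = ev.seq_sim if ev.seq_sim is not None else ev.size_sim
        rank = (-primary, abs(d), cand.pos, cand.record_id)
        result = MatchResult(
            query=query, benchmark=cand, evaluation=ev, d=d, r=r, seq_sim=ev.seq_sim
        )
        if best is None or rank < best[0]:
            best = (rank, result)
    return (best[1] if best else None), best_seen


def match_callset(
    callset: Sequence[SVRecord],
    benchmark: Sequence[SVRecord],
    ref: Optional[Reference],
    config: MatchConfig,
    source: str = "",
    call_exclusions: Optional[Counter] = None,
    benchmark_exclusions: Optional[Counter] = None,
) -> Classification:
    """First-pass classification of a callset against a benchmark set."""
    index = BenchmarkIndex(benchmark, reference=ref)
    queries = sorted(callset, key=record_sort_key)
    consumed: Set[Tuple] = set()
    cls = Classification(
        source=source or (queries[0].source if queries else ""),
        n_benchmark=len(benchmark),
        n_calls=len(callset),
        call_exclusions=call_exclusions or Counter(),
        benchmark_exclusions=benchmark_exclusions or Counter(),
        benchmark_fingerprint=tuple(sorted(r.key for r in benchmark)),
    )
    matched_bench: Dict[Tuple, MatchResult] = {}
    for q in queries:
        cands = candidate_search(q, index, config, exclude=consumed)
        res, best_seen = match_one(q, cands, ref, config)
        if res is None:
            cls.fp_calls.append(q)
            cls.best_seq_sim[q.key] = best_seen
        else:
            consumed.add(res.benchmark.key)
            matched_bench[res.benchmark.key] = res
            cls.tp_matches.append(res)
    for b in sorted(benchmark, key=record_sort_key):
        if b.key in consumed:
            cls.tp_benchmark.append(b)
        else:
            cls.fn_benchmark.append(b)
    cls.check_invariants()
    return cls
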