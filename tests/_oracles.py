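"""Independent test oracles: a pure-Python global-alignment DP, an
alignment-statistics recount, and a brute-force (index-free) classifier.

These deliberately re-derive results from first principles so they can catch
defects in the accelerated implementations they are compared against.
"""

from __future__ import annotations

import re
from typing import List, Optional, Tuple

import numpy as np

from svjoint.config import MatchConfig
from svjoint.match_criteria import evaluate_pair, type_compatible
from svjoint.sv_io import Reference, SVRecord, record_sort_key, recompute_end


def nw_oracle(
    s1: str, s2: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> Tuple[int, str, str]:
    """Textbook O(n*m) global alignment with the same tie-breaking order as
    the production kernel (diagonal, then vertical, then horizontal)."""
    n, m = len(s1), len(s2)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    ptr = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        score[0][j] = gap * j
        ptr[0][j] = 2
    for i in range(1, n + 1):
        score[i][0] = gap * i
        ptr[i][0] = 1
        for j in range(1, m + 1):
            s = match if s1[i - 1] == s2[j - 1] else mismatch
            options = (
                (score[i - 1][j - 1] + s, 0),
                (score[i - 1][j] + gap, 1),
                (score[i][j - 1] + gap, 2),
            )
            best = max(options, key=lambda t: (t[0], -t[1]))
            score[i][j], ptr[i][j] = best
    a1, a2 = [], []
    i, j = n, m
    while i > 0 or j > 0:
        t = ptr[i][j]
        if t == 0:
            a1.append(s1[i - 1])
            a2.append(s2[j - 1])
            i, j = i - 1, j - 1
        elif t == 1:
            a1.append(s1[i - 1])
            a2.append("-")
            i -= 1
        else:
            a1.append("-")
            a2.append(s2[j - 1])
            j -= 1
    return score[n][m], "".join(reversed(a1)), "".join(reversed(a2))


def relief_score_oracle(aln1: str, aln2: str, rf: float, gap_run_min: int = 3) -> float:
    """Recount M and G with regexes and apply (M + G*RF) / L."""
    assert len(aln1) == len(aln2)
    if not aln1:
        return 1.0
    matches = sum(1 for x, y in zip(aln1, aln2) if x == y and x != "-")
    g = 0
    for s in (aln1, aln2):
        for run in re.finditer(r"-+", s):
            if len(run.group()) >= gap_run_min:
                g += len(run.group())
    return min(1.0, max(0.0, (matches + g * rf) / len(aln1)))


def pair_score_oracle(s1: str, s2: str, config: MatchConfig) -> float:
    _, a1, a2 = nw_oracle(s1, s2, config.nw_match, config.nw_mismatch, config.nw_gap)
    return relief_score_oracle(a1, a2, config.relief_factor, config.gap_run_min)


# ---------------------------------------------------------------------------
# brute-force classifier (no index, no binary search)


def brute_force_classify(
    calls: List[SVRecord],
    benchmark: List[SVRecord],
    ref: Optional[Reference],
    config: MatchConfig,
) -> dict:
    """Greedy matching in query order over linear scans of the benchmark,
    mirroring the staged search-space rules; returns id-sets per class."""
    consumed = set()
    matched_pairs = {}
    fp = set()
    for q in sorted(calls, key=record_sort_key):
        on_chrom = [b for b in benchmark if b.chrom == q.chrom]
        if not on_chrom:
            fp.add(q.record_id)
            continue
        if ref is not None and q.chrom in ref:
            chrom_len = ref.chrom_length(q.chrom)
        else:
            chrom_len = max(max(b.end, b.ref_footprint_end) for b in on_chrom)
        w0 = max(config.small_window, min(config.expanded_window, int(chrom_len * 1e-5)))
        cands = [
            b for b in on_chrom if abs(b.pos - q.pos) <= w0 and b.key not in consumed
        ]
        if not cands and q.length >= 100:
            lo, hi = config.size_ratio_band
            cands = [
                b
                for b in on_chrom
                if abs(b.pos - q.pos) <= config.expanded_window
                and b.key not in consumed
                and type_compatible(q.svtype, b.svtype, config.match_mode)
                and lo <= q.length / b.length <= hi
            ]
        best = None
        for c in cands:
            ev = evaluate_pair(q, c, ref, config)
            if not ev.all_pass:
                continue
            primary = ev.seq_sim if ev.seq_sim is not None else ev.size_sim
            rank = (-primary, abs(q.pos - c.pos), c.pos, c.record_id)
            if best is None or rank < best[0]:
                best = (rank, c)
        if best is None:
            fp.add(q.record_id)
        else:
            consumed.add(best[1].key)
            matched_pairs[q.record_id] = best[1].record_id
    fn = {b.record_id for b in benchmark if b.key not in consumed}
    tp = {b.record_id for b in benchmark if b.key in consumed}
    return {"tp_benchmark": tp, "fn_benchmark": fn, "fp_calls": fp, "pairs": matched_pairs}


# ---------------------------------------------------------------------------
# dense random instances (records may contend for the same benchmark entries)


def make_dense_instance(
    seed: int,
    ref: Reference,
    n_benchmark: int = 15,
    chrom: str = "1",
    region: Tuple[int, int] = (5_000, 60_000),
) -> Tuple[List[SVRecord], List[SVRecord]]:
    """Random benchmark + contending callset on one chromosome. Positions are
    intentionally crowded so candidate windows overlap and consumption order
    matters."""
    rng = np.random.default_rng(seed)
    bench: List[SVRecord] = []
    for i in range(n_benchmark):
        pos = int(rng.integers(*region))
        svtype = str(rng.choice(["INS", "DEL", "DUP"], p=[0.45, 0.45, 0.1]))
        length = int(rng.integers(20, 400))
        bench.append(_make_record(ref, chrom, pos, svtype, length, rng, f"b{i}", "benchmark"))
    calls: List[SVRecord] = []
    k = 0
    for b in bench:
        for _ in range(int(rng.integers(0, 3))):  # 0..2 contending calls each
            k += 1
            shift = int(rng.integers(-300, 301))
            jitter = float(rng.uniform(0.75, 1.25))
            length = max(20, int(round(b.length * jitter)))
            pos = max(2, b.pos + shift)
            if b.symbolic:
                calls.append(_make_record(ref, chrom, pos, b.svtype, length, rng, f"q{k}", "calls"))
            elif b.svtype == "INS":
                inserted = b.alt_seq[len(b.ref_seq):]
                seq = (inserted + _rand_seq(rng, length))[:length]
                anchor = ref.fetch(chrom, pos, pos)
                calls.append(
                    SVRecord(
                        chrom=chrom, pos=pos, end=pos, svtype="INS", length=length,
                        ref_seq=anchor, alt_seq=anchor + seq,
                        record_id=f"q{k}", source="calls",
                    )
                )
            else:
                calls.append(_make_record(ref, chrom, pos, "DEL", length, rng, f"q{k}", "calls"))
    for _ in range(5):  # plus unrelated decoys
        k += 1
        pos = int(rng.integers(*region))
        calls.append(
            _make_record(ref, chrom, pos, str(rng.choice(["INS", "DEL"])),
                         int(rng.integers(20, 400)), rng, f"q{k}", "calls")
        )
    return sorted(calls, key=record_sort_key), sorted(bench, key=record_sort_key)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _make_record(
    ref: Reference, chrom: str, pos: int, svtype: str, length: int,
    rng: np.random.Generator, rid: str, source: str,
) -> SVRecord:
    anchor = ref.fetch(chrom, pos, pos)
    if svtype == "INS":
        rec = SVRecord(
            chrom=chrom, pos=pos, end=pos, svtype="INS", length=length,
            ref_seq=anchor, alt_seq=anchor + _rand_seq(rng, length),
            record_id=rid, source=source,
        )
    elif svtype == "DEL":
        rec = SVRecord(
            chrom=chrom, pos=pos, end=pos, svtype="DEL", length=length,
            ref_seq=ref.fetch(chrom, pos, pos + length), alt_seq=anchor,
            record_id=rid, source=source,
        )
    else:
        rec = SVRecord(
            chrom=chrom, pos=pos, end=pos, svtype=svtype, length=length,
            ref_seq=anchor, alt_seq="", symbolic=True, record_id=rid, source=source,
        )
    return recompute_end(rec)
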