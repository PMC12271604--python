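"""Seeded synthetic data: reference, truth SVs and perturbed callsets.

The generator emulates the failure modes the benchmarking method targets:
breakpoint shifts and size jitter from imprecise alignment, dropped calls,
novel decoy calls, second alleles at a matched site, and — centrally — one
large variant reported as several adjacent smaller calls carrying exact
subsequences of the original, which single-record matching misses but merge
validation should rescue. Truth sites are separated by at least twice the
expanded search window so every expected label is decidable in isolation.
All randomness flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .config import MatchConfig
from .joint_analysis import _apply_edits
from .sv_io import Reference, SVRecord, recompute_end, record_sort_key, write_fasta, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass(frozen=True)
class PerturbationSpec:
    """How a truth set is degraded into a callset.

    ``dropout_rate``, ``split_fraction`` and the in-place perturbation are
    mutually exclusive per record (dropout wins, then split); ``fp_rate`` and
    ``allele_injection_rate`` add extra calls. Split calls carry exact
    subsequences of the original variant, so merge validation is decided by
    the similarity thresholds alone. Shift and jitter defaults stay within
    half the matching tolerances (|shift| <= 100 bp, size ratio >= 0.85), so
    in-place perturbed calls are expected first-pass TPs.
    """

    breakpoint_shift_sd: float = 10.0
    max_shift: int = 100
    size_jitter_frac: float = 0.1
    split_fraction: float = 0.0
    split_k_choices: Tuple[int, ...] = (2, 3, 4, 5, 6)
    split_gap: int = 10
    dropout_rate: float = 0.0
    fp_rate: float = 0.0
    allele_injection_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("split_fraction", "dropout_rate", "fp_rate", "allele_injection_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.dropout_rate + self.split_fraction > 1.0:
            raise ValueError("dropout_rate + split_fraction must not exceed 1")
        if not (0.0 <= self.size_jitter_frac <= 0.15):
            raise ValueError("size_jitter_frac above 0.15 would break the expected labels")


@dataclass
class ExpectedLabels:
    """Ground-truth classification implied by the perturbation bookkeeping."""

    tp_benchmark_ids: Set[str] = field(default_factory=set)
    fn_benchmark_ids: Set[str] = field(default_factory=set)
    matched_call_ids: Set[str] = field(default_factory=set)
    fp_call_ids: Set[str] = field(default_factory=set)
    lp_call_ids: Set[str] = field(default_factory=set)
    #: benchmark id -> tuple of LP member call ids for expected merges
    merges: Dict[str, Tuple[str, ...]] = field(default_factory=dict)


def simulate_reference(
    length: int,
    seed: int,
    repeat_fraction: float = 0.0,
    chrom: str = "1",
) -> Tuple[Reference, List[Tuple[int, int, int]]]:
    """Random reference of ``length`` bp with optional planted tandem-repeat
    tracts (start, end, unit_len; 1-based inclusive) covering approximately
    ``repeat_fraction`` of the sequence."""
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kbp")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length)
    tracts: List[Tuple[int, int, int]] = []
    planted = 0
    target = int(repeat_fraction * length)
    guard = 0
    while planted < target and guard < 10_000:
        guard += 1
        unit_len = int(rng.integers(2, 21))
        copies = int(rng.integers(5, 30))
        tract_len = unit_len * copies
        start = int(rng.integers(0, length - tract_len))
        unit = rng.choice(_BASES, size=unit_len)
        seq[start : start + tract_len] = np.tile(unit, copies)
        tracts.append((start + 1, start + tract_len, unit_len))
        planted += tract_len
    ref = Reference({chrom: seq.tobytes().decode("ascii")})
    return ref, tracts


DEFAULT_TYPE_MIX: Mapping[str, float] = {"INS": 0.4, "DEL": 0.4, "DUP": 0.1, "INV": 0.1}


def _sample_size(rng: np.random.Generator, config: MatchConfig) -> int:
    """Log-uniform sizes between min_size and ~5 kbp: small SVs dominate, as
    in real callsets."""
    lo, hi = np.log(config.min_size), np.log(min(5_000, config.max_size))
    return int(round(np.exp(rng.uniform(lo, hi))))


def simulate_truth(
    ref: Reference,
    n_sv: int,
    seed: int,
    type_mix: Optional[Mapping[str, float]] = None,
    size_sampler=None,
    config: Optional[MatchConfig] = None,
    min_separation: Optional[int] = None,
    source: str = "benchmark",
) -> List[SVRecord]:
    """Place ``n_sv`` non-overlapping truth SVs with exact sequences.

    INS/DEL are sequence-resolved; DUP/INV are emitted as symbolic alleles.
    Sites are separated by at least ``min_separation`` (default twice the
    expanded search window) so matching decisions never interact."""
    config = config or MatchConfig()
    type_mix = dict(type_mix or DEFAULT_TYPE_MIX)
    min_separation = min_separation or 2 * config.expanded_window
    rng = np.random.default_rng(seed)
    chroms = sorted(ref.lengths)
    types = sorted(type_mix)
    probs = np.array([type_mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    records: List[SVRecord] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(records) < n_sv:
        attempts += 1
        if attempts > 200 * n_sv:
            raise RuntimeError(
                f"could only place {len(records)} of {n_sv} SVs with separation "
                f"{min_separation}; enlarge the reference"
            )
        svtype = str(rng.choice(types, p=probs))
        length = _sample_size(rng, config) if size_sampler is None else int(size_sampler(rng))
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = ref.chrom_length(chrom)
        footprint = 1 if svtype == "INS" else length + 1
        if clen < footprint + 2 * min_separation + 2:
            continue
        pos = int(rng.integers(min_separation + 1, clen - footprint - min_separation))
        lo, hi = pos - min_separation, pos + footprint + min_separation
        if any(not (hi < a or b < lo) for a, b in occupied[chrom]):
            continue
        occupied[chrom].append((lo, hi))
        anchor = ref.fetch(chrom, pos, pos)
        idx = len(records) + 1
        if svtype == "INS":
            inserted = _random_seq(rng, length)
            rec = SVRecord(
                chrom=chrom, pos=pos, end=pos, svtype="INS", length=length,
                ref_seq=anchor, alt_seq=anchor + inserted,
                record_id=f"truth_{idx}", source=source,
            )
        elif svtype == "DEL":
            ref_seq = ref.fetch(chrom, pos, pos + length)
            rec = SVRecord(
                chrom=chrom, pos=pos, end=pos, svtype="DEL", length=length,
                ref_seq=ref_seq, alt_seq=anchor,
                record_id=f"truth_{idx}", source=source,
            )
        else:  # symbolic DUP / INV
            rec = SVRecord(
                chrom=chrom, pos=pos, end=pos, svtype=svtype, length=length,
                ref_seq=anchor, alt_seq="", symbolic=True,
                record_id=f"truth_{idx}", source=source,
            )
        records.append(recompute_end(rec))
    records.sort(key=record_sort_key)
    return records


def apply_to_reference(ref: Reference, chrom: str, records: Sequence[SVRecord]) -> str:
    """ALT haplotype of the whole chromosome with the (sequence-resolved,
    non-overlapping) records applied in coordinate order."""
    resolved = [r for r in records if not r.symbolic and r.chrom == chrom]
    hap = _apply_edits(ref, chrom, 1, ref.chrom_length(chrom), resolved)
    if hap is None:
        raise ValueError("records overlap; cannot build a haplotype")
    return hap


# ---------------------------------------------------------------------------
# perturbation


def _split_record(
    truth: SVRecord, k: int, gap: int, ref: Reference, source: str
) -> Optional[List[SVRecord]]:
    """Split one resolved truth SV into k adjacent parts carrying exact
    subsequences. Deletion parts partition the deleted bases contiguously;
    insertion parts place consecutive slices at positions ``gap`` bp apart."""
    L = truth.length
    if truth.symbolic or L < 20 * k:
        return None
    cuts = np.linspace(0, L, k + 1).astype(int)
    parts: List[SVRecord] = []
    if truth.svtype == "INS":
        inserted = truth.alt_seq[len(truth.ref_seq):]
        for j in range(k):
            piece = inserted[cuts[j]: cuts[j + 1]]
            pos = truth.pos + j * gap
            anchor = ref.fetch(truth.chrom, pos, pos)
            parts.append(SVRecord(
                chrom=truth.chrom, pos=pos, end=pos, svtype="INS", length=len(piece),
                ref_seq=anchor, alt_seq=anchor + piece,
                record_id=f"{truth.record_id}_part{j + 1}", source=source,
            ))
    elif truth.svtype == "DEL":
        # deleted bases are truth.pos+1 .. truth.pos+L
        for j in range(k):
            del_lo = truth.pos + 1 + cuts[j]
            del_hi = truth.pos + cuts[j + 1]
            pos = del_lo - 1
            parts.append(recompute_end(SVRecord(
                chrom=truth.chrom, pos=pos, end=pos, svtype="DEL",
                length=del_hi - del_lo + 1,
                ref_seq=ref.fetch(truth.chrom, pos, del_hi),
                alt_seq=ref.fetch(truth.chrom, pos, pos),
                record_id=f"{truth.record_id}_part{j + 1}", source=source,
            )))
    else:
        return None
    return parts


def _perturb_in_place(
    truth: SVRecord, spec: PerturbationSpec, rng: np.random.Generator,
    ref: Reference, source: str,
) -> SVRecord:
    shift = int(round(rng.normal(0.0, spec.breakpoint_shift_sd)))
    shift = int(np.clip(shift, -spec.max_shift, spec.max_shift))
    # keep the distance criterion comfortably satisfied for small SVs
    shift = int(np.clip(shift, -(truth.length // 2 + 10), truth.length // 2 + 10))
    pos = max(2, truth.pos + shift)
    jitter_cap = int(spec.size_jitter_frac * truth.length)
    trim = int(rng.integers(0, jitter_cap + 1)) if jitter_cap > 0 else 0
    length = max(truth.length - trim, 20)
    trim = truth.length - length
    anchor = ref.fetch(truth.chrom, pos, pos)
    if truth.svtype == "INS":
        inserted = truth.alt_seq[len(truth.ref_seq):]
        inserted = inserted[: length] if trim else inserted
        rec = SVRecord(
            chrom=truth.chrom, pos=pos, end=pos, svtype="INS", length=len(inserted),
            ref_seq=anchor, alt_seq=anchor + inserted,
            record_id=f"{truth.record_id}_call", source=source,
        )
    elif truth.svtype == "DEL":
        rec = SVRecord(
            chrom=truth.chrom, pos=pos, end=pos, svtype="DEL", length=length,
            ref_seq=ref.fetch(truth.chrom, pos, pos + length), alt_seq=anchor,
            record_id=f"{truth.record_id}_call", source=source,
        )
    else:
        rec = SVRecord(
            chrom=truth.chrom, pos=pos, end=pos, svtype=truth.svtype, length=length,
            ref_seq=anchor, alt_seq="", symbolic=True,
            record_id=f"{truth.record_id}_call", source=source,
        )
    return recompute_end(rec)


def _decoy_record(
    rng: np.random.Generator, ref: Reference, occupied: Dict[str, List[Tuple[int, int]]],
    config: MatchConfig, min_separation: int, idx: int, source: str,
) -> Optional[SVRecord]:
    chroms = sorted(ref.lengths)
    for _ in range(200):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clen = ref.chrom_length(chrom)
        length = _sample_size(rng, config)
        svtype = "INS" if rng.random() < 0.5 else "DEL"
        footprint = 1 if svtype == "INS" else length + 1
        if clen < footprint + 2 * min_separation + 2:
            continue
        pos = int(rng.integers(min_separation + 1, clen - footprint - min_separation))
        lo, hi = pos - min_separation, pos + footprint + min_separation
        if any(not (hi < a or b < lo) for a, b in occupied[chrom]):
            continue
        occupied[chrom].append((lo, hi))
        anchor = ref.fetch(chrom, pos, pos)
        if svtype == "INS":
            rec = SVRecord(
                chrom=chrom, pos=pos, end=pos, svtype="INS", length=length,
                ref_seq=anchor, alt_seq=anchor + _random_seq(rng, length),
                record_id=f"decoy_{idx}", source=source,
            )
        else:
            rec = SVRecord(
                chrom=chrom, pos=pos, end=pos, svtype="DEL", length=length,
                ref_seq=ref.fetch(chrom, pos, pos + length), alt_seq=anchor,
                record_id=f"decoy_{idx}", source=source,
            )
        return recompute_end(rec)
    return None


def perturb_callset(
    truth: Sequence[SVRecord],
    ref: Reference,
    spec: PerturbationSpec,
    config: Optional[MatchConfig] = None,
    source: str = "calls",
) -> Tuple[List[SVRecord], ExpectedLabels]:
    """Degrade a truth set into a callset with known expected labels."""
    config = config or MatchConfig()
    rng = np.random.default_rng(spec.seed)
    min_separation = 2 * config.expanded_window
    calls: List[SVRecord] = []
    expected = ExpectedLabels()
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in ref.lengths}
    for t in truth:
        footprint = 1 if t.svtype == "INS" else t.length + 1
        occupied.setdefault(t.chrom, []).append(
            (t.pos - min_separation, t.pos + footprint + min_separation)
        )
    for t in truth:
        u = rng.random()
        if u < spec.dropout_rate:
            expected.fn_benchmark_ids.add(t.record_id)
            continue
        splittable = (not t.symbolic) and t.svtype in ("INS", "DEL")
        if u < spec.dropout_rate + spec.split_fraction and splittable:
            k_opts = [k for k in spec.split_k_choices if t.length >= 20 * k]
            if k_opts:
                k = int(rng.choice(k_opts))
                parts = _split_record(t, k, spec.split_gap, ref, source)
                if parts is not None:
                    calls.extend(parts)
                    part_ids = tuple(p.record_id for p in parts)
                    expected.lp_call_ids.update(part_ids)
                    expected.tp_benchmark_ids.add(t.record_id)
                    expected.merges[t.record_id] = part_ids
                    continue
            # not splittable at any k: fall through to in-place perturbation
        call = _perturb_in_place(t, spec, rng, ref, source)
        calls.append(call)
        expected.matched_call_ids.add(call.record_id)
        expected.tp_benchmark_ids.add(t.record_id)
        if rng.random() < spec.allele_injection_rate:
            # a second, clearly distinct allele at the same site: too large to
            # size-match the benchmark record, so an expected FP
            allele_len = t.length * 2
            anchor = ref.fetch(t.chrom, t.pos, t.pos)
            allele = recompute_end(SVRecord(
                chrom=t.chrom, pos=t.pos, end=t.pos, svtype="INS", length=allele_len,
                ref_seq=anchor, alt_seq=anchor + _random_seq(rng, allele_len),
                record_id=f"{t.record_id}_allele", source=source,
            ))
            calls.append(allele)
            expected.fp_call_ids.add(allele.record_id)
    n_decoys = int(round(spec.fp_rate * len(truth)))
    for i in range(n_decoys):
        rec = _decoy_record(rng, ref, occupied, config, min_separation, i + 1, source)
        if rec is not None:
            calls.append(rec)
            expected.fp_call_ids.add(rec.record_id)
    calls.sort(key=record_sort_key)
    return calls, expected


# ---------------------------------------------------------------------------
# the split-insertion worked case


def split_insertion_case(
    seed: int,
    ins_len: int = 147,
    part_lens: Tuple[int, ...] = (49, 98),
    gap: int = 10,
    ref_len: int = 100_000,
    chrom: str = "1",
) -> Tuple[Reference, List[SVRecord], List[SVRecord]]:
    """One benchmark insertion reported as adjacent split insertions carrying
    its exact subsequences. Returns (reference, benchmark, callset)."""
    if sum(part_lens) != ins_len:
        raise ValueError("part lengths must sum to the benchmark insertion length")
    ref, _ = simulate_reference(ref_len, seed, chrom=chrom)
    rng = np.random.default_rng(seed + 1)
    pos = ref_len // 2
    inserted = _random_seq(rng, ins_len)
    anchor = ref.fetch(chrom, pos, pos)
    benchmark = [SVRecord(
        chrom=chrom, pos=pos, end=pos, svtype="INS", length=ins_len,
        ref_seq=anchor, alt_seq=anchor + inserted,
        record_id="bench_ins", source="benchmark",
    )]
    calls: List[SVRecord] = []
    offset = 0
    for j, plen in enumerate(part_lens):
        p = pos + j * gap
        a = ref.fetch(chrom, p, p)
        calls.append(SVRecord(
            chrom=chrom, pos=p, end=p, svtype="INS", length=plen,
            ref_seq=a, alt_seq=a + inserted[offset: offset + plen],
            record_id=f"call_part{j + 1}", source="calls",
        ))
        offset += plen
    return ref, benchmark, calls


def write_bundle(
    out_dir: Union[str, Path],
    ref: Reference,
    benchmark: Sequence[SVRecord],
    callsets: Mapping[str, Sequence[SVRecord]],
    expected: Optional[Mapping[str, ExpectedLabels]] = None,
) -> Dict[str, Path]:
    """Write a complete synthetic bundle: FASTA, benchmark VCF, one VCF per
    callset and (optionally) expected-label TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    paths["fasta"] = out_dir / "reference.fasta"
    write_fasta(paths["fasta"], {c: ref.fetch(c, 1, ref.chrom_length(c)) for c in sorted(ref.lengths)})
    paths["benchmark"] = out_dir / "benchmark.vcf"
    write_vcf(paths["benchmark"], benchmark, reference=ref, source="benchmark")
    for name, calls in callsets.items():
        p = out_dir / f"{name}.vcf"
        write_vcf(p, calls, reference=ref, source=name)
        paths[name] = p
    if expected:
        for name, labels in expected.items():
            p = out_dir / f"{name}.expected.tsv"
            with open(p, "w") as fh:
                fh.write("record_id\tside\texpected\n")
                for rid in sorted(labels.tp_benchmark_ids):
                    fh.write(f"{rid}\tbenchmark\tTP\n")
                for rid in sorted(labels.fn_benchmark_ids):
                    fh.write(f"{rid}\tbenchmark\tFN\n")
                for rid in sorted(labels.matched_call_ids):
                    fh.write(f"{rid}\tcall\tTP\n")
                for rid in sorted(labels.fp_call_ids):
                    fh.write(f"{rid}\tcall\tFP\n")
                for rid in sorted(labels.lp_call_ids):
                    fh.write(f"{rid}\tcall\tLP\n")
            paths[f"{name}_expected"] = p
    return paths
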