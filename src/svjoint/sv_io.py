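"""VCF / FASTA ingestion and per-class VCF output.

Records are normalised into :class:`SVRecord`: one object per ALT allele with
a positive length, a recomputed end coordinate and the raw REF/ALT column
sequences. Coordinates are 1-based inclusive throughout; insertions carry no
reference span (``end == pos``).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pysam
from pyfaidx import Fasta

from .config import MatchConfig, SUPPORTED_SVTYPES

logger = logging.getLogger(__name__)

_SYMBOLIC_RE = re.compile(r"^<([A-Za-z0-9:_]+)>$")


@dataclass(frozen=True)
class SVRecord:
    """One structural variant.

    ``pos``/``end`` are 1-based inclusive; ``end == pos`` for insertions.
    ``ref_seq``/``alt_seq`` hold the raw REF/ALT column sequences (``alt_seq``
    is empty for symbolic alleles such as ``<DUP>``). ``length`` is always
    positive.
    """

    chrom: str
    pos: int
    end: int
    svtype: str
    length: int
    ref_seq: str = ""
    alt_seq: str = ""
    symbolic: bool = False
    record_id: str = "."
    source: str = ""
    genotype: Optional[str] = None

    def __post_init__(self) -> None:
        # coerce numpy integers so downstream serialization sees plain ints
        for name in ("pos", "end", "length"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.length <= 0:
            raise ValueError(f"SV length must be positive, got {self.length}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.svtype not in SUPPORTED_SVTYPES:
            raise ValueError(f"unsupported svtype {self.svtype!r}")

    @property
    def key(self) -> Tuple[str, str, str, int, int]:
        """Identity of the record within one callset."""
        return (self.source, self.record_id, self.chrom, self.pos, self.length)

    @property
    def span(self) -> int:
        """Reference span in bp (1 for insertions)."""
        return self.end - self.pos + 1

    @property
    def ref_footprint_end(self) -> int:
        """Last reference base covered by the REF column (>= pos)."""
        return self.pos + max(len(self.ref_seq), 1) - 1

    def variant_sequence(self) -> str:
        """The sequence the similarity criterion compares: the REF column for
        deletions (the deleted bases), the ALT column otherwise."""
        return self.ref_seq if self.svtype == "DEL" else self.alt_seq


class Reference:
    """Per-chromosome sequence accessor with 1-based inclusive fetching.

    Out-of-bounds requests are clamped to the chromosome ends, so the caller
    can extend windows blindly.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        self.lengths: Dict[str, int] = {k: len(v) for k, v in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "Reference":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: fa[name][:] for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chrom_length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def fetch(self, chrom: str, start: int, stop: int) -> str:
        """Bases ``start..stop`` (1-based inclusive), clamped to the contig."""
        seq = self._seqs[chrom]
        if stop < start:
            return ""
        lo = max(start, 1)
        hi = min(stop, len(seq))
        if hi < lo:
            return ""
        return seq[lo - 1 : hi]


def chrom_sort_key(chrom: str) -> Tuple[int, int, str]:
    """Natural chromosome order: 1..22, X, Y, MT, then others alphabetically."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, chrom)


def record_sort_key(rec: SVRecord) -> Tuple[Tuple[int, int, str], int, str]:
    return (chrom_sort_key(rec.chrom), rec.pos, rec.record_id)


def infer_sv_length(
    pos: int,
    end: Optional[int],
    ref_seq: str,
    alt_seq: str,
    svtype: str,
    info_svlen: Optional[int],
) -> Optional[int]:
    """Resolve the SV length, preferring INFO/SVLEN over coordinates over
    sequence content. Returns ``None`` when no source is usable."""
    if info_svlen:
        return abs(int(info_svlen))
    if svtype in ("DEL", "DUP", "INV"):
        if end is not None and end > pos:
            return end - pos
        if svtype == "DEL" and ref_seq and alt_seq and len(ref_seq) > len(alt_seq):
            return len(ref_seq) - len(alt_seq)
        return None
    # INS: length of the inserted sequence
    if alt_seq and ref_seq and len(alt_seq) > len(ref_seq):
        return len(alt_seq) - len(ref_seq)
    if alt_seq and not ref_seq:
        return len(alt_seq)
    return None


def recompute_end(record: SVRecord) -> SVRecord:
    """Recompute ``end`` from the length, discarding the INFO END (which is
    unreliable for insertions in many callsets and simulated truth sets)."""
    if record.svtype == "INS":
        return replace(record, end=record.pos)
    return replace(record, end=record.pos + record.length - 1)


@dataclass
class ParseResult:
    records: List[SVRecord]
    exclusions: Counter = field(default_factory=Counter)

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusions.values())


def _classify_alt(ref: str, alt: str, info_svtype: Optional[str]) -> Tuple[Optional[str], bool]:
    """Determine (svtype, symbolic) for one ALT allele; svtype None when the
    allele is not a supported SV type."""
    m = _SYMBOLIC_RE.match(alt) if alt else None
    if m:
        tag = m.group(1).split(":")[0].upper()
        return (tag if tag in SUPPORTED_SVTYPES else None, True)
    if info_svtype:
        tag = info_svtype.split(":")[0].upper()
        if tag in SUPPORTED_SVTYPES:
            return tag, False
        return None, False
    if ref and alt and set(alt) <= set("ACGTNacgtn"):
        if len(alt) > len(ref):
            return "INS", False
        if len(ref) > len(alt):
            return "DEL", False
    return None, False


def _info_scalar(value, index: int):
    """Pick the per-ALT element out of a possibly tuple-valued INFO field."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if len(value) == 0:
            return None
        return value[index] if index < len(value) else value[0]
    return value


def parse_callset(
    vcf_path: Union[str, Path],
    config: MatchConfig,
    source_label: str = "",
) -> ParseResult:
    """Read one VCF (v4.2, plain or bgzip) into filtered, sorted SVRecords.

    Multi-allelic lines are split per ALT. Records are excluded — and tallied
    by reason — when the type is unsupported (e.g. BND/TRA/SNV), the
    chromosome is outside the configured inclusion set, no length can be
    determined, or the length falls outside [min_size, max_size]. Malformed
    records are skipped with a warning, never aborting the parse.
    """
    path = Path(vcf_path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    out: List[SVRecord] = []
    excl: Counter = Counter()
    seen_ids: Counter = Counter()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            try:
                alts = rec.alts or ()
                info_svtype = rec.info.get("SVTYPE")
                if isinstance(info_svtype, (tuple, list)):
                    info_svtype = info_svtype[0] if info_svtype else None
                info_svlen = rec.info.get("SVLEN")
                info_end = rec.stop  # 1-based inclusive END
                gt = None
                if rec.samples:
                    sample = rec.samples[0]
                    if "GT" in sample and sample["GT"] is not None:
                        sep = "|" if sample.phased else "/"
                        gt = sep.join("." if a is None else str(a) for a in sample["GT"])
                for ai, alt in enumerate(alts):
                    svtype, symbolic = _classify_alt(rec.ref or "", alt or "", info_svtype)
                    if svtype is None:
                        excl["unsupported_type"] += 1
                        continue
                    if not config.chrom_allowed(rec.chrom):
                        excl["excluded_chrom"] += 1
                        continue
                    length = infer_sv_length(
                        rec.pos,
                        info_end,
                        rec.ref or "",
                        "" if symbolic else (alt or ""),
                        svtype,
                        _info_scalar(info_svlen, ai),
                    )
                    if length is None:
                        excl["no_length"] += 1
                        continue
                    if length < config.min_size:
                        excl["below_min_size"] += 1
                        continue
                    if length > config.max_size:
                        excl["above_max_size"] += 1
                        continue
                    rid = rec.id or f"{rec.chrom}_{rec.pos}_{svtype}"
                    if len(alts) > 1:
                        rid = f"{rid}_alt{ai + 1}"
                    seen_ids[rid] += 1
                    if seen_ids[rid] > 1:
                        rid = f"{rid}_dup{seen_ids[rid]}"
                    sv = SVRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        end=rec.pos,  # recomputed below
                        svtype=svtype,
                        length=length,
                        ref_seq=rec.ref or "",
                        alt_seq="" if symbolic else (alt or ""),
                        symbolic=symbolic,
                        record_id=rid,
                        source=source_label,
                        genotype=gt,
                    )
                    out.append(recompute_end(sv))
            except Exception as exc:  # malformed record: skip, keep parsing
                excl["malformed"] += 1
                logger.warning("skipping malformed record in %s: %s", path.name, exc)
    out.sort(key=record_sort_key)
    return ParseResult(records=out, exclusions=excl)


# ---------------------------------------------------------------------------
# VCF output


def _build_header(
    records: Sequence[SVRecord],
    reference: Optional[Reference],
    source: str,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line(
        '##INFO=<ID=SVJ_CLASS,Number=1,Type=String,Description="Benchmark class (TP/FP/FN/LP)">'
    )
    header.add_line(
        '##INFO=<ID=SVJ_SEQSIM,Number=1,Type=Float,Description="Sequence similarity of the accepted match">'
    )
    header.add_line(
        '##INFO=<ID=SVJ_D,Number=1,Type=Integer,Description="Signed breakpoint distance to the matched record">'
    )
    header.add_line(
        '##INFO=<ID=SVJ_R,Number=1,Type=Float,Description="Span ratio to the matched record">'
    )
    header.add_line(
        '##INFO=<ID=SVJ_MERGE_ID,Number=1,Type=String,Description="Identifier linking merged LP members to their validated benchmark record">'
    )
    if source:
        header.add_line(f"##svjoint_source={source}")
    chroms: Dict[str, int] = {}
    for rec in records:
        need = max(rec.end, rec.ref_footprint_end) + 1
        chroms[rec.chrom] = max(chroms.get(rec.chrom, 0), need)
    if reference is not None:
        for c in list(chroms):
            if c in reference:
                chroms[c] = reference.chrom_length(c)
    for c in sorted(chroms, key=chrom_sort_key):
        header.contigs.add(c, length=chroms[c])
    return header


def write_vcf(
    path: Union[str, Path],
    records: Sequence[SVRecord],
    reference: Optional[Reference] = None,
    source: str = "",
    annotations: Optional[Mapping[Tuple, Mapping[str, object]]] = None,
) -> None:
    """Write records to a VCF, optionally annotating each with classification
    INFO tags keyed by ``SVRecord.key``."""
    records = sorted(records, key=record_sort_key)
    header = _build_header(records, reference, source)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            ref = rec.ref_seq or "N"
            alt = f"<{rec.svtype}>" if rec.symbolic else (rec.alt_seq or f"<{rec.svtype}>")
            kwargs = {}
            if rec.symbolic:
                # resolved alleles carry their span in REF; symbolic ones need END
                kwargs["stop"] = max(rec.end, rec.pos)
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=(ref, alt),
                id=rec.record_id,
                **kwargs,
            )
            row.info["SVTYPE"] = rec.svtype
            row.info["SVLEN"] = rec.length if rec.svtype != "DEL" else -rec.length
            if annotations and rec.key in annotations:
                for k, v in annotations[rec.key].items():
                    row.info[k] = v
            out.write(row)


def write_class_vcfs(
    out_dir: Union[str, Path],
    classification,
    reference: Optional[Reference] = None,
) -> Dict[str, Path]:
    """Write tp/fp/fn/lp VCFs for one classification into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    ann: Dict[Tuple, Dict[str, object]] = {}
    for m in classification.tp_matches:
        tag = {
            "SVJ_CLASS": "TP",
            "SVJ_SEQSIM": float(m.seq_sim) if m.seq_sim is not None else None,
            "SVJ_D": int(m.d),
            "SVJ_R": float(m.r),
        }
        ann[m.benchmark.key] = {k: v for k, v in tag.items() if v is not None}
        if m.via_merge:
            merge_id = f"merge_{m.benchmark.record_id}"
            ann[m.benchmark.key]["SVJ_MERGE_ID"] = merge_id
            for member in m.merge_members:
                ann[member.key] = {"SVJ_CLASS": "LP", "SVJ_MERGE_ID": merge_id}
        else:
            ann[m.query.key] = dict(ann[m.benchmark.key])
    for name, recs in (
        ("tp", classification.tp_benchmark),
        ("fp", classification.fp_calls),
        ("fn", classification.fn_benchmark),
        ("lp", classification.lp_calls),
    ):
        p = out_dir / f"{name}.vcf"
        default = {"SVJ_CLASS": name.upper()}
        local_ann = {r.key: {**default, **ann.get(r.key, {})} for r in recs}
        write_vcf(p, recs, reference=reference, annotations=local_ann)
        paths[name] = p
    return paths


def write_fasta(path: Union[str, Path], sequences: Mapping[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
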