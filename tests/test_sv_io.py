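import numpy as np
import pytest

from svjoint.config import MatchConfig
from svjoint.sv_io import (
    Reference,
    SVRecord,
    chrom_sort_key,
    infer_sv_length,
    parse_callset,
    recompute_end,
    write_class_vcfs,
    write_fasta,
    write_vcf,
)

from conftest import make_del, make_ins, make_symbolic, rand_seq


def test_reference_fetch_is_one_based_inclusive():
    ref = Reference({"1": "ACGTACGT"})
    assert ref.fetch("1", 1, 1) == "A"
    assert ref.fetch("1", 2, 4) == "CGT"
    assert ref.fetch("1", 1, 8) == "ACGTACGT"
    # clamped at the ends, empty when the window is inverted
    assert ref.fetch("1", -5, 2) == "AC"
    assert ref.fetch("1", 7, 100) == "GT"
    assert ref.fetch("1", 5, 4) == ""
    assert ref.chrom_length("1") == 8
    assert "1" in ref and "2" not in ref


def test_reference_fasta_roundtrip(tmp_path):
    seqs = {"1": "ACGT" * 30, "X": "GGCCTTAA" * 11}
    path = tmp_path / "ref.fasta"
    write_fasta(path, seqs, width=10)
    ref = Reference.from_fasta(path)
    for chrom, seq in seqs.items():
        assert ref.fetch(chrom, 1, len(seq)) == seq


def test_chrom_sort_key_orders_numerics_then_xy():
    chroms = ["X", "2", "10", "1", "Y", "chr3"]
    ordered = sorted(chroms, key=chrom_sort_key)
    assert ordered.index("1") < ordered.index("2") < ordered.index("10")
    assert ordered.index("10") < ordered.index("X") < ordered.index("Y")


def test_infer_sv_length_precedence():
    # explicit SVLEN wins (absolute value)
    assert infer_sv_length(100, 150, "N", "<DEL>", "DEL", -300) == 300
    # then END - POS for spanned types
    assert infer_sv_length(100, 150, "N", "<DEL>", "DEL", None) == 50
    # then the REF/ALT sequence difference
    assert infer_sv_length(100, 100, "A", "A" + "C" * 40, "INS", None) == 40
    assert infer_sv_length(100, 100, "A" + "G" * 25, "A", "DEL", None) == 25
    # nothing to go on -> None
    assert infer_sv_length(100, 100, "N", "<INV>", "INV", None) is None


def test_recompute_end_conventions():
    ins = SVRecord(chrom="1", pos=10, end=99, svtype="INS", length=30,
                   ref_seq="A", alt_seq="A" + "C" * 30, record_id="i", source="s")
    assert recompute_end(ins).end == 10
    dele = SVRecord(chrom="1", pos=10, end=0, svtype="DEL", length=30,
                    ref_seq="N" * 31, alt_seq="N", record_id="d", source="s")
    assert recompute_end(dele).end == 39  # pos + L - 1


def test_vcf_roundtrip_preserves_records(tmp_path, ref):
    rng = np.random.default_rng(3)
    records = [
        make_ins(ref, "1", 5_000, rand_seq(rng, 60), rid="a"),
        make_del(ref, "1", 9_000, 120, rid="b"),
        make_symbolic("1", 15_000, "DUP", 400, rid="c"),
        make_symbolic("1", 20_000, "INV", 800, rid="d"),
    ]
    path = tmp_path / "calls.vcf"
    write_vcf(path, records, reference=ref, source="calls")
    result = parse_callset(path, MatchConfig(), source_label="calls")
    assert len(result.records) == len(records)
    by_id = {r.record_id: r for r in result.records}
    for orig in records:
        got = by_id[orig.record_id]
        assert (got.chrom, got.pos, got.svtype, got.length) == (
            orig.chrom, orig.pos, orig.svtype, orig.length)
        assert got.symbolic == orig.symbolic
        if not orig.symbolic:
            assert got.ref_seq == orig.ref_seq
            assert got.alt_seq == orig.alt_seq


def _write_raw_vcf(path, body_lines, contigs=("1", "2", "MT")):
    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c},length=1000000>")
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type">')
    lines.append('##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Len">')
    lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="End">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    lines.extend(body_lines)
    path.write_text("\n".join(lines) + "\n")


def test_parse_exclusions_and_multiallelic(tmp_path):
    vcf = tmp_path / "mixed.vcf"
    seq45 = "G" * 45
    seq80 = "T" * 80
    _write_raw_vcf(vcf, [
        # kept: resolved insertion
        f"1\t1000\tok1\tA\tA{seq45}\t.\tPASS\tSVTYPE=INS;SVLEN=45",
        # kept twice: multiallelic with two SV alleles
        f"1\t2000\tma\tA\tA{seq45},A{seq80}\t.\tPASS\tSVTYPE=INS",
        # excluded: below minimum size
        "1\t3000\tsmall\tA\tACCCCC\t.\tPASS\tSVTYPE=INS;SVLEN=5",
        # excluded: unsupported type
        "1\t4000\tbnd\tA\t<BND>\t.\tPASS\tSVTYPE=BND;SVLEN=100",
        # excluded: non-canonical chromosome
        f"MT\t5000\tmito\tA\tA{seq45}\t.\tPASS\tSVTYPE=INS;SVLEN=45",
        # excluded: symbolic with no length information
        "1\t6000\tnolen\tA\t<INV>\t.\tPASS\tSVTYPE=INV",
        # kept: symbolic DEL with END
        "2\t7000\tsymdel\tA\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=7400",
    ])
    result = parse_callset(vcf, MatchConfig(), source_label="calls")
    ids = sorted(r.record_id for r in result.records)
    assert len([i for i in ids if i.startswith("ma")]) == 2
    assert "ok1" in ids and "symdel" in ids
    assert len(result.records) == 4
    exc = result.exclusions
    assert exc["below_min_size"] == 1
    assert exc["unsupported_type"] == 1
    assert exc["excluded_chrom"] == 1
    assert exc["no_length"] == 1
    symdel = next(r for r in result.records if r.record_id == "symdel")
    assert symdel.symbolic and symdel.svtype == "DEL" and symdel.length == 400


def test_parse_rejects_above_max_size(tmp_path):
    vcf = tmp_path / "big.vcf"
    _write_raw_vcf(vcf, ["1\t1000\thuge\tA\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=60000"])
    result = parse_callset(vcf, MatchConfig(), source_label="calls")
    assert not result.records
    assert result.exclusions["above_max_size"] == 1


def test_write_class_vcfs_partitions(tmp_path, ref, config):
    from svjoint.matcher import match_callset

    rng = np.random.default_rng(11)
    bench = [make_ins(ref, "1", 50_000, rand_seq(rng, 100), rid="b1", source="benchmark")]
    calls = [
        make_ins(ref, "1", 50_010, bench[0].alt_seq[1:], rid="q1"),
        make_del(ref, "1", 120_000, 200, rid="q2"),
    ]
    cls = match_callset(calls, bench, ref, config, source="calls")
    paths = write_class_vcfs(tmp_path, cls, reference=ref)
    assert sorted(p.name for p in paths.values()) == [
        "fn.vcf", "fp.vcf", "lp.vcf", "tp.vcf"]
    # TP/FN are benchmark-side labels, FP/LP call-side labels
    tp = parse_callset(paths["tp"], config, source_label="tp").records
    fp = parse_callset(paths["fp"], config, source_label="fp").records
    fn = parse_callset(paths["fn"], config, source_label="fn").records
    assert [r.record_id for r in tp] == ["b1"]
    assert [r.record_id for r in fp] == ["q2"]
    assert not fn


def test_svrecord_key_and_span():
    rec = SVRecord(chrom="1", pos=np.int64(100), end=np.int64(100), svtype="INS",
                   length=np.int64(50), ref_seq="A", alt_seq="A" + "C" * 50,
                   record_id="x", source="s")
    # numpy integers are coerced to plain ints for VCF writing
    assert type(rec.pos) is int and type(rec.length) is int
    assert rec.span == 1  # insertions have no reference span
    with pytest.raises(AttributeError):
        rec.pos = 5  # frozen
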