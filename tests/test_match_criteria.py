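import dataclasses

import numpy as np
import pytest

from svjoint._nw import needleman_wunsch
from svjoint.config import MatchConfig
from svjoint.match_criteria import (
    aligned_pair_score,
    alignment_stats,
    evaluate_pair,
    extend_length,
    overlap_status,
    relief_score,
    sequence_similarity,
    size_similarity,
    type_compatible,
)

from _oracles import nw_oracle, pair_score_oracle, relief_score_oracle
from conftest import make_del, make_ins, make_symbolic, rand_seq


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def test_extend_length_step():
    assert extend_length(20) == 200
    assert extend_length(100) == 200
    assert extend_length(101) == 1000
    assert extend_length(50_000) == 1000
    with pytest.raises(ValueError):
        extend_length(0)


def test_type_compatibility_modes():
    assert type_compatible("INS", "INS")
    assert not type_compatible("INS", "DEL")
    assert not type_compatible("INS", "DUP", "strict")
    assert type_compatible("INS", "DUP", "loose")
    assert type_compatible("DUP", "INS", "loose")
    assert not type_compatible("DEL", "INV", "loose")


def test_size_similarity_symmetry(ref):
    rng = np.random.default_rng(0)
    a = make_del(ref, "1", 10_000, 100, rid="a")
    b = make_del(ref, "1", 10_000, 70, rid="b")
    assert size_similarity(a, b) == pytest.approx(0.7)
    assert size_similarity(b, a) == pytest.approx(0.7)
    assert size_similarity(a, a) == 1.0
    _ = rng  # silence unused warning


def test_overlap_uses_length_dependent_extension(ref, config):
    # two 50 bp deletions 350 bp apart: extended by 200 bp each -> overlap
    a = make_del(ref, "1", 10_000, 50, rid="a")
    b = make_del(ref, "1", 10_350, 50, rid="b")
    assert overlap_status(a, b, config)
    # 500 bp apart: extended intervals end at +250 / start at -200 -> no overlap
    c = make_del(ref, "1", 10_500, 50, rid="c")
    assert not overlap_status(a, c, config)
    # a 200 bp deletion gets the 1 kbp extension and reaches back to a
    d = make_del(ref, "1", 11_000, 200, rid="d")
    assert overlap_status(a, d, config)


def test_insertions_get_fixed_overlap_extension(ref, config):
    rng = np.random.default_rng(1)
    big = make_ins(ref, "1", 10_000, rand_seq(rng, 5_000), rid="a")
    # a large insertion still only reaches +/-100 bp, not its length
    near = make_ins(ref, "1", 10_190, rand_seq(rng, 5_000), rid="b")
    far = make_ins(ref, "1", 10_210, rand_seq(rng, 5_000), rid="c")
    assert overlap_status(big, near, config)
    assert not overlap_status(big, far, config)


# ---------------------------------------------------------------------------
# alignment and relief scoring


def test_nw_hand_example(config):
    """Worked relief-factor example: AAAATTTTCCCC vs AAAACCCC aligns with one
    4 bp gap run; M=8, G=4, L=12."""
    s1, s2 = "AAAATTTTCCCC", "AAAACCCC"
    _, a1, a2 = needleman_wunsch(s1, s2)
    stats = alignment_stats(a1, a2, config.gap_run_min)
    assert (stats.matches, stats.relieved_gaps, stats.aln_len) == (8, 4, 12)
    assert relief_score(stats, 0.5) == pytest.approx(10 / 12)
    assert relief_score(stats, 0.0) == pytest.approx(8 / 12)
    assert relief_score(stats, 1.0) == 1.0


def test_nw_matches_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n1, n2 = int(rng.integers(0, 40)), int(rng.integers(0, 40))
        s1, s2 = rand_seq(rng, n1), rand_seq(rng, n2)
        score, a1, a2 = needleman_wunsch(s1, s2)
        oscore, o1, o2 = nw_oracle(s1, s2)
        assert score == oscore
        assert _decode(a1) == o1 and _decode(a2) == o2


def test_nw_respects_custom_scoring():
    s1, s2 = "ACGTACGTAA", "ACGTTACGT"
    for match, mismatch, gap in [(1, -1, -2), (2, -3, -1), (1, -2, -4)]:
        score, a1, a2 = needleman_wunsch(s1, s2, match=match, mismatch=mismatch, gap=gap)
        oscore, o1, o2 = nw_oracle(s1, s2, match, mismatch, gap)
        assert score == oscore and _decode(a1) == o1 and _decode(a2) == o2


def test_relief_stats_match_independent_recount(config):
    rng = np.random.default_rng(5)
    for _ in range(40):
        s1, s2 = rand_seq(rng, int(rng.integers(1, 60))), rand_seq(rng, int(rng.integers(1, 60)))
        _, a1, a2 = needleman_wunsch(s1, s2)
        stats = alignment_stats(a1, a2, config.gap_run_min)
        got = relief_score(stats, config.relief_factor)
        want = relief_score_oracle(_decode(a1), _decode(a2), config.relief_factor,
                                   config.gap_run_min)
        assert got == pytest.approx(want)


def test_short_gap_runs_are_not_relieved(config):
    # gaps in runs shorter than gap_run_min earn no relief credit
    a1 = np.frombuffer(b"AC-GT", dtype=np.uint8).copy()
    a2 = np.frombuffer(b"ACCGT", dtype=np.uint8).copy()
    stats = alignment_stats(a1, a2, config.gap_run_min)
    assert stats.relieved_gaps == 0 and stats.matches == 4
    # but a 3-run is
    b1 = np.frombuffer(b"AC---GT", dtype=np.uint8).copy()
    b2 = np.frombuffer(b"ACCCCGT", dtype=np.uint8).copy()
    stats = alignment_stats(b1, b2, config.gap_run_min)
    assert stats.relieved_gaps == 3


def test_relief_monotone_in_rf():
    rng = np.random.default_rng(9)
    cfgs = [MatchConfig(relief_factor=rf) for rf in (0.0, 0.25, 0.5, 0.75, 1.0)]
    for _ in range(20):
        s1 = rand_seq(rng, int(rng.integers(10, 50)))
        s2 = rand_seq(rng, int(rng.integers(10, 50)))
        scores = [aligned_pair_score(s1, s2, c) for c in cfgs]
        assert scores == sorted(scores)


# ---------------------------------------------------------------------------
# sequence similarity


def test_sequence_similarity_raw_equals_oracle(ref, config):
    rng = np.random.default_rng(13)
    seq = rand_seq(rng, 50)
    a = make_ins(ref, "1", 10_000, seq, rid="a")
    b = make_ins(ref, "1", 10_000, seq[:40] + rand_seq(rng, 10), rid="b")
    # without a reference only the raw variant sequences are compared
    got = sequence_similarity(a, b, None, config)
    want = pair_score_oracle(a.variant_sequence(), b.variant_sequence(), config)
    assert got == pytest.approx(want)


def test_sequence_similarity_context_rescues_shifted_insertion(ref, config):
    """The same inserted sequence reported 30 bp away scores imperfectly raw
    (different anchors) but the shared-context haplotypes are nearly identical."""
    rng = np.random.default_rng(17)
    seq = rand_seq(rng, 80)
    a = make_ins(ref, "1", 30_000, seq, rid="a")
    b = make_ins(ref, "1", 30_030, seq, rid="b")
    raw = pair_score_oracle(a.variant_sequence(), b.variant_sequence(), config)
    with_ctx = sequence_similarity(a, b, ref, config)
    assert with_ctx >= raw
    assert with_ctx >= 0.9


def test_sequence_similarity_is_max_of_raw_and_context(ref, config):
    rng = np.random.default_rng(19)
    seq = rand_seq(rng, 40)
    a = make_ins(ref, "1", 40_000, seq, rid="a")
    b = make_ins(ref, "1", 40_010, seq[:30] + rand_seq(rng, 10), rid="b")
    got = sequence_similarity(a, b, ref, config)
    raw = pair_score_oracle(a.variant_sequence(), b.variant_sequence(), config)
    start = min(a.pos, b.pos)
    stop = max(a.ref_footprint_end, b.ref_footprint_end)
    ctxs = []
    for rec in (a, b):
        ctxs.append(ref.fetch("1", start, rec.pos - 1) + rec.variant_sequence()
                    + ref.fetch("1", rec.ref_footprint_end + 1, stop))
    ctx = pair_score_oracle(ctxs[0], ctxs[1], config)
    assert got == pytest.approx(max(raw, ctx))


def test_sequence_similarity_none_for_symbolic(ref, config):
    a = make_symbolic("1", 50_000, "DUP", 300, rid="a")
    b = make_symbolic("1", 50_020, "DUP", 310, rid="b")
    assert sequence_similarity(a, b, ref, config) is None


def test_rf_zero_is_match_fraction(ref):
    cfg = MatchConfig(relief_factor=0.0)
    rng = np.random.default_rng(23)
    for _ in range(20):
        s1 = rand_seq(rng, int(rng.integers(5, 50)))
        s2 = rand_seq(rng, int(rng.integers(5, 50)))
        _, o1, o2 = nw_oracle(s1, s2)
        matches = sum(1 for x, y in zip(o1, o2) if x == y and x != "-")
        assert aligned_pair_score(s1, s2, cfg) == pytest.approx(matches / len(o1))


# ---------------------------------------------------------------------------
# the combined evaluation


def test_evaluate_pair_accepts_near_identical(ref, config):
    rng = np.random.default_rng(29)
    seq = rand_seq(rng, 200)
    a = make_ins(ref, "1", 60_000, seq, rid="a")
    b = make_ins(ref, "1", 60_015, seq[:190], rid="b")
    ev = evaluate_pair(a, b, ref, config)
    assert ev.type_ok and ev.distance_ok and ev.overlap_ok and ev.size_ok
    assert ev.seq_sim is not None and ev.seq_sim >= config.seq_sim_threshold
    assert ev.all_pass


def test_evaluate_pair_distance_uses_larger_length(ref, config):
    rng = np.random.default_rng(31)
    # 500 bp apart: only allowed because the larger variant exceeds 100 bp
    a = make_del(ref, "1", 70_000, 150, rid="a")
    b = make_del(ref, "1", 70_500, 150, rid="b")
    assert evaluate_pair(a, b, ref, config).distance_ok
    c = make_del(ref, "1", 70_000, 50, rid="c")
    d = make_del(ref, "1", 70_500, 50, rid="d")
    assert not evaluate_pair(c, d, ref, config).distance_ok
    _ = rng


def test_evaluate_pair_skips_alignment_on_cheap_failure(ref, config):
    rng = np.random.default_rng(37)
    a = make_ins(ref, "1", 80_000, rand_seq(rng, 100), rid="a")
    b = make_del(ref, "1", 80_005, 100, rid="b")  # type criterion fails
    ev = evaluate_pair(a, b, ref, config)
    assert not ev.type_ok and not ev.all_pass
    assert ev.seq_sim is None  # alignment was never run
    ev_forced = evaluate_pair(a, b, ref, config, skip_seq_if_failed=False)
    assert ev_forced.seq_sim is not None


def test_evaluate_pair_symbolic_seq_vacuous(ref, config):
    a = make_symbolic("1", 90_000, "INV", 500, rid="a")
    b = make_symbolic("1", 90_030, "INV", 480, rid="b")
    ev = evaluate_pair(a, b, ref, config)
    assert ev.seq_sim is None and ev.seq_ok and ev.all_pass


def test_evaluation_is_immutable(ref, config):
    a = make_symbolic("1", 90_000, "INV", 500, rid="a")
    ev = evaluate_pair(a, a, ref, config)
    with pytest.raises(dataclasses.FrozenInstanceError):
        ev.all_pass = False
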