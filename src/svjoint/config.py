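"""Run configuration: every tunable threshold of the benchmarking method."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

#: Default size-bin edges (bp). Eight bins from "small" (<100 bp) up to the
#: maximum admitted SV size; the first edge tracks ``min_size`` and the last
#: tracks ``max_size``.
DEFAULT_BIN_EDGES: Tuple[int, ...] = (20, 100, 250, 500, 1000, 2500, 5000, 10000, 50000)

_AUTOSOMES = tuple(str(i) for i in range(1, 23))
#: Chromosomes admitted by default: human autosomes plus X and Y, with and
#: without the "chr" prefix. Decoy/patch contigs are excluded.
DEFAULT_CHROMOSOMES: Tuple[str, ...] = (
    _AUTOSOMES + ("X", "Y") + tuple("chr" + c for c in _AUTOSOMES + ("X", "Y"))
)

SUPPORTED_SVTYPES = ("INS", "DEL", "DUP", "INV")


@dataclass
class MatchConfig:
    """All parameters governing SV ingestion, matching and merge validation.

    Attributes
    ----------
    min_size, max_size:
        Admitted SV length range in bp. Calls outside the range are excluded
        at parse time and tallied.
    size_sim_threshold, seq_sim_threshold:
        Pass thresholds for the size- and sequence-similarity criteria.
    size_ratio_band:
        Length-ratio band (query/candidate) used to filter candidates found
        in the expanded search window.
    match_mode:
        ``strict`` requires identical SV types; ``loose`` additionally allows
        INS/DUP matches (callers frequently report duplications as
        insertions).
    relief_factor:
        Weight in [0, 1] partially crediting gap characters that belong to
        long gap runs when scoring an alignment. Softens the penalty for
        alignment-induced gaps between equivalent variant representations.
    gap_run_min:
        Minimal gap-run length (columns) for a run to be credited by the
        relief factor.
    nw_match, nw_mismatch, nw_gap:
        Global-alignment scoring scheme (linear gap penalty).
    fixed_ins_overlap_ext:
        Fixed breakpoint extension (bp) applied to span-less variants (INS)
        for the overlap test.
    small_window, expanded_window:
        Initial and widened candidate-search half-windows (bp).
    large_sv_threshold:
        Above this sequence length (bp) direct global alignment is replaced
        by minimizer-anchored alignment.
    kmer_k, minimizer_w:
        k-mer length and window size of the minimizer sketch.
    bin_edges:
        Size-stratification bin edges (bp).
    cluster_gap:
        Maximal gap (bp) between consecutive same-type calls grouped into
        one supercluster for merge validation.
    max_merge_cardinality:
        Maximal number of adjacent calls combined into one merged candidate.
    chromosomes:
        Admitted chromosome names; ``None`` admits everything.
    threads:
        Upper bound on worker threads; results are independent of its value.
    signal_bam:
        Reserved hook for read-signal-based filtering of merge candidates;
        currently unused.
    """

    min_size: int = 20
    max_size: int = 50_000
    size_sim_threshold: float = 0.7
    seq_sim_threshold: float = 0.7
    size_ratio_band: Tuple[float, float] = (0.7, 1.2)
    match_mode: str = "strict"
    relief_factor: float = 0.5
    gap_run_min: int = 3
    nw_match: int = 1
    nw_mismatch: int = -1
    nw_gap: int = -2
    fixed_ins_overlap_ext: int = 100
    small_window: int = 200
    expanded_window: int = 1_000
    large_sv_threshold: int = 10_000
    kmer_k: int = 15
    minimizer_w: int = 10
    bin_edges: Tuple[int, ...] = DEFAULT_BIN_EDGES
    cluster_gap: int = 1_000
    max_merge_cardinality: int = 6
    chromosomes: Optional[Tuple[str, ...]] = field(default=DEFAULT_CHROMOSOMES)
    threads: int = 1
    signal_bam: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.min_size <= self.max_size):
            raise ValueError("require 0 < min_size <= max_size")
        if not (0.0 <= self.relief_factor <= 1.0):
            raise ValueError("relief_factor must lie in [0, 1]")
        for name in ("size_sim_threshold", "seq_sim_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.size_ratio_band
        if not lo < hi:
            raise ValueError("size_ratio_band low bound must be below high bound")
        if self.match_mode not in ("strict", "loose"):
            raise ValueError("match_mode must be 'strict' or 'loose'")
        if self.gap_run_min < 1:
            raise ValueError("gap_run_min must be >= 1")
        if self.max_merge_cardinality < 2:
            raise ValueError("max_merge_cardinality must be >= 2")
        if list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise ValueError("bin_edges must be strictly increasing")

    def chrom_allowed(self, chrom: str) -> bool:
        return self.chromosomes is None or chrom in self.chromosomes

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_ratio_band"] = list(self.size_ratio_band)
        d["bin_edges"] = list(self.bin_edges)
        d["chromosomes"] = None if self.chromosomes is None else list(self.chromosomes)
        return d
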