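"""Summary metrics, size stratification, deviation statistics and reports.

Recall, precision and F1 use benchmark-side TP counts: Rc = TP/(TP+FN),
Pr = TP/(TP+FP), F1 their harmonic mean. Latent positives are reported as
their own count and excluded from both the precision numerator and
denominator. Per-match deviation is summarised by the signed breakpoint
distance d (query start minus benchmark start) and the span ratio r.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .config import MatchConfig
from .matcher import Classification, MatchResult


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_rates(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    """(recall, precision, f1) as fractions in [0, 1]."""
    rc = _safe_div(tp, tp + fn)
    pr = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * pr * rc, pr + rc)
    return rc, pr, f1


def round_percent(fraction: float, digits: int = 1) -> float:
    """Percentage rounded half-up, as printed in reports (0.51551 -> 51.6)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SizeBinSpec:
    """Ordered bin edges partitioning [min_size, max_size]; the last bin is
    closed on the right."""

    edges: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.edges) < 2 or list(self.edges) != sorted(set(self.edges)):
            raise ValueError("edges must be strictly increasing with >= 2 values")

    @classmethod
    def from_config(cls, config: MatchConfig) -> "SizeBinSpec":
        return cls(tuple(config.bin_edges))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self) -> List[str]:
        out = []
        for i in range(self.n_bins):
            close = "]" if i == self.n_bins - 1 else ")"
            out.append(f"[{self.edges[i]},{self.edges[i + 1]}{close}")
        return out

    def bin_of(self, length: int) -> int:
        """Index of the bin containing ``length`` (out-of-range clamps to the
        nearest bin)."""
        if length >= self.edges[-1]:
            return self.n_bins - 1
        idx = int(np.searchsorted(self.edges, length, side="right")) - 1
        return max(0, idx)


@dataclass
class BenchmarkSummary:
    """Counts and derived metrics for one callset (optionally one size bin)."""

    label: str
    tp: int
    fp: int
    fn: int
    lp: int
    recall: float
    precision: float
    f1: float
    mean_seq_sim: Optional[float]
    frac_d_within_50: Optional[float]
    frac_r_in_band: Optional[float]
    bins: List["BenchmarkSummary"] = field(default_factory=list)
    exclusions: Dict[str, int] = field(default_factory=dict)
    warning: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "lp": self.lp,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "mean_seq_sim": self.mean_seq_sim,
            "frac_d_within_50": self.frac_d_within_50,
            "frac_r_in_band": self.frac_r_in_band,
            "exclusions": dict(sorted(self.exclusions.items())),
        }
        if self.warning:
            d["warning"] = self.warning
        if self.bins:
            d["bins"] = [b.to_dict() for b in self.bins]
        return d


def summary_from_counts(
    tp: int, fp: int, fn: int, lp: int = 0, label: str = "", **extra
) -> BenchmarkSummary:
    rc, pr, f1 = compute_rates(tp, fp, fn)
    return BenchmarkSummary(
        label=label,
        tp=tp,
        fp=fp,
        fn=fn,
        lp=lp,
        recall=rc,
        precision=pr,
        f1=f1,
        mean_seq_sim=extra.get("mean_seq_sim"),
        frac_d_within_50=extra.get("frac_d_within_50"),
        frac_r_in_band=extra.get("frac_r_in_band"),
    )


def summarize(
    classification: Classification,
    bins: Optional[SizeBinSpec] = None,
    config: Optional[MatchConfig] = None,
) -> BenchmarkSummary:
    """Global metrics of a final classification, plus per-bin sub-summaries
    when a bin spec (or config) is given."""
    cls = classification
    tp, fp, fn, lp = (
        len(cls.tp_benchmark),
        len(cls.fp_calls),
        len(cls.fn_benchmark),
        len(cls.lp_calls),
    )
    dev = deviation_stats(cls.tp_matches, config=config)
    summary = summary_from_counts(tp, fp, fn, lp, label=cls.source, **dev)
    summary.exclusions = dict(cls.call_exclusions)
    if cls.n_benchmark == 0:
        summary.warning = "empty benchmark set: recall undefined, reported as 0"
    if bins is None and config is not None:
        bins = SizeBinSpec.from_config(config)
    if bins is not None:
        summary.bins = size_stratify(cls, bins)
    return summary


def size_stratify(classification: Classification, bins: SizeBinSpec) -> List[BenchmarkSummary]:
    """Per-bin summaries: benchmark records (TP/FN) are binned by their own
    length, unmatched and latent calls by theirs; per-bin counts sum to the
    global counts."""
    counts = {
        k: [0] * bins.n_bins for k in ("tp", "fp", "fn", "lp")
    }
    seqsims: List[List[float]] = [[] for _ in range(bins.n_bins)]
    for rec in classification.tp_benchmark:
        counts["tp"][bins.bin_of(rec.length)] += 1
    for rec in classification.fn_benchmark:
        counts["fn"][bins.bin_of(rec.length)] += 1
    for rec in classification.fp_calls:
        counts["fp"][bins.bin_of(rec.length)] += 1
    for rec in classification.lp_calls:
        counts["lp"][bins.bin_of(rec.length)] += 1
    for m in classification.tp_matches:
        if m.seq_sim is not None:
            seqsims[bins.bin_of(m.benchmark.length)].append(m.seq_sim)
    out = []
    for i, lab in enumerate(bins.labels()):
        s = summary_from_counts(
            counts["tp"][i], counts["fp"][i], counts["fn"][i], counts["lp"][i], label=lab
        )
        s.mean_seq_sim = float(np.mean(seqsims[i])) if seqsims[i] else None
        out.append(s)
    return out


def deviation_stats(
    matches: Sequence[MatchResult],
    config: Optional[MatchConfig] = None,
    d_window: int = 50,
) -> dict:
    """Breakpoint-deviation summary of accepted matches: histograms of the
    signed d and of r, the fraction with |d| <= 50 bp and the fraction with r
    inside the size-ratio band."""
    band = config.size_ratio_band if config is not None else (0.7, 1.2)
    if not matches:
        return {
            "mean_seq_sim": None,
            "frac_d_within_50": None,
            "frac_r_in_band": None,
            "d_values": [],
            "r_values": [],
        }
    d = np.array([m.d for m in matches], dtype=np.int64)
    r = np.array([m.r for m in matches], dtype=np.float64)
    sims = [m.seq_sim for m in matches if m.seq_sim is not None]
    return {
        "mean_seq_sim": float(np.mean(sims)) if sims else None,
        "frac_d_within_50": float(np.mean(np.abs(d) <= d_window)),
        "frac_r_in_band": float(np.mean((r >= band[0]) & (r <= band[1]))),
        "d_values": d.tolist(),
        "r_values": r.tolist(),
    }


def tp_overlap(classifications: Sequence[Classification]) -> Dict[Tuple[str, ...], int]:
    """For every combination of callsets, the number of benchmark records that
    are TP in exactly that combination. All classifications must share one
    benchmark set."""
    if not classifications:
        return {}
    fp0 = classifications[0].benchmark_fingerprint
    for c in classifications[1:]:
        if c.benchmark_fingerprint != fp0:
            raise ValueError("classifications do not share one benchmark set")
    membership: Dict[Tuple, Tuple[str, ...]] = {}
    for c in classifications:
        for rec in c.tp_benchmark:
            membership[rec.key] = membership.get(rec.key, ()) + (c.source,)
    combos: Dict[Tuple[str, ...], int] = {}
    for combo in membership.values():
        combos[combo] = combos.get(combo, 0) + 1
    return dict(sorted(combos.items(), key=lambda kv: (-len(kv[0]), kv[0])))


# ---------------------------------------------------------------------------
# report rendering

_TXT_COLUMNS = ("callset", "TP", "FP", "FN", "LP", "Rc", "Pr", "F1", "SeqSim")


def _summary_row(s: BenchmarkSummary) -> List[str]:
    seqsim = "-" if s.mean_seq_sim is None else f"{round_percent(s.mean_seq_sim):.1f}"
    return [
        s.label or "-",
        str(s.tp),
        str(s.fp),
        str(s.fn),
        str(s.lp),
        f"{round_percent(s.recall):.1f}",
        f"{round_percent(s.precision):.1f}",
        f"{round_percent(s.f1):.1f}",
        seqsim,
    ]


def _format_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    widths = [
        max(len(str(header[i])), *(len(r[i]) for r in rows)) if rows else len(str(header[i]))
        for i in range(len(header))
    ]
    def fmt(row):
        return "  ".join(str(v).ljust(w) for v, w in zip(row, widths)).rstrip()
    lines = [fmt(header), fmt(["-" * w for w in widths])]
    lines.extend(fmt(r) for r in rows)
    return "\n".join(lines)


def render_report(
    summaries: Sequence[BenchmarkSummary],
    overlap: Optional[Mapping[Tuple[str, ...], int]],
    config: MatchConfig,
    out_dir: Union[str, Path],
    make_plots: bool = True,
) -> Dict[str, Path]:
    """Write report.txt, report.html, summary.json and upset.tsv (plus PNG
    charts) into ``out_dir``. Output bytes depend only on inputs and config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    rows = [_summary_row(s) for s in summaries]
    txt_parts = ["Benchmarking summary", "", _format_table(_TXT_COLUMNS, rows)]
    for s in summaries:
        if s.bins:
            txt_parts += [
                "",
                f"Size-stratified metrics: {s.label}",
                _format_table(
                    ("bin",) + _TXT_COLUMNS[1:],
                    [[b.label] + _summary_row(b)[1:] for b in s.bins],
                ),
            ]
    if overlap:
        txt_parts += [
            "",
            "Benchmark TP overlap (exact combinations)",
            _format_table(
                ("callsets", "benchmark_TPs"),
                [["+".join(k), str(v)] for k, v in overlap.items()],
            ),
        ]
    paths["txt"] = out_dir / "report.txt"
    paths["txt"].write_text("\n".join(txt_parts) + "\n")

    payload = {
        "callsets": [s.to_dict() for s in summaries],
        "tp_overlap": [
            {"callsets": list(k), "count": v} for k, v in (overlap or {}).items()
        ],
        "config": config.to_dict(),
    }
    paths["json"] = out_dir / "summary.json"
    paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    paths["upset"] = out_dir / "upset.tsv"
    with open(paths["upset"], "w") as fh:
        fh.write("callsets\tcount\n")
        for k, v in (overlap or {}).items():
            fh.write("+".join(k) + f"\t{v}\n")

    plot_files: List[str] = []
    if make_plots:
        plot_files = _render_plots(summaries, overlap, out_dir)

    paths["html"] = out_dir / "report.html"
    paths["html"].write_text(_render_html(summaries, overlap, plot_files))
    return paths


def _render_plots(summaries, overlap, out_dir: Path) -> List[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files: List[str] = []
    if summaries:
        labels = [s.label or "?" for s in summaries]
        fig, ax = plt.subplots(figsize=(max(4, 1.4 * len(labels)), 3.2))
        x = np.arange(len(labels))
        for off, (metric, title) in enumerate(
            (("recall", "Rc"), ("precision", "Pr"), ("f1", "F1"))
        ):
            ax.bar(x + (off - 1) * 0.26, [round_percent(getattr(s, metric)) for s in summaries],
                   width=0.24, label=title)
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=30, ha="right")
        ax.set_ylabel("%")
        ax.legend(frameon=False)
        fig.tight_layout()
        name = "metrics.png"
        fig.savefig(out_dir / name, dpi=100)
        plt.close(fig)
        files.append(name)
    if overlap:
        combos = list(overlap.items())
        fig, axes = plt.subplots(
            2, 1, figsize=(max(4, 0.8 * len(combos)), 4.2), sharex=True,
            gridspec_kw={"height_ratios": [2, 1]},
        )
        xs = np.arange(len(combos))
        axes[0].bar(xs, [v for _, v in combos], color="0.3")
        axes[0].set_ylabel("benchmark TPs")
        all_sets = sorted({s for k, _ in combos for s in k})
        for yi, name in enumerate(all_sets):
            for xi, (k, _) in enumerate(combos):
                filled = name in k
                axes[1].plot(xi, yi, "o", color="0.2" if filled else "0.85", ms=8)
        axes[1].set_yticks(range(len(all_sets)))
        axes[1].set_yticklabels(all_sets)
        axes[1].set_xticks(xs)
        axes[1].set_xticklabels(["+".join(k) for k, _ in combos], rotation=30, ha="right")
        fig.tight_layout()
        name = "upset.png"
        fig.savefig(out_dir / name, dpi=100)
        plt.close(fig)
        files.append(name)
    return files


def _html_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    head = "".join(f"<th>{h}</th>" for h in header)
    body = "\n".join(
        "<tr>" + "".join(f"<td>{v}</td>" for v in r) + "</tr>" for r in rows
    )
    return f"<table>\n<tr>{head}</tr>\n{body}\n</table>"


def _render_html(summaries, overlap, plot_files: List[str]) -> str:
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>SV benchmarking report</title>",
        "<style>body{font-family:sans-serif;margin:2em;}table{border-collapse:collapse;}"
        "td,th{border:1px solid #999;padding:4px 8px;text-align:right;}"
        "th{background:#eee;}td:first-child,th:first-child{text-align:left;}</style>",
        "</head><body>",
        "<h1>SV benchmarking report</h1>",
        "<h2>Summary</h2>",
        _html_table(_TXT_COLUMNS, [_summary_row(s) for s in summaries]),
    ]
    for s in summaries:
        if s.bins:
            parts += [
                f"<h2>Size-stratified metrics: {s.label}</h2>",
                _html_table(
                    ("bin",) + _TXT_COLUMNS[1:],
                    [[b.label] + _summary_row(b)[1:] for b in s.bins],
                ),
            ]
    if overlap:
        parts += [
            "<h2>Benchmark TP overlap</h2>",
            _html_table(
                ("callsets", "benchmark TPs"),
                [["+".join(k), str(v)] for k, v in overlap.items()],
            ),
        ]
    for f in plot_files:
        parts.append(f"<p><img src='{f}' alt='{f}'></p>")
    parts.append("</body></html>")
    return "\n".join(parts) + "\n"
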