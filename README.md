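# svjoint

Structural-variant (SV) benchmarking with local joint validation of split
calls.

`svjoint` scores one or more SV callsets (VCF) against a benchmark truth set
(VCF) over a reference genome (FASTA). Every call is classified as a **true
positive** (TP, it recovers a benchmark variant), **false positive** (FP, no
benchmark counterpart), or — after a second, joint pass — **latent positive**
(LP, a call that alone matches nothing but, merged with adjacent calls,
reconstructs a benchmark variant). Benchmark variants recovered by no call are
**false negatives** (FN). The tool reports recall, precision and F1 overall
and per size bin, breakpoint-deviation statistics, per-class VCFs, and
multi-callset TP-overlap (upset-style) tables and plots.

## Why joint validation

Long-read SV callers frequently report one large insertion or deletion as
several adjacent smaller calls. Single-record matching then counts the event
twice as an error: the fragments become FPs and the benchmark variant an FN.
`svjoint` groups residual FP calls of the same type into breakpoint-proximal
superclusters, builds the merged haplotype of each contiguous subset, and
validates it against each nearby missed benchmark variant. An accepted merge
turns the members into LPs and the benchmark record into a TP, so
representation differences stop inflating both error counts.

## Matching model

Two variants are the same event when five criteria agree:

1. **Type** — identical SVTYPE (`--match-mode loose` additionally accepts
   INS/DUP pairs).
2. **Breakpoint distance** — start positions within the length-dependent
   extension: 200 bp for SVs ≤ 100 bp, 1 kbp above.
3. **Overlap** — the extended spans intersect; insertions, having no physical
   span, get a fixed ±100 bp extension.
4. **Size similarity** — `min(L1, L2) / max(L1, L2) ≥ 0.7`.
5. **Sequence similarity** — a relief-factor score over a global alignment:

   ```
   score = (M + G · RF) / alignment_length
   ```

   where `M` counts matched columns, `G` counts gap characters in runs of at
   least 3 columns (the typical footprint of two representations of one
   event), and the relief factor `RF` (default 0.5) partially credits those
   long-run gaps instead of fully penalising them. The score is the maximum of
   the raw variant-sequence score and a shared-context score computed on
   reference haplotypes with each variant embedded, which absorbs placement
   shifts. Threshold 0.7. Symbolic alleles (`<DUP>`, `<INV>`) pass this
   criterion vacuously.

Candidate search is two-staged: a narrow window scaled to the chromosome
(1e-5 of its length, clamped to [200, 1000] bp), then — for calls ≥ 100 bp
with an empty first window — a 1 kbp window with type and size-ratio
prefilters. Among passing candidates the highest sequence similarity wins, so
two calls can match the two allelic benchmark records at a multi-allelic
site. Each benchmark record is consumed at most once; processing order is
genomic, making results deterministic and independent of thread count.
Variants longer than 10 kbp are compared through a minimizer-anchored
alignment (k = 15, w = 10) that chains colinear unique anchors and aligns only
the gaps between them.

## Usage

```sh
# score two callsets against a benchmark
svjoint bench --benchmark truth.vcf --calls caller_a.vcf --calls caller_b.vcf \
    --ref genome.fasta --out results/

# generate a seeded synthetic bundle (reference, truth, perturbed calls,
# expected labels) for testing
svjoint simulate --out bundle/ --seed 1 --n-sv 50
```

`bench` writes per-callset `tp/fp/fn/lp.vcf` (TP/FN hold benchmark records,
FP/LP call records, with `SVJ_*` INFO annotations), `report.txt`,
`report.html`, `summary.json`, `upset.tsv`, plots and a `manifest.json` with
config echo and input checksums.

## Worked example: rescuing a split insertion

A 147 bp benchmark insertion reported as two adjacent insertions of 49 bp and
98 bp (10 bp apart, carrying its exact subsequences) fails single-record
matching — each part is far too small for the size criterion — so the first
pass yields 2 FP and 1 FN. Joint validation merges the parts (combined length
49 + 98 = 147, size similarity 1.0), aligns the merged haplotype against the
benchmark haplotype, and accepts:

```python
from svjoint import MatchConfig, match_callset, reclassify
from svjoint.fixtures import split_insertion_case

config = MatchConfig()
ref, benchmark, calls = split_insertion_case(seed=1)
first = match_callset(calls, benchmark, ref, config, source="calls")
print(len(first.fp_calls), len(first.fn_benchmark))   # 2 1
final = reclassify(first, ref, config)
merge = final.tp_matches[0]
print(merge.merged_length, sorted(c.record_id for c in final.lp_calls))
# 147 ['call_part1', 'call_part2']
```

The two calls become LPs, the benchmark record a TP, and the merged variant
length is exactly 147 bp.

## Scope

In scope: VCF-level comparison of INS/DEL/DUP/INV on the primary chromosomes,
sizes 20 bp – 50 kbp; allele-aware matching; joint split-call validation;
size-stratified metrics; deviation statistics; multi-callset overlap
reporting; a seeded fixture generator. Out of scope: read-signal (BAM)
re-genotyping, genotype concordance, breakends/translocations, and running
upstream callers. See `docs/methods.md` for the full model, parameter table
and limitations.
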