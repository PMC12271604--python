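# Methods

This document specifies the model implemented by `svjoint`: record handling,
the five matching criteria, candidate search, allele-aware selection, joint
validation of split calls, metrics, the synthetic-fixture generator, and the
numerical choices and limitations behind each.

## 1. Records and filtering

A VCF record is normalised to an `SVRecord` with 1-based inclusive `pos`/`end`
(`end == pos` for insertions, `end = pos + L - 1` for spanned types), a
positive `length`, raw REF/ALT sequences, and a `symbolic` flag for ALTs such
as `<DUP>`. Multi-allelic rows are split into one record per SV allele.

Length inference precedence: `|SVLEN|`, else `END − POS` for spanned types,
else the REF/ALT length difference. Records are excluded (and counted per
reason) when the type is unsupported (only INS/DEL/DUP/INV are scored), the
chromosome is outside the inclusion list (default 1–22, X, Y, with or without
`chr`), no length can be inferred, or the length falls outside
[`min_size`, `max_size`] = [20, 50000] bp.

The sequence a variant contributes to similarity scoring is its ALT column
(insertions, duplications) or its REF column (deletions — the deleted bases).

## 2. The five matching criteria

For a query call `q` and benchmark record `b` (lengths `L_q`, `L_b`):

| # | criterion | rule |
|---|-----------|------|
| 1 | type | same SVTYPE; `loose` mode also accepts {INS, DUP} |
| 2 | distance | `|S_q − S_b| ≤ E(max(L_q, L_b))` with `E(L) = 200` bp for `L ≤ 100`, `1000` bp otherwise |
| 3 | overlap | spans extended by `E(L)` on both sides intersect; insertions use a fixed ±100 bp |
| 4 | size | `min(L_q, L_b)/max(L_q, L_b) ≥ 0.7` |
| 5 | sequence | relief-factor similarity ≥ 0.7 (below); vacuous when either allele is symbolic |

The expensive alignment is only computed when criteria 1–4 already hold.

### Relief-factor sequence similarity

Sequences are globally aligned (Needleman–Wunsch, match +1, mismatch −1,
linear gap −2; deterministic tie-break diagonal → up → left). With `M` matched
columns, `G` gap characters lying in maximal gap runs of ≥ `gap_run_min` = 3
columns (counted in both rows), and alignment length `A`:

```
score = (M + G · RF) / A,   clipped to [0, 1]
```

`RF = 0.5` by default. Long gap runs are the expected footprint when the same
event is represented with different breakpoints, so they are half-credited;
isolated 1–2 column gaps (sequencing noise) are not. At `RF = 0` the score
reduces to the plain match fraction; it is monotone non-decreasing in `RF`.

The reported similarity is the maximum of

* the **raw score** of the two variant sequences, and
* the **shared-context score**: over the window from `min(S_q, S_b)` to the
  downstream-most REF footprint end (for DUP/INV, the downstream-most `end`),
  each variant's sequence is embedded into the reference at its own position
  and the two haplotypes are aligned. This absorbs placement shifts and nearby
  SNVs.

A consequence worth stating: for two deletions whose REF columns faithfully
copy the reference, the two context haplotypes coincide up to breakpoint
placement, so context similarity is near 1 whenever the size criterion holds.
The discriminating criteria for deletion pairs are therefore 1–4 plus the raw
score; this matches the method as defined.

### Large variants

When both sequences exceed `large_sv_threshold` = 10 kbp, direct `O(n·m)`
alignment is replaced by a minimizer-anchored path: 15-mers are hashed
(splitmix64), window-minimum sampled (w = 10), unique hashes shared by both
sequences become anchors, and the longest colinear chain (patience LIS,
trimmed to disjoint k-spans) splits the problem into small inter-anchor
segments that are NW-aligned; anchor spans count as matched columns. A chain
needs ≥ 2 anchors — a single anchor in sequences this long is almost surely a
chance k-mer hit — otherwise the pair falls back to direct alignment when the
DP matrix fits under 2.5·10⁸ cells, and scores 0 beyond that (two unrelated
>15 kbp sequences). On identical inputs the anchored score is exactly 1; on
block-substituted inputs it agrees with direct alignment to ~5·10⁻³.

## 3. Candidate search and allele-aware selection

The benchmark is indexed per chromosome by sorted start position.

* **Stage 1**: candidates with `|pos − q.pos| ≤ w0`,
  `w0 = clamp(chrom_len · 10⁻⁵, 200, 1000)` bp — on a 250 Mbp chromosome
  `w0 = 1000`, on small contigs 200.
* **Stage 2** (only when stage 1 is empty and `L_q ≥ 100`): window widened to
  1 kbp with two prefilters, type compatibility and length ratio
  `L_q/L_b ∈ [0.7, 1.2]`.

All candidates are evaluated against the five criteria. Among passes the
winner has the highest sequence similarity (size similarity when the pair is
symbolic), then smallest `|d|`, then smallest benchmark position — so at a
multi-allelic site two queries match the two allelic records by content, not
proximity. Queries are processed in genomic order and each benchmark record
is consumed at most once: results are deterministic, order-invariant and
independent of `threads` (the setting is an upper bound for embarrassingly
parallel per-chromosome work; the reduction order is fixed).

For each accepted match the signed breakpoint deviation `d = S_q − S_b` and
span ratio `r = span_q / span_b` are recorded.

## 4. Joint validation of split calls (latent positives)

After the first pass:

1. Residual FP calls are grouped per (chromosome, type) by single linkage with
   gap ≤ `cluster_gap` = 1 kbp. Within a cluster, calls whose intervals
   overlap are alternate alleles, not split parts: only the member with the
   best first-pass similarity is kept, the rest return to the FP pool.
   Clusters need ≥ 2 members.
2. Residual FN benchmark records are visited in genomic order. For each,
   every nearby (≤ 1 kbp) same-type cluster is validated: contiguous member
   runs of cardinality 2..`max_merge_cardinality` = 6 are combined in
   breakpoint order. A run is a candidate when its combined length — the sum
   of insertion lengths, or the breakpoint span for deletions — is
   size-similar (≥ 0.7) to the target.
3. For candidates, the merged haplotype (reference over the shared window
   with the run's edits applied) is aligned against the target haplotype with
   the same relief scoring. The best run with score ≥ 0.7 is accepted
   (ties: smaller span, then leftmost).
4. On acceptance the members become LP, the target becomes TP with a
   merge-derived match (`d` and `r` computed from the merged span, and the
   merged length recorded). Each call joins at most one merge.

Invariants, asserted on every run: TP + FN equals the filtered benchmark
size; matched + FP + LP equals the filtered callset size; reclassification
never decreases TP nor increases FP or FN.

## 5. Metrics and reports

With benchmark-side TP/FN and call-side FP (LPs excluded from both sides):

```
recall = TP / (TP + FN)    precision = TP / (TP + FP)    F1 = harmonic mean
```

Percentages are printed at one decimal, rounded half-up (`0.51550 → 51.6`).
Size stratification uses right-open bins over edges
(20, 100, 250, 500, 1000, 2500, 5000, 10000, 50000), the last bin closed;
benchmark records are binned by their own length, calls by theirs, and
per-bin counts sum to the global counts. Deviation reporting includes the
mean sequence similarity of accepted matches, the fraction with
`|d| ≤ 50` bp and the fraction with `r ∈ [0.7, 1.2]`. For multiple callsets
sharing one benchmark, the exact-combination TP overlap is written as a TSV
and drawn as an upset-style chart.

## 6. Synthetic fixture generator

`svjoint.fixtures` produces fully seeded data whose expected labels are known
by construction, not by running the matcher:

* **Reference**: i.i.d. A/C/G/T of requested length, optionally with planted
  tandem-repeat tracts.
* **Truth**: log-uniform sizes in [20, 5000] bp (small SVs dominate), type
  mix 40/40/10/10 for INS/DEL/DUP/INV; INS/DEL sequence-resolved, DUP/INV
  symbolic. Sites are separated by ≥ 2 kbp — twice the expanded search
  window — so no call can interact with a foreign site and every expected
  label is decidable in isolation.
* **Perturbations** per truth record: dropout (expected FN), split into
  k = 2..6 adjacent parts carrying exact subsequences (expected LP members +
  benchmark TP), or in-place noise with breakpoint shift clipped to
  ±min(100, L/2 + 10) bp and size jitter ≤ 15 % (half the criterion
  tolerances, hence expected first-pass TP). Additionally: decoy calls far
  from all sites (expected FP) and injected second alleles of length 2L at
  matched sites (size similarity 0.5 — guaranteed FP).

The generator's scope is intentionally narrow: it validates the classifier's
decision logic at sites engineered to be unambiguous. It does not model read
noise, repeat-mediated ambiguity between neighbouring sites, or genotypes.

## 7. Parameters

| parameter | default | meaning |
|---|---|---|
| `min_size` / `max_size` | 20 / 50000 | length filter (bp) |
| `size_sim_threshold` | 0.7 | criterion 4 |
| `seq_sim_threshold` | 0.7 | criterion 5 and merge validation |
| `relief_factor` | 0.5 | gap-run credit in [0, 1] |
| `gap_run_min` | 3 | minimal relieved gap-run length |
| `nw_match/mismatch/gap` | +1 / −1 / −2 | alignment scoring |
| `small_window` / `expanded_window` | 200 / 1000 | search-window clamp (bp) |
| `fixed_ins_overlap_ext` | 100 | insertion overlap extension (bp) |
| `size_ratio_band` | (0.7, 1.2) | stage-2 prefilter and `r` band |
| `large_sv_threshold` | 10000 | anchored-alignment cutoff (bp) |
| `kmer_k` / `minimizer_w` | 15 / 10 | sketch parameters |
| `cluster_gap` | 1000 | supercluster linkage gap (bp) |
| `max_merge_cardinality` | 6 | largest merged run |
| `bin_edges` | 20..50000 (8 bins) | size stratification |
| `match_mode` | strict | `loose` adds INS/DUP pairing |
| `threads` | 1 | upper bound; results invariant |
| `signal_bam` | None | reserved hook, not implemented |

## 8. Numerical choices

* Alignment runs in a compiled (numba) kernel on uint8 arrays with a full
  uint8 pointer matrix and two rolling int64 score rows; tie-breaking is fixed
  so alignments (not just scores) are reproducible and testable against a
  pure-Python oracle.
* Rounding of printed percentages uses decimal half-up, not binary banker's
  rounding, so printed values match hand arithmetic on published counts.
* All randomness in fixtures flows through one `numpy` `default_rng(seed)`;
  no global seeding.
* Test and acceptance workloads are scaled down from genome scale (hundreds
  of kbp references, tens of variants) so the full suite runs in well under
  a minute on one CPU; the algorithms are size-independent.

## 9. Limitations

* No BAM-level signal inspection: a `signal_bam` hook exists in the
  configuration but is deliberately unimplemented; classification is purely
  VCF/FASTA-based.
* No genotype concordance; GT is carried through but not scored.
* Breakends (BND) and inter-chromosomal events are excluded at parse time.
* Merge validation only combines same-type clusters with sequence-resolved
  members against sequence-resolved targets (INS/DEL in practice); symbolic
  targets are never merge-rescued.
* Context-based similarity saturates for deletion pairs (section 2), so
  deletion matching leans on criteria 1–4 plus the raw sequence score.
* `loose` type mode pairs INS with DUP at the type criterion but the sequence
  criterion still compares the literal ALT sequences; a duplication written
  symbolically matches an insertion only through the non-sequence criteria.
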