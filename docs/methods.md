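# Methods

## Scope and model

The package reproduces, end to end, a desk-side lncRNA biomarker analysis
for renal fibrosis in the UUO rat model: candidate lncRNA identification,
RPKM differential expression in two compartments (renal tissue, urine),
cis-neighbor annotation, Smad3-motif promoter prioritization, tissue–urine
concordance, and 2^−ΔΔCt qPCR quantification. Upstream read processing
(QC, alignment, assembly) is out of scope: inputs are a genome FASTA, a GTF
annotation and transcript-level count tables.

All internal coordinates are 0-based half-open; GTF I/O performs the ±1
conversion at the boundary. The TSS of a multi-isoform gene is the most 5′
transcript start across isoforms (strand-aware), so each gene has a single
promoter and the motif count per gene is well defined.

## Candidate lncRNA filter

A transcript is removed when its **spliced** (exonic) length is ≤ 200 nt —
"more than 200 nt" read strictly, so a 200-nt transcript is removed — or
when *any* coding-potential predictor calls it coding (union removal). The
removal reason records `too_short` (checked first) or the list of flagging
predictors. The filter is monotone: adding a predictor can only shrink the
candidate set.

The four external coding-potential tools are not wrapped or re-implemented;
what matters to the pipeline is the consensus rule, which is exact. Two
built-in predictors provide the score → threshold → is_coding interface:

* **Longest ORF** — longest ATG→in-frame-stop open reading frame over the
  three forward frames (transcripts are stranded), stop codon included;
  coding when > 300 nt. This is the pipeline default: on data where coding
  transcripts carry real ORFs it is a clean, assumption-free separator.
* **Hexamer bias** — mean log ratio of coding vs non-coding in-frame hexamer
  frequencies (frame 0, step 3); coding when > 0. It requires trained
  frequency tables supplied by the caller, so it is available through
  configuration but not enabled by default.

## Differential expression

Expression is RPKM with `N` taken as the column sum of the analyzed matrix
(not an external mapped-read total); the identity Σᵢ rpkmᵢⱼ·Lᵢ = 10⁹ holds
per sample and is asserted in the tests. Fold change is
log₂((m₁ + ε)/(m₂ + ε)) on group-mean RPKM with pseudocount ε = 0.25 RPKM,
which bounds fold changes at zero expression. Significance is a two-sided
Welch t-test on log₂(RPKM + ε); with two groups the stated "two-tailed ANOVA
via t-test" reduces to a t-test, and the unequal-variance form is the robust
default. A transcript is significant when |log₂FC| ≥ 1 (inclusive) *and*
p < 0.05 (strict). Raw p-values are used, matching the single-transcript
validation style of small-n designs; Benjamini–Hochberg adjustment is an
option (`bh_correction`). Degenerate rows (zero variance in both groups) get
p = 1 when the means agree and p = 0 otherwise, so p-values are never NaN.

## Cis neighbors and promoter scan

Cis distance is the gap between gene spans (0 on overlap), boundary
inclusive at 100 kb; gene bodies, not TSSs, anchor the window because the
search is phrased around gene loci. Upstream/downstream is assigned from the
lncRNA's strand. The production path uses an interval tree; the O(n·m)
brute force is retained as the oracle in the tests.

Promoters are the 5 kb immediately upstream of the TSS, clipped (and
flagged) at contig edges, returned in transcription orientation. The scan
counts **all** overlapping exact CAGACA occurrences ("CAGACAGACA" counts 2);
no de-overlap rule exists in the field's description of the motif count and
exhaustive counting is the reproducible choice. The default scans the sense
strand only, mirroring the single literal motif; `both_strands` adds TGTCTG
hits labeled antisense. N never matches. Prioritization is strict:
k = 5 passes, k = 4 fails. The scan is applied to up-regulated candidate
lncRNAs only (the biology is TGF-β *induction*); a flag extends it to all
dysregulated candidates.

## Concordance and qPCR

Biomarker candidates are transcripts significant in both compartments with
equal direction; near-misses are not rescued, and discordant overlaps are
reported with `concordant = false`. qPCR follows the Livak construction with
the **arithmetic mean ΔCt of the Sham group** as calibrator; consequently the
geometric mean of calibrator-group folds is exactly 1 (asserted).
Group-level results report mean ± SD of per-sample folds (bar-plot style)
plus the geometric mean; significance is a Welch t-test on ΔCt, the
statistically natural (log) scale. Urine tables are normalized to the
cel-miR-39 spike-in — mathematically the same ΔΔCt with the spike as
reference; a global shift in spike Ct cancels exactly.

## Synthetic data

The generator emulates the study conditions: 2 conditions × 2 compartments
× 3 replicates; negative-binomial counts with var = μ + αμ², baseline mean
200 and dispersion α = 0.05 (the standard RNA-seq overdispersion model —
nothing in the source design fixes a noise law); planted |log₂FC| = 2 on
20 up + 20 down lncRNAs and 10 + 10 mRNAs; 6 promoters planted with 5–10
CAGACA copies and 14 with 0–4; 25 cis pairs at exact gaps from 100 nt up to
the inclusive 100 kb boundary. Urine counts are an independent draw with
their own DE subset (compartments are separate libraries), planted so the
tissue∩urine intersection yields 5 concordant-up, 2 concordant-down and one
discordant lncRNA.

Design choices that make planted truth *exactly* recoverable:

* Background sequence is i.i.d. uniform ACGT, but every lncRNA promoter is
  rebuilt explicitly: background CAGACA occurrences are disrupted by
  single-base substitutions before the planted copies are written (spaced
  ≥ 16 nt so no overlapping spurious occurrence can survive), making the
  sense-strand scan count equal the planted count exactly.
* lncRNA transcripts are scrubbed of ORFs > 300 nt (mutating ATG starts
  until none remains — the loop terminates because each step removes an A);
  coding transcripts carry a planted 456 nt ORF. The built-in ORF predictor
  therefore separates the classes perfectly.
* lncRNA blocks are separated by > 100 kb from every coding gene except the
  intended cis partner, whose span gap is realized exactly and verified
  after layout.
* Gene totals are 60 lncRNA + 600 coding genes so that, as in real RNA-seq,
  most reads come from non-DE genes; with column-sum library sizes, a
  composition-skewed design would otherwise bias estimated fold changes by
  several tenths of a log₂ unit at desk scale.

One global seed drives a named substream per artifact (genome,
counts-tissue, counts-urine, qPCR per table), so artifacts regenerate
independently and all outputs are byte-identical across runs.

What the generator does **not** model — and what passing tests therefore do
not show about real data: fragment-length effects and transcript degradation
(urine RNA is heavily degraded in reality), GC and length bias, isoform
structure beyond a fixed two-exon geometry, multi-isoform genes, batch
effects, and realistic promoter base composition. Recovery results on this
generator demonstrate correctness of the pipeline's logic, not field
performance of the thresholds.

## Numerical and reporting choices

* qPCR Ct values: Ct = base − log₂(abundance) + N(0, 0.15²) cycles; the
  0.15-cycle SD is a typical technical-replicate spread for SYBR assays.
* Welch p-values are computed vectorized per matrix row;
  zero-variance fix-ups are applied after the vectorized pass.
* Problem sizes in tests (e.g., 2,000-transcript null matrices, 200-seed
  qPCR replications, 100 randomized cis instances) were chosen as the
  smallest sizes at which the checked moments stabilize well inside their
  asserted bounds.
* The run report asserts the pipeline's structural invariants on every run:
  prioritized ⊆ scanned up-regulated candidates, concordant ⊆ jointly
  significant, and every cis pair anchored at a dysregulated lncRNA.

## Known limitations

* The consensus filter's real-world behavior depends entirely on the
  predictors plugged in; the built-ins are deliberately simple stand-ins.
* RPKM with column-sum library sizes is composition-sensitive; strongly
  asymmetric DE shifts estimated fold changes (documented above, and the
  reason the generator keeps DE genes a small fraction of the library).
* Raw (unadjusted) p-values at n = 3/group have limited power and no FDR
  control; the BH option exists but changes the semantics of the cutoffs.
* Promoters overlapping an upstream neighbor are not truncated; the window
  is defined purely by distance.
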