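# lncfibro

Discovery and prioritization of long non-coding RNAs (lncRNAs) in renal
fibrosis, modeled on the unilateral ureteral obstruction (UUO) rat study
design: RNA-seq of renal tissue and urine from UUO vs sham-operated animals,
3 replicates per group.

The package implements the full desk-side analysis chain:

1. **Candidate lncRNA filtering** — a transcript is a candidate lncRNA when
   its spliced length exceeds 200 nt and *no* coding-potential predictor
   flags it as coding (union-removal consensus). The external tools this rule
   is normally fed with (CPC, CNCI, Pfam Scan, PhyloCSF) are replaced by a
   pluggable predictor interface with two built-ins: longest-ORF length and
   in-frame hexamer usage bias.
2. **Differential expression** — expression is quantified as RPKM,
   `rpkm = c · 10⁹ / (N · L)` with `c` the read count, `N` the library size
   and `L` the exonic length; a transcript is called differentially
   expressed between UUO and Sham when |log₂FC| ≥ 1 and a two-sided Welch
   t-test on log₂(RPKM + 0.25) gives p < 0.05.
3. **Cis-neighbor search** — protein-coding genes whose spans lie within
   ±100 kb (inclusive) of a dysregulated lncRNA locus, with exact gap
   distances and strand-aware upstream/downstream relations.
4. **Smad3 promoter scoring** — the 5 kb upstream of each up-regulated
   lncRNA's TSS is scanned for the Smad-binding element CAGACA (all
   overlapping occurrences, sense strand by default); genes with **more than
   4** motifs are prioritized as TGF-β/Smad3 pathway candidates.
5. **Urinary biomarker concordance** — lncRNAs significantly changed in the
   *same direction* in both renal tissue and urine.
6. **qPCR quantification** — the Livak 2^−ΔΔCt method
   (ΔΔCt = ΔCt − mean ΔCt of the Sham calibrator group), with an endogenous
   reference (GAPDH/18S) for tissue and the cel-miR-39 spike-in for urine.

Because the original sequencing data is not needed to test any of this
logic, the package ships a synthetic-data generator that emits a toy genome,
annotation, negative-binomial count matrices and Ct tables with *planted*
truth — known DE genes, motif counts, cis-pair distances and qPCR folds —
so every stage is checked by exact parameter recovery.

## Worked example

Run the numbered analysis drivers from the repository root:

```sh
python analysis/01_simulate.py              # emit results/data (seed 1)
python analysis/02_filter_lncrna.py
python analysis/03_differential_expression.py
python analysis/04_cis_neighbors.py
python analysis/05_promoter_smad_scan.py
python analysis/06_concordance_qpcr.py
```

which prints, among other lines:

```
660 transcripts in; 60 lncRNA candidates
tissue: lncRNA 20 up / 20 down; mRNA 10 up / 10 down (of 660 transcripts)
40 dysregulated lncRNA genes searched (+/-100 kb): 25 coding neighbors
20 up-regulated lncRNA promoters scanned for CAGACA
6 genes with k > 4 selected as TGF-beta/Smad3 candidates
8 lncRNAs dysregulated in both compartments; 5 concordant up, 2 concordant down
qPCR (tissue):
  LNC0001: fold = 3.91 +/- 0.11, p = 0.0047
```

Reading this: of 660 simulated transcripts the consensus filter keeps
exactly the 60 generated lncRNAs; the DE caller recovers all 40 planted DE
lncRNAs with the right direction; every dysregulated lncRNA's planted coding
neighbor is found at its exact distance; exactly the 6 promoters planted
with 5–10 CAGACA copies pass the >4-motif rule; 7 lncRNAs change
concordantly in tissue and urine (5 up, 2 down); and the simulated 4-fold
qPCR induction of LNC0001 is recovered as 3.91 ± 0.11.

The same pipeline runs as a single command over a YAML config:

```sh
lncfibro simulate --seed 1 --out data/
lncfibro run --config pipeline.yaml
```

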