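# natlnc

Annotation, classification and co-expression analysis of long non-coding RNAs
(lncRNAs) from an assembled transcriptome, built around natural antisense
transcripts (NATs).

Plant genomes harbour thousands of lncRNAs whose relationship to neighbouring
protein-coding genes carries functional information: NAT-lncRNAs transcribed
antisense to a coding gene are often concordantly expressed with — and can be
required for — their cognate sense gene, the paradigm case being a
cold-induced antisense transcript that activates a MADS-box floral repressor
during vernalization in *Arabidopsis*. `natlnc` packages the desk-side half of
that kind of study as a tested, reusable pipeline:

1. **Identification** — a four-stage filter cascade over an assembled
   transcriptome (GTF with assembler class codes):
   keep class codes `u`/`x`/`i`; drop transcripts with length < 150 nt or
   FPKM_max < 1 (FPKM_max = maximum FPKM over all samples); drop transcripts
   with protein-coding potential — a BLASTX hit with e-value < 10⁻⁴,
   alignment ≥ 40 aa, identity ≥ 35% and coverage of query or subject ≥ 35%,
   *or* a positive signed coding-potential score; drop transcripts
   sense-overlapping coding genes (intron-contained sense transcripts are
   kept for classification as incRNAs).
2. **Classification** — each surviving lncRNA is assigned exactly one class
   by strand-aware interval geometry, in priority order: `NAT_OVERLAPPING`
   (≥ 1 bp antisense span overlap), `INCRNA` (inside a sense intron),
   `NAT_DIVERGENT` (head-to-head, 5′–5′ gap ≤ window), `NAT_CONVERGENT`
   (tail-to-tail), `LINCRNA` (otherwise). A brute-force classifier with the
   same contract serves as a testing oracle.
3. **Expression statistics** — fraction-enrichment (poly(A)+/−,
   nuclear/cytosolic) and differential calls with a Welch t-test on
   log2(FPKM+1) gated at *P* < 0.05 and fold-change ≥ 2, and k-means heatmap
   row ordering on row-fractional densities.
4. **Co-expression** — neighbour pairs in seven categories (CCO/CCD/CCC for
   adjacent coding–coding pairs, NCO/NCD/NCC for NAT–gene pairs, LC for
   lincRNA–nearest-gene pairs), Pearson correlation (p.c.c.) across all
   samples, one-tailed Mann–Whitney *U* comparisons between categories
   (exact enumeration when both n ≤ 8), and the concordant set
   (NCO pairs with p.c.c. > 0.6).
5. **sRNA QC** — reads-per-million quantification, secondary-siRNA detection
   outside an amiRNA target window, and amiRNA\* specificity checks
   (5′ uridine; base pairing with mismatch positions at the cleavage-critical
   window).

A synthetic-data module generates all inputs with planted ground truth
(geometry classes, pair correlations, fraction enrichments, coding decoys,
sRNA signals), so every stage is testable without any download.

## Input formats

* annotation: GTF (1-based inclusive; converted internally to 0-based
  half-open), transcript lines may carry `class_code`, `biotype`,
  `lnc_class` attributes;
* expression: TSV FPKM matrix (rows = features) + TSV sample sheet with
  columns `sample_id`, `condition`, `timepoint`, `fraction`, `replicate`;
* homology hits: BLAST tabular `outfmt 6` extended with two trailing
  coverage columns `qcovs` and `scovs` (percent of query / subject covered
  by the alignment); for BLASTX the `length` column is in amino acids;
* sequences: FASTA (transcript-stranded);
* sRNA counts: BED-like TSV (`chrom start end strand count`, 0-based
  half-open) preceded by a `#total_mapped=<int>` header line.

## Worked example

The package ships a hand-checkable six-transcript example in which each
cascade stage removes exactly one transcript:

```bash
python - <<'EOF'
from natlnc.examples import write_toy_bundle
from natlnc.pipeline import run_pipeline
run_pipeline(write_toy_bundle("demo"))
EOF
cat demo/results/report.txt
```

prints

```
natlnc 0.1.0 pipeline report

Filter cascade:
  class_code: in 6, removed 1, out 5
  length_abundance: in 5, removed 1, out 4
  coding_potential: in 4, removed 1, out 3
  sense_overlap: in 3, removed 1, out 2

LncRNA classes: INCRNA=0, LINCRNA=1, NAT_CONVERGENT=0, NAT_DIVERGENT=0, NAT_OVERLAPPING=1

Fraction enrichment (polyA_plus vs polyA_minus): 0 enriched in polyA_plus, 0 in polyA_minus, 2 ns
Differential (cond2 vs cond1): 2 lncRNAs

Neighbour pairs: 2 scored, 0 excluded; 1 concordant NCO pairs (pcc > 0.6)
```

Reading the numbers: of the six assembled transcripts, one is a known
transcript (class code `=`), one is below 150 nt, one has a qualifying
protein-homology hit and a positive coding-potential score, and one overlaps
a coding gene in the sense direction — leaving one antisense-overlapping
NAT-lncRNA and one lincRNA. The NAT and its sense gene share a correlated
expression profile (p.c.c. > 0.6), so the NCO pair lands in the concordant
set; the lincRNA's profile anti-tracks its nearest gene.

The same works at scale with synthetic data:

```bash
natlnc make-fixtures --out bundle --seed 7
natlnc run-all --config bundle/config.yaml
```

`bundle/truth.tsv` holds the planted labels; with the default configuration
(120 coding genes, 10 lncRNAs per class, 10 decoys, 9 conditions × 3
replicates) the pipeline recovers every planted class, removes every decoy,
calls all 30 planted poly(A)+-enriched lncRNAs, and separates the NCO pair
category from coding–coding pairs (median p.c.c. ≈ 0.75 vs ≈ 0).

Subcommands `identify`, `classify`, `diffexp`, `enrich`, `pairs` and
`srna-qc` expose the stages individually; `natlnc --help` lists the flags.

## Scope notes

Read alignment and transcript assembly are upstream (the pipeline consumes a
finished GTF). The coding-potential calculator is pluggable: any callable
`(transcript, sequence) -> float` with the sign contract *positive ⇒ coding*
can replace the built-in ORF-feature scorer. Differential calls use a
replicate Welch t-test, not a count-based model; the *P* and fold-change
gates are the contract. See `docs/methods.md` for the statistical model,
parameter defaults and limitations.
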