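# Methods

## Coordinate conventions and geometry

All internal coordinates are 0-based half-open on both strands; GTF I/O is
the single conversion point, so a round trip through `read_annotation` /
`write_annotation` preserves every printed start/end integer. Gene extent is
the union span of a gene's isoforms; introns are the gaps between consecutive
exons of each isoform.

The classifier assigns exactly one class per lncRNA by priority:
antisense span overlap (≥ 1 bp) → sense intron containment → head-to-head
(divergent) within the pairing window → tail-to-tail (convergent) within the
window → lincRNA. Divergent means the two 5′ ends flank the gap; convergent
means the two 3′ ends do. Partner ties break by largest overlap (overlap
class) or smallest gap, then lexicographically smallest gene id. The indexed
classifier (sorted endpoints + prefix-max-end overlap scan) is checked
against an exhaustive-scan implementation of the same contract; both are in
`nat_classify`.

Two deliberate geometry choices:

* **Pairing window.** Divergent/convergent pairing needs a distance cutoff
  for the taxonomy to be decidable; the default `window_bp = 1000` is the
  conventional promoter-proximal scale and is configurable everywhere.
* **Sense-intronic transcripts.** The identification cascade removes
  sense-overlapping transcripts, but a transcript fully contained within a
  single intron of the overlapped gene is exempt by default
  (`exempt_intron_contained=True`): such transcripts are exactly the
  sense-intronic (incRNA) class the classifier must be able to see, and
  removing them at the cascade would make that class unreachable. Sense
  overlaps that touch exons are always removed. With the exemption disabled
  the cascade removes all sense span overlaps. The final taxonomy can keep
  incRNA as its own class, fold it into lincRNA, or drop it
  (`--fold-incrna-into`).

A useful symmetry for testing: classification is invariant under
reverse-complementing the chromosome (mirroring all coordinates and flipping
all strands). Note a bare strand flip is *not* a symmetry — it exchanges
head-to-head and tail-to-tail geometry.

## Identification cascade

Stages run in order, each recording per-transcript removal reasons and
conserving counts (n_in = n_removed + n_out):

1. class codes: keep `u`, `x`, `i`; unknown codes are preserved verbatim and
   treated as "not retained". Known-ncRNA catalogs are consumed as
   `biotype known_ncRNA` tags in the input and removed here.
2. length/abundance: remove length < 150 nt or FPKM_max < 1 (both strict, as
   printed); transcripts absent from the expression matrix have undefined
   FPKM_max and are removed with their own reason code.
3. coding potential: a transcript is coding if a homology hit passes all of
   e-value < 10⁻⁴ (strict) and alignment ≥ 40 aa, identity ≥ 35%,
   max(query coverage, subject coverage) ≥ 35% (inclusive, as printed), OR
   its signed coding-potential score is > 0 (strict). "Coverage in either
   query or subject" is read literally as the maximum of the two.
4. sense overlap, as above.

### Coding-potential scorer

The scorer is pluggable (`(transcript, seq) -> float`, positive ⇒ coding);
external per-transcript scores can be supplied through any callable. The
built-in default is a monotone sum of three centred ORF features:

    score = (orf_max_aa/100 − 1) + (min(coverage,1)/0.5 − 1) + 0.5·(integrity − 1)

with `coverage` the fraction of the transcript covered by the longest ORF and
`integrity` 1 when that ORF ends at a stop codon. Any transcript with
orf_max_aa < 100 and coverage < 0.5 is guaranteed a negative score; a
full-length ORF of a few hundred aa is solidly positive. The scorer honours
only the sign contract — its magnitude is not comparable to any external
tool's score. ORFs are scanned in the three forward frames of the
already-stranded transcript sequence (ATG to first in-frame stop; `N` never
completes a start or stop codon; an ATG with no downstream stop yields an
open-ended ORF flagged as lacking integrity).

## Expression statistics

Differential and fraction-enrichment calls use a Welch two-sample t-test on
log2(FPKM + eps), eps = 1 by default, with the gates *P* < alpha (default
0.05, raw p-values; Benjamini–Hochberg available behind `--fdr`) and
fold-change ≥ 2 computed on pseudo-count-stabilised FPKM means,
(mean_a+eps)/(mean_b+eps). This is a deliberate, documented stand-in for
count-based differential machinery: the calls are threshold-driven and only
the gates are part of the contract. Degenerate inputs: both groups constant
with equal means → p = 1; constant with different means → p = 0.

Small-sample behaviour worth knowing: with 3 replicates per group the
Welch–Satterthwaite approximation is conservative (true type-I error ≈ 0.033
at nominal 0.05 under normality; verified by direct simulation). Calibration
is therefore demonstrated at 6 replicates per group, where the test attains
its nominal level; at 3 replicates the test errs only on the conservative
side, which costs a little power and never inflates false positives.

Heatmap ordering scales each row to fractional density (row / row max),
clusters with k-means (k-means++ init, 10 restarts, best inertia, mandatory
seed), and orders rows by cluster profile peak position, then each feature's
own peak position, then feature id. k defaults to 6 and is configurable; the
ordering is fully deterministic given (data, k, seed).

## Neighbour pairs and co-expression

Pair categories: NCO/NCD/NCC from the classifier's partners; LC pairs each
lincRNA with its closest gene by span-gap distance (0 if touching, ties to
the smaller gene id); CC* pairs are immediately adjacent coding genes typed
by the same geometry rules. Each unordered pair is counted once.

Correlation is Pearson's r between the lncRNA's FPKM vector and the
gene-level FPKM vector of the partner (gene level = sum of isoform FPKM),
across all samples by default with an optional sample filter. Pairs with a
member below FPKM_max < 1, missing from the matrix, or with a zero-variance
vector are excluded with a reason rather than scored — an undefined
correlation set to 0 would distort category distributions.

Category comparisons use a one-tailed Mann–Whitney U test (H1: category A
stochastically greater). When both categories have ≤ 8 members the p-value is
computed by exhaustive enumeration of all C(n+m, n) rank assignments with
ties counted ½; otherwise the normal approximation with tie correction and
continuity correction is used. Boxplot summaries report median, quartiles and
1.5×IQR whiskers. The concordant set is the NCO pairs with p.c.c. strictly
greater than 0.6.

## sRNA checks

Region abundance is reads per million mapped reads (RPM = count / total ×
10⁶), summing counts of regions overlapping the query by ≥ 1 bp
(strand-agnostic by default). Secondary-siRNA detection asks whether reads
on a knocked-down transcript fall outside the amiRNA target site ± 50 bp
flank at ≥ 1 RPM — a presence/absence criterion, not a phasing score; the
thresholds are configurable. The amiRNA\* check finds the best ungapped
antisense match of the passenger strand in the sense mRNA (Watson–Crick
pairs; G:U wobble only behind `--allow-gu`), reports mismatch positions
1-based from the star 5′ end, flags mismatches in the cleavage-critical
window (default positions 9–11 — the standard cleavage-site region, a
configurable stand-in since no canonical definition exists), and whether the
star begins with a 5′ uridine (which would favour effector loading).
T and U are interchangeable in all sequence inputs.

## Synthetic data

The generator lays planted loci sequentially along one synthetic chromosome.
Coding genes are two-exon models (600 + 700 nt exons, 300 nt intron; incRNA
hosts carry a 1400 nt intron); planted lncRNAs are single-exon, 300–800 nt.
Guard spacing makes every geometric decision unambiguous: divergent and
convergent gaps are drawn from [margin, window − margin] (margin 200 bp by
default), lincRNAs and all between-block distances stay ≥ window + margin
from every gene, so no planted feature lies within the margin of a window
boundary and no accidental neighbour relationships arise. Planted
coding–coding pairs in the three CC geometries give the co-expression
analysis a background distribution.

Expression is log-normal: per-feature baseline log2-FPKM ~ Uniform(3, 7),
per-condition effects with s.d. 1.5 log2 units drawn bivariate-normal within
each planted pair (correlation rho_nco = 0.8 for overlapping-NAT pairs,
rho_other = 0 for all other planted pairs), plus replicate noise
(s.d. 0.2 log2 units); FPKM = 2^value, hence strictly positive. The two
fraction sample groups share one extra condition effect and differ by the
planted enrichment offset (default 3 log2 units, i.e. 8-fold). Because FPKM
is log-normal, Pearson correlation on the raw FPKM scale is attenuated
relative to the planted log-scale rho (≈ 0.75 observed for rho = 0.8 at
these variances); the generator's own recovery check is therefore stated on
the log2 scale, while the pipeline correlates raw FPKM vectors as the
analysis defines.

Sequences are ATG-free for planted lncRNAs (so their ORF count is exactly
zero) and carry a single long ORF covering ~90% of the transcript for coding
genes and decoys; homology decoys additionally receive one hit passing all
criteria, and about half of the true lncRNAs receive a near-miss hit failing
exactly one criterion. sRNA counts place all reads in a 21-nt target window
(negative case) or spread a configured fraction across the transcript body
(positive case).

What the generator does **not** emulate: splice-isoform diversity (at most
two exons), overdispersed count noise, mapping and assembly artifacts,
genome-wide gene-density variation, and any dependence structure beyond one
planted correlation per pair. Passing recovery tests therefore demonstrates
the correctness of the geometry, the filters and the statistics under the
stated model, not robustness to real-data noise sources upstream of the
pipeline's inputs.

## Problem sizes used in validation

The default validation genome has 120 coding genes, 10 lncRNAs per class, 10
decoys, 10 coding–coding pairs per geometry, and 9 conditions × 3 replicates
plus the two fraction groups. Calibration and power checks use 2000 features;
classifier–oracle agreement uses 1000 random transcripts per seed across
three seeds; co-expression separation uses 50 pairs per category. These sizes
give the binomial and rank statistics comfortable resolution while keeping
the whole suite fast on a single CPU.

## Known limitations

* Gene-level geometry uses union spans; isoform-level class disagreements are
  resolved only by the documented priority order.
* The built-in coding-potential scorer sees only ORF structure; it will pass
  a non-coding transcript that happens to contain a long spurious ORF, and
  external evidence (homology) is the intended complement.
* Welch-on-log2 calls are not a substitute for count-based models when raw
  counts are available.
* The Mann–Whitney exact path enumerates C(n+m, n) assignments and is
  intentionally capped at n, m ≤ 8.
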