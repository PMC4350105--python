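# Methods

## Data model and coordinate conventions

All genomic coordinates are 0-based half-open (BED convention); GTF-lite
1-based starts are decremented on read and never appear internally. A bin
track is a dense per-chromosome vector of non-negative intensities on a
fixed `bin_width` grid (default 100 bp); absent bedGraph records are zero.
A promoter is the TSS ± `flank` window (default 2 kb) anchored at the
stranded 5′ end of the locus — the genomic start on `+`, the genomic end on
`-`; pri-miRNA loci follow the same rule. Unstranded genes are treated as
`+` and logged. Promoters running past coordinate 0 are clamped and
flagged rather than dropped, keeping the gene universe stable. CGI shores
are the `shore_width` flanks (default 2 kb) abutting each CGI with no gap;
shore laterality is stored in genome orientation (left = 5′) and reoriented
by gene strand at classification time.

Biotype classification of ncRNAs against coding gene bodies is
location-only (strand-blind): zero body overlap is intergenic, full
containment is intragenic (host = the largest containing gene, ties broken
lexicographically), anything else is overlapping. Strand-blindness is the
more inclusive reading when the relation of nested transcription to host
strand is not constrained.

## Differential methylation

Normalization is linear: each track is scaled by (mean cohort total)/(its
total), after which all totals are equal. Per bin, the tumor and normal
per-sample values are compared with a two-sided Wilcoxon rank-sum test.
Cohorts with n + m ≤ 12 use exact enumeration of all C(n+m, n) assignments
of the (mid)ranks, with the two-sided p as twice the smaller tail, capped
at 1 — the same convention as scipy's exact Mann–Whitney. Larger cohorts
use the normal approximation with midranks, the tie-corrected variance and
a 0.5 continuity correction; columns whose rank variance is zero get p = 1.
The realistic cohort regime (tens of samples) therefore always runs the
approximation; the exact branch exists for correctness at test scale.

Fold change is computed on pseudocounted group means,
(mean_T + c)/(mean_N + c) with c = 0.5 normalized units, which avoids
infinite ratios at empty bins without affecting large counts. Bins whose
group means both fall below a coverage floor (`min_mean`, default 1.0) are
excluded from testing *and* from the BH family: capture leaves CpG-poor
bins systematically empty, and adjusting over never-covered bins only
dilutes power. BH runs genome-wide over the tested bins (not
per-chromosome). A bin is called when fold ≥ 2 (hyper) or ≤ 1/2 (hypo)
*and* adjusted p < 0.01; means (not medians) are used for the fold.

DMR merging is a strict connected-components pass on the bin grid: runs of
adjacent called bins of one direction, where any intervening grid bin —
uncalled or opposite-direction — breaks the run. Singleton DMRs are
allowed. Consequently total DMR coverage always equals called bins ×
bin width.

## Promoter calls and the five patterns

A gene is called in a direction iff some DMR of that direction overlaps its
promoter by ≥ 50% of the DMR's length (inclusive — "at least 50%" is read
inclusively). Genes called in both directions by distinct DMRs are
reported twice, flagged ambiguous, and excluded from single-direction
summaries. The identical rule applied to CGI bodies and to each shore
separately yields differential CGIs/shores.

Pattern assignment follows a fixed precedence that makes the five classes
exhaustive and mutually exclusive:

1. no promoter CGI → pattern 5 (CGI-less);
2. DMR–CGI overlap > 50% of *either* region (the larger of the two
   single-denominator fractions, strict inequality) → pattern 1
   (CGI-confined);
3. DMR strictly 5′ of every promoter CGI (zero bp CGI overlap) and
   touching the 5′ shore → pattern 2; strictly 3′ likewise → pattern 3;
4. otherwise → pattern 4 (shore-straddling / sub-half CGI overlap).

Note the asymmetry: the promoter-call rule is inclusive at 50%, the
CGI-confined rule is strict ("greater than 50%"). Shore laterality for
patterns 2/3 follows the gene strand; unstranded genes default to genome
left = 5′ (logged). For promoters with several CGIs, "strictly 5′/3′"
must hold against every CGI. When several supporting DMRs imply different
patterns, the DMR with the largest promoter overlap decides; exact ties
take the lowest pattern number and are flagged. The precedence order and
tie-break are our choices; they are the simplest deterministic resolution
of otherwise overlapping definitions.

TSS profiles divide each promoter into 10-bp windows in stranded
orientation (column 0 = 2 kb upstream); a cell is 1 iff the window
intersects ≥ 1 DMR of the chosen direction, and column means give the
average aberrant-methylation frequency curve. Host–ncRNA concordance
classes intragenic pairs by promoter overlap (max of the two
single-denominator fractions, split at 50%) and counts direction matches.
Region-set enrichment uses a two-sided Fisher exact test on the 2×2
called × promoter-touches-region table, with a Haldane 0.5 correction on
the odds ratio when any cell is zero.

## Expression integration and panels

lncRNA expression uses a small cell-line FPKM table (one control, two tumor
lines): per tumor line the pseudocounted ratio against the control mean
(ε = 0.1 FPKM) is labeled up (> 2), down (< 1/2) or none, and a gene is a
candidate only when every tumor line agrees. miRNA expression uses the
cohort RPM matrix: a two-sided two-sample t-test on log2(RPM + 1) —
log-transformed for variance stabilization of count-derived values — with
BH across miRNAs at 5%. Candidates are the opposing-direction
intersection: hyper + down = silencing, hypo + up = activating; concordant
genes are dropped and counted.

Histone concordance sums each mark's density over the promoter and labels
a gene changed when the pseudocounted tumor/control ratio is ≥ 2 (or
≤ 1/2, boundary inclusive) in every tumor line.

Panel scoring Z-transforms each feature across samples (sample SD, ddof 1;
zero-variance features dropped with a warning), flips the sign of features
whose cancer-associated direction is negative so that higher always means
more tumor-like, and takes the per-sample *mean* over features — the mean
rather than the sum keeps scores comparable across panel sizes. Because of
the sign flip, mixed hyper/hypo panels have a monotone ROC;
single-direction panels are the special case with all signs equal. AUC is
computed from the ROC curve and equals the Mann–Whitney
pair-ordering probability with ties worth 1/2. Whether methylation or
expression levels feed the panel is the caller's choice; both are accepted
and reported separately.

## Functional similarity

Pairwise gene similarity is the Jaccard index of annotation-term sets;
group similarity is the symmetric best-match average (each gene's maximum
similarity to the other group, averaged over both directions, with
self-pairing excluded in self-comparisons); the cross-group score is
normalized as 2·S(A,B)/(S(A,A)+S(B,B)). These are deliberately simple,
documented surrogates — the similarity system itself is an open design
choice, and an information-content measure over an ontology DAG is a
natural extension point, not implemented. Term enrichment is a one-sided
Fisher exact test per term with BH across terms; terms annotating no
universe gene are skipped.

## The synthetic cohort generator

The generator defines the conditions every guarantee is stated under.
Defaults: 2 chromosomes × 2 Mb on a 100-bp grid; 100 coding genes, 80
lncRNAs, 20 pri-miRNAs laid out in 20-kb slots (intragenic and overlapping
ncRNAs co-located with coding hosts to realize a 50/30/20
intergenic/intragenic/overlapping mix); a TSS-centered 800-bp CGI in 60%
of promoters; 20 tumor vs 10 normal samples; negative-binomial counts with
baseline mean 100 reads/bin and dispersion k = 10 (variance m + m²/k) —
counts from capture cohorts are overdispersed, so Poisson was rejected;
CGI bins get a 3× baseline (capture enriches CpG-dense DNA, applied once
where CGIs overlap); per-sample library factors are log-uniform on
[0.8, 1.25].

Spikes multiply (hyper) or divide (hypo) the tumor-group mean by the fold
change (default 4) over a pattern-specific stranded TSS-relative window:
the CGI itself for pattern 1, a mid-shore block for 2/3, a CGI-edge
straddling block for 4, and a TSS-centered block for CGI-less pattern 5.
Windows are placed so every pattern-defining fraction clears its 50%
threshold by a wide margin — recovery should fail on statistics, never on
knife-edge geometry — and every spike lies inside its target promoter.
Spike targets are restricted to promoters whose CGI content is exactly
their own layout (no contamination from a neighbour's CGI), keeping truth
labels unambiguous. Expression coupling sets tumor expression to
control/4 (silencing) or control×4 (activating) before log-normal noise
(log2 SD 0.25); histone tracks move the active mark (H3K4me3) and the
repressive mark (H3K27me3) by 3× in opposite senses at coupled promoters.
Everything is deterministic given the config seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: mappability/GC/fragment-size artifacts,
copy-number confounding, spatial autocorrelation of methylation outside
spikes, tumor heterogeneity and purity, and batch structure. Results on
real cohorts depend on all of these.

## Problem sizes, tolerances and degenerate inputs

The test suite and the acceptance script run cohorts at the default 2 × 2
Mb / 30-sample design (tens of seeds) and a 400-kb / 24-sample design for
end-to-end determinism; these sizes were chosen so the full analysis of
one cohort takes on the order of a second while keeping per-bin power
comfortably above the call threshold (a fold-4 spike at baseline 100 gives
rank-sum p ≈ 1e-5 at 20 vs 10, surviving genome-wide BH at 0.01 with
dozens of truly spiked bins). Statistical recovery targets (≥ 90% of
spiked bases, ≤ 10% false called bases, null called fraction within the BH
level plus 3 SE, candidate precision/recall ≥ 0.9, permutation AUC in
[0.4, 0.6]) are aggregated across seeds; numeric primitives are checked
against brute-force oracles to 1e-9. Small-genome layouts in the
acceptance script search successive derived seeds until the spike table
fits the generated CGI layout, deterministically per input seed.

Degenerate inputs are rejected loudly rather than coerced: empty intervals
in overlap arithmetic, off-grid or negative bedGraph records, duplicate
gene ids, missing expression cells, zero-total samples in normalization,
single-group cohorts, zero-variance panels, one-class ROC labels, and
zero intra-class similarity in normalization all raise typed errors. BED
scores are −log10(min adjusted p) capped at 300 to avoid infinities at
p = 0.

## Known limitations

No smoothing or HMM segmentation (a single uncalled bin splits a DMR — the
strict reading of gap-free merging); no covariate adjustment or paired
designs; transcript-level isoform promoters are out of scope (one promoter
per gene); no cross-validation or feature selection for panels (features
are defined by the candidate rule, not learned); heat-map rendering is
limited to matrix export.
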