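# Methods

## Scope and model

The package implements the downstream half of an A-to-I editome study
of early human embryos: it starts from per-sample candidate variant
tables (chromosome, 1-based position, ref, alt, AC, AN) and ends at the
statistics relating recurrent edits, microRNA binding sites (MBSs) and
maternal mRNA clearance. Read processing, alignment and variant calling
are upstream of this artifact; their read-level thresholds (mean base
quality ≥ 25, mapping quality ≥ 20, PCR duplicates removed) are recorded
as provenance metadata in `FilterConfig` but not applied here.

Coordinates are 0-based half-open internally (BED arithmetic) and
1-based in every user-facing position. The editing level AF is always
recomputed as AC/AN; AF fields in input files are ignored so there is a
single source of truth.

## Editome identification

Candidate calls pass through four stages:

1. **Known-variant exclusion.** Any call whose position appears in a
   supplied genomic-variant set is dropped. This is the step that drives
   the per-sample DNA–RNA concordance to zero on cohorts with planted
   SNP contaminants.
2. **Strand-aware classification.** The substitution is expressed on the
   transcript strand using the gene model at the site. Sites overlapping
   genes on both strands, and intergenic sites, are strand-unknown; for
   them an A>G and its reverse complement T>C collapse into one
   strand-ambiguous class, which is counted in the A>G proportion QC
   metric alongside strand-definite A>G. Only these two classes continue.
3. **Per-call filters** (defaults from the validation settings of the
   adapted pipeline): coverage AN ≥ 2 and level AF ≥ 0.1 for Alu edits;
   non-Alu edits additionally need AC ≥ 2 edit-supporting reads.
   Rejection reasons are reported (`low_coverage`, `low_level`,
   `few_mismatch_reads`) and acceptance is monotone in AC at fixed AN.
4. **Cohort support.** Alu sites count once detected in one sample;
   non-Alu sites need at least two normal samples — or at least two
   abnormal samples — of the same stage. Normal and abnormal
   observations are never pooled.

"Detected in a sample" throughout means the call passed the per-call
filters in that sample, not merely that the position was covered.

## REEs, targeted genes, persistence, loss

An REE of a stage is an accepted edit observed in ≥ `ree_fraction`
(default 0.5) of the stage's normal samples. The denominator is all
normal samples of the stage regardless of per-site coverage; an optional
covered-denominator mode is deliberately not the default because
coverage-blindness is a known property of the definition (sites can
drop out for lack of reads, which the loss scan must keep in mind when
interpreting complete losses).

A gene is REE-targeted when the union of its REEs is observed in
≥ `gene_fraction` (default 0.8) of the stage's samples — the union is
taken within each sample, so two REEs each below threshold can jointly
qualify a gene.

Stage flows classify each source-stage REE at the next stage as
`remained_REE`, `detected_not_REE`, or `not_detected`; the three counts
sum to the source set size by construction.

The loss scan examines 12 (stage, condition) groups — GV/MII oocytes
from elder mothers, and androgenetic (AG) / parthenogenetic (PG)
zygotes, 2-cell, 4-cell, 8-cell embryos and morulae. With the default
`max_detection_fraction = 0`, a stage's REE is reported for a group only
when detected in none of that group's samples. The "nearly lost"
variant is exposed by raising `max_detection_fraction`; no default is
claimed for it because the criterion is not pinned by the source
analyses.

Editing–expression correlation defaults to Spearman rank correlation
(robust to AF and FPKM scale; the choice is configurable since the
source analyses do not state the estimator). Pairs with fewer than
three joint observations or constant inputs are reported undefined with
a reason rather than silently dropped.

## MBS prediction and the five-way cascade

Site types follow the canonical seed-match taxonomy, with only exact
Watson–Crick pairs (wobble pairs excluded): 6mer — reverse complement
of seed positions 2–7; 7mer-m8 — of positions 2–8; 7mer-A1 — 6mer plus
an A opposite miRNA position 1 (the 3′ end of the site); 8mer — both.
Each seed-core match yields exactly one site, the longest type at that
position, so nested types are not double-counted.

Two stand-in predictors sit behind one interface: the seed scanner
(family-level) and a seed-anchored local aligner over the full mature
sequence (Biopython `PairwiseAligner`; match 2, mismatch −1, gap open
−8, extend −2, minimum score 24 ≈ twelve net matched bases beyond the
anchor). Alignment predictions are collapsed to family level on the
4-property key (family, target UTR, site type, start/end) and the two
predictors are intersected on the same key. The set logic — collapsing,
intersection, classification — is the substantive computation; the
predictors are deliberately simple and replaceable.

For an edit on a (gene, family) pair, per transcript we compare the
pre- and post-edit site-key sets and count `introduced` (post-only) and
`removed` (pre-only) sites. The comparison is restricted to sites whose
span intersects the edit's ±7 nt neighborhood — every window a single
substitution can alter — which equals the whole-transcript multiset
difference for window-local predictors (property-tested); an
unrestricted `whole_transcript` mode exists for sensitivity analysis.
Strict "site contains the edit" filtering was rejected because an edit
at a site's m8 or A1 position shifts the site type and span, and strict
containment would miscount that shift as a pure gain or loss when the
site count is actually unchanged.

The cascade then runs in order: `no_overlaps` (the edit falls in no
pre-existing site and introduces none), `site_unchanged` (every
transcript has introduced = removed), `gain` (no transcript loses, at
least one gains), `lost` (mirror image), `mixed` (some gain, some
lose). The categories are exhaustive and mutually exclusive, fuzzed
over count vectors and checked against a brute-force window-scan oracle
on random triples.

## Clearance statistics

Maternal genes have median FPKM > 2 (strict) in GV or MII oocytes over
normal samples; a maternal gene is a clearance target ("decay at
8-cell") when min(median GV, median MII) > 2 × median 8-cell (strict).

The chi-square test of MBS-gaining frequency uses the disjoint REE vs
non-REE partition of MBS-overlapping edits — a valid 2×2 independence
test — rather than the "REE vs all" contrast, which is reported only
descriptively; Σ(O−E)²/E without continuity correction by default.
Stages with a zero margin are skipped with a reason, and p values are
BH-adjusted across the tested stages.

"Paired Wilcoxon rank-sum" is implemented as the one-sample signed-rank
test on differences (the standard behavior of paired mode in common
statistics environments; a paired rank-sum test does not otherwise
exist). Zero differences are dropped by default (`wilcox`), with
Pratt's method available. Exact p for n ≤ 25 without ties, normal
approximation with tie correction otherwise. The Hodges–Lehmann
pseudomedian is the median of Walsh averages; the one-sided lower bound
uses the exact signed-rank quantile for n ≤ 25 (subset-sum counting)
and the normal approximation above. The unpaired test is Mann–Whitney
with the analogous estimate (median of pairwise differences) and bound;
`y=None` degenerates to a signed-rank comparison against a 0 baseline.
The per-(gene, sample) statistic for the enrichment comparison is the
raw count of MBS-gaining edits observed in that sample on that gene;
normalization by UTR length is possible but not claimed as a default
since the source analyses leave it unstated.

BH adjustment is the step-up procedure (via statsmodels), validated to
preserve ranking and never decrease under re-adjustment.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: stages with
12 normal samples each (plus 4 samples per abnormal group), 60
single-exon protein-coding genes (5′-UTR 60 nt, CDS 300 nt, 3′-UTR
240 nt) with alternating strands, an Alu mask over the middle half of
half the 3′-UTRs, 300 recurrent edits with per-stage detection
probability 0.9 and geometric stage-window persistence (0.5 per
extension, matching the observed ~50% stage-to-stage persistence), 500
sporadic noise edits at 0.2, 50 homozygous-like SNP contaminants
(AF ~ U(0.9, 1)), 40 non-A>G noise variants so the A>G proportion is
exercised below 1, dropout sets of 10 AG + 10 PG + 4 elder-mother
sites, and 8 miRNA families. AN is a shifted negative binomial
(minimum 2, mean ≈ 12) and AC ~ Binomial(AN, AF) with AF ~ Beta(8, 3),
mimicking low-depth single-cell profiles; sampled pairs are redrawn
until they pass the per-call filters for the site's repeat context,
since the design probabilities describe *detection*. Edited-strand
context is biased as ADAR prefers (G at −1 with probability 0.05, at
+1 with 0.6).

**Truth labels are enforced by construction.** Per-stage observation
counts are truncated binomials: planted REEs are conditioned to reach
the recurrence threshold in their stages, noise edits to stay below it,
dropout sites never appear in their designated group, and every other
REE gets at least one detection per abnormal group of its stages.
Without this conditioning, exact recovery would be a matter of luck —
with 500 noise edits over 5 stages, the unconditioned probability of at
least one noise edit reaching 6/12 samples is near one. The truncation
is mild (it shifts detection frequencies by at most a few percent,
verified by a frequency test at n = 50) and it is what makes the
closed-loop tests sharp: precision/recall against the manifest is
exactly 1, not approximately 1.

MBS-gaining edits are planted by writing a family's 8mer target into a
3′-UTR with one G reverted to A and placing the edit there; the
placement is verified at generation time with the package's own
classifier (gain for the designated family, no overlaps for all
others) and re-tried elsewhere on failure. Planted windows keep 20 nt
of clearance from every other edit so later plantings cannot disturb a
verified neighborhood. Gains are biased onto clearance-target genes
(75%), which is the structure the enrichment statistics detect.

Expression profiles are log-normal (σ = 0.25) around stage medians:
clearance targets decay 4-fold from oocyte to 8-cell, other maternal
genes stay flat above the maternal threshold, non-maternal genes stay
below it; genes whose sampled noise breaks their planted label are
redrawn. A lightweight replicate generator
(`generate_clearance_replicate`) produces only the expression matrix
and per-pair gain counts (Poisson baseline 0.3, excess 0.6 on targets;
excess 0 under the null) so that power and null-calibration studies run
hundreds of replicates in seconds.

Everything is a pure function of (design, seed): same seed, byte-
identical output files.

## What the synthetic data does and does not show

The generator reproduces the *logical* structure of a real cohort —
stage-grouped recurrence, SNP contamination, condition-specific
dropout, seed-match gains on clearance targets, maternal decay — but
not its noise sources: no multi-mapping artifacts, no hyper-edited
clusters, no coverage-driven dropout correlated with expression, no
splice isoform complexity (single-exon genes), and detection is
conditionally independent across samples. Passing the closed-loop tests
therefore demonstrates that the pipeline's logic is correct and its
thresholds behave as specified, not that its sensitivity or false
discovery rate on real embryonic RNA-seq matches any published figure;
headline counts from the source cohorts (hundreds of thousands of
sites, thousands of REEs) are functions of 2,071 real samples and are
not reproducible at this scale.

## Problem sizes

Default test and acceptance runs use cohorts of 60 genes and 5–7 stages
(≈ 14,000–17,000 calls), 1,000 random triples for the MBS oracle
comparison, and 50–500 replicates for the enrichment power and null
calibration; the full suite completes in well under a minute on one
CPU. These sizes give exact recovery checks and stable rate estimates
(binomial SE ≈ 0.01 at 500 replicates) while staying desk-scale.

## Known limitations

- The aligner stand-in scores only seed-anchored candidates; it cannot
  propose seedless (compensatory 3′-pairing) sites.
- Recoding annotation assumes in-frame CDS blocks and skips transcripts
  whose CDS length is not a multiple of three.
- The Hodges–Lehmann one-sided bounds use the achieved-level quantile
  (exact small-sample, normal otherwise) without interpolation, so the
  nominal 95% level is conservative for tiny n.
- Multi-species conservation filtering of miRNA families is out of
  scope; the family table is a direct input.
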