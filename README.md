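# editome

Analysis of adenosine-to-inosine (A-to-I) RNA editing in early human
embryonic development, from per-sample candidate variant tables to the
statistics linking recurrent edits with maternal mRNA clearance.

A-to-I editing, catalysed by the ADAR enzymes on double-stranded RNA,
reads out as an A>G mismatch in RNA-seq. In bulk and single-cell
embryonic transcriptomes a subset of edits recurs reliably within a
developmental stage; this package identifies those **Recurrent Embryonic
Edits (REEs)** and asks how they interact with the microRNA machinery
that clears maternal transcripts during the oocyte-to-embryo transition.

The pipeline covers:

- **Editome identification** — exclusion of known genomic variants,
  transcript-strand A>G classification, per-call coverage/level filters
  (Alu edits: coverage ≥ 2 and editing level AF = AC/AN ≥ 0.1; non-Alu
  edits additionally ≥ 2 edit-supporting reads), and cohort support rules
  (Alu sites: ≥ 1 sample; non-Alu sites: ≥ 2 normal — or ≥ 2 abnormal —
  samples of the same stage, never pooled), plus QC metrics (A>G
  proportion, Alu ratio, DNA–RNA concordance, ADAR motif context).
- **REE analysis** — per stage, an accepted edit is an REE when observed
  in ≥ 50% of the stage's normal samples; a gene is REE-targeted when
  ≥ 1 of its REEs is seen in ≥ 80% of samples. Stage-transition flows
  (remained REE / detected but not REE / not detected), editing–expression
  rank correlation, and a 12-group scan for REEs completely lost in
  androgenetic (AG), parthenogenetic (PG) or elder-mother samples.
- **Region annotation** — per-transcript classes reduced by the priority
  CDS > 5′-UTR > 3′-UTR > non-coding exonic > intronic > intergenic, and
  codon-level recoding effects.
- **MicroRNA binding sites (MBS)** — canonical seed-match site types
  (8mer, 7mer-m8, 7mer-A1, 6mer; exact Watson–Crick only), a seed scanner
  and a seed-anchored mature-sequence aligner intersected at miRNA-family
  level on the (family, UTR, site type, coordinates) key, and a five-way
  classification of each edit's per-(gene, family) effect:
  no_overlaps / site_unchanged / gain / lost / mixed.
- **Clearance statistics** — maternal genes (median FPKM > 2 in GV or
  MII oocytes), clearance targets ("decay at 8-cell": the smaller oocyte
  median is more than twice the 8-cell median), chi-square independence
  tests of MBS-gaining frequency, one-tailed paired signed-rank and
  unpaired rank-sum tests with Hodges–Lehmann estimates, and
  Benjamini–Hochberg adjustment.
- **Synthetic cohorts** — a deterministic generator
  (genome, gene models, Alu mask, miRNA families, per-sample VCFs,
  FPKM matrix) with a ground-truth manifest, so that every pipeline stage
  is testable end to end without external data.

## Worked example

```python
from editome import CohortDesign, simulate_cohort, identify_editome, detect_rees
from editome.ree import stage_flow

design = CohortDesign(seed=1, stages=("oocyte_GV", "oocyte_MII",
                                      "zygote", "2cell", "4cell"))
sim = simulate_cohort(design)
result = identify_editome(
    sim.calls, sim.sample_meta, sim.reference.alu_mask,
    snp_sets=[sim.manifest.snp_positions],
    gene_models=sim.reference.gene_models,
)
print("filter counts:", result.counts)
per_sample = result.accepted_per_sample()
rees = {s: detect_rees(per_sample, sim.sample_meta, s) for s in design.stages}
print("REEs per stage:", {s: len(r) for s, r in rees.items()})
flow = stage_flow(rees["zygote"], rees["2cell"], per_sample, sim.sample_meta)
print("zygote->2cell:", flow.remained_ree, flow.detected_not_ree, flow.not_detected)
```

prints

```
filter counts: {'input': 13904, 'after_snp_exclusion': 10193, 'a2g_candidates': 10139, 'after_site_filters': 10139, 'accepted_sites': 733}
REEs per stage: {'oocyte_GV': 65, 'oocyte_MII': 79, 'zygote': 103, '2cell': 96, '4cell': 130}
zygote->2cell: 44 56 3
```

The cohort of 13,904 candidate calls loses the planted genomic-SNP
contaminants to the known-variant filter, keeps only A>G changes on the
transcript strand, and condenses to 733 accepted sites. Each stage
yields the planted recurrent edits (REE counts reflect overlapping
stage windows), and of the 103 zygote REEs, 44 remain REEs at the
2-cell stage, 56 are still detected but below the 50% threshold, and
only 3 vanish — recurrent edits fade gradually rather than disappearing,
which is the pattern the persistence analysis quantifies.

The same workflow is available from the shell:

```bash
editome simulate --seed 1 --outdir sim/
editome filter --calls sim/calls/*.vcf --meta sim/meta.tsv \
    --alu sim/alu.bed --snps sim/snps.tsv --gtf sim/model.gtf --out sites.tsv
editome ree --calls sim/calls/*.vcf --meta sim/meta.tsv \
    --alu sim/alu.bed --snps sim/snps.tsv --gtf sim/model.gtf --out ree.tsv
```

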