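"""Synthetic cohorts with a ground-truth manifest.

The generator emulates what a stage-structured embryonic RNA-seq cohort
provides to the pipeline: a small genome with single-exon protein-coding
genes, an Alu mask over a subset of 3'-UTRs, per-sample A>G variant
tables with AC/AN sampled at single-cell-like depth, genomic-SNP
contaminants, condition-specific dropout of recurrent edits, edits
engineered to gain microRNA binding sites preferentially on maternal
clearance targets, and maternal-decay FPKM profiles.

Ground-truth labels are enforced by construction: a planted recurrent
edit is re-sampled until it clears the recurrence threshold in its
stages, a noise edit until it stays below it, a dropout site never
appears in its designated abnormal group, and every other recurrent edit
is guaranteed at least one detection in each abnormal group of its
stages.  Detection frequencies therefore match the design probabilities
only up to this (mild) truncation, which is what makes closed-loop
recovery tests exact.  Everything is a pure function of the design and
its seed.
"""

from __future__ import annotations

import json
import math
import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    DEFAULT_STAGES,
    EditCall,
    Gene,
    GeneModelSet,
    GenomicIntervalSet,
    SampleMeta,
    Transcript,
    write_edit_calls_vcf,
    write_interval_mask,
    write_sample_meta,
)
from .mbs import MiRNAFamily, mbs_delta_for_edit, write_family_table
from .ree import DEFAULT_GROUP_SPECS

__all__ = [
    "CohortDesign",
    "GroundTruthManifest",
    "Reference",
    "SimulatedCohort",
    "generate_reference",
    "generate_families",
    "generate_cohort",
    "generate_expression",
    "generate_clearance_replicate",
    "simulate_cohort",
    "write_cohort",
]

Site = tuple[str, int]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CohortDesign:
    """Study conditions for one synthetic cohort.

    Defaults mirror the analysis assumptions: recurrent edits detected in
    90% of their stage's samples against a 50% recurrence threshold,
    sporadic noise edits at 20%, homozygous-like SNP contaminants, ten
    androgenetic plus ten parthenogenetic dropout sites, and a 4-fold
    maternal decay from oocyte to 8-cell on clearance targets.
    """

    seed: int = 0
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_normal_per_stage: int = 12
    n_abnormal_per_group: int = 4
    # reference geometry (single-exon genes: 5'UTR | CDS | 3'UTR)
    n_genes: int = 60
    utr5_length: int = 60
    cds_length: int = 300
    utr3_length: int = 240
    intergenic_gap: int = 150
    alu_utr_fraction: float = 0.5
    # planted edits
    n_ree: int = 300
    ree_detection_prob: float = 0.9
    ree_persist_prob: float = 0.5
    ree_fraction: float = 0.5
    n_noise: int = 500
    noise_detection_prob: float = 0.2
    n_non_a2g_noise: int = 40
    non_a2g_detection_prob: float = 0.1
    n_snp: int = 50
    snp_presence_prob: float = 0.8
    dropout: Mapping[str, int] = field(
        default_factory=lambda: {"AG": 10, "PG": 10, "elder_mother": 4}
    )
    # AC/AN sampling (low-depth single-cell-like profiles)
    af_alpha: float = 8.0
    af_beta: float = 3.0
    an_negbin_r: float = 3.0
    an_mean_extra: float = 10.0
    an_min: int = 2
    # ADAR-motif context bias on the edited strand
    context_g_minus1: float = 0.05
    context_g_plus1: float = 0.6
    # miRNA families and planted MBS gains
    n_families: int = 8
    matures_per_family_max: int = 3
    mature_length: int = 21
    mbs_gain_fraction: float = 0.3
    clearance_gain_bias: float = 0.75
    # expression / clearance
    maternal_fraction: float = 0.6
    clearance_fraction: float = 0.5
    maternal_decay_fold: float = 4.0
    expr_sigma: float = 0.25
    mbs_gain_baseline: float = 0.3
    mbs_gain_excess: float = 0.6

    def __post_init__(self) -> None:
        probs = (
            self.ree_detection_prob, self.noise_detection_prob,
            self.snp_presence_prob, self.ree_persist_prob,
            self.alu_utr_fraction, self.mbs_gain_fraction,
            self.clearance_gain_bias, self.maternal_fraction,
            self.clearance_fraction, self.non_a2g_detection_prob,
            self.context_g_minus1, self.context_g_plus1,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all design probabilities must lie in [0, 1]")
        if self.utr3_length < 8:
            raise ValueError("3'-UTR shorter than 8 cannot host binding sites")

    def abnormal_groups(self) -> list[tuple[str, str]]:
        return [(s, c) for s, c in DEFAULT_GROUP_SPECS if s in self.stages]


@dataclass
class GroundTruthManifest:
    """Everything needed to score recovery without re-simulation."""

    ree_sites_by_stage: dict[str, set[Site]]
    noise_sites: set[Site]
    non_a2g_sites: set[Site]
    snp_positions: set[Site]
    dropout: dict[tuple[str, str], set[Site]]
    site_gene: dict[Site, str]
    site_utr3_pos: dict[Site, int]
    mbs_gain: dict[Site, str]          # site -> family engineered to gain
    clearance_targets: set[str]
    maternal_others: set[str]
    non_maternal: set[str]
    context_params: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        def site_key(s: Site) -> str:
            return f"{s[0]}:{s[1]}"

        payload = {
            "ree_sites_by_stage": {
                st: sorted(map(site_key, v))
                for st, v in self.ree_sites_by_stage.items()
            },
            "noise_sites": sorted(map(site_key, self.noise_sites)),
            "non_a2g_sites": sorted(map(site_key, self.non_a2g_sites)),
            "snp_positions": sorted(map(site_key, self.snp_positions)),
            "dropout": {
                f"{st}|{c}": sorted(map(site_key, v))
                for (st, c), v in self.dropout.items()
            },
            "site_gene": {site_key(s): g for s, g in sorted(self.site_gene.items())},
            "site_utr3_pos": {site_key(s): p for s, p in sorted(self.site_utr3_pos.items())},
            "mbs_gain": {site_key(s): f for s, f in sorted(self.mbs_gain.items())},
            "clearance_targets": sorted(self.clearance_targets),
            "maternal_others": sorted(self.maternal_others),
            "non_maternal": sorted(self.non_maternal),
            "context_params": self.context_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @property
    def all_ree_sites(self) -> set[Site]:
        out: set[Site] = set()
        for v in self.ree_sites_by_stage.values():
            out |= v
        return out


@dataclass
class Reference:
    chrom: str
    genome: dict[str, list[str]]      # mutable during edit planting
    gene_models: GeneModelSet
    alu_mask: GenomicIntervalSet
    gene_layout: dict[str, dict]      # gene_id -> strand/utr3 interval etc.

    def sequence(self, chrom: str) -> str:
        return "".join(self.genome[chrom])

    def transcript_base(self, gene_id: str, utr3_offset: int) -> str:
        """Base at a 0-based 3'-UTR offset, transcript orientation."""
        lay = self.gene_layout[gene_id]
        s, e = lay["utr3"]
        if lay["strand"] == "+":
            return self.genome[self.chrom][s + utr3_offset]
        return _COMP[self.genome[self.chrom][e - 1 - utr3_offset]]

    def set_transcript_base(self, gene_id: str, utr3_offset: int, base: str) -> None:
        lay = self.gene_layout[gene_id]
        s, e = lay["utr3"]
        if lay["strand"] == "+":
            self.genome[self.chrom][s + utr3_offset] = base
        else:
            self.genome[self.chrom][e - 1 - utr3_offset] = _COMP[base]

    def utr3_offset_to_genomic(self, gene_id: str, utr3_offset: int) -> int:
        """1-based genomic position of a 0-based 3'-UTR offset."""
        lay = self.gene_layout[gene_id]
        s, e = lay["utr3"]
        return (s + utr3_offset + 1) if lay["strand"] == "+" else (e - utr3_offset)

    def utr3_sequence(self, gene_id: str) -> str:
        lay = self.gene_layout[gene_id]
        s, e = lay["utr3"]
        seq = "".join(self.genome[self.chrom][s:e])
        if lay["strand"] == "-":
            seq = "".join(_COMP[b] for b in reversed(seq))
        return seq


@dataclass
class SimulatedCohort:
    design: CohortDesign
    reference: Reference
    families: list[MiRNAFamily]
    calls: list[EditCall]
    sample_meta: dict[str, SampleMeta]
    expression: pd.DataFrame
    manifest: GroundTruthManifest


# ---------------------------------------------------------------------------
# Reference


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + a stop codon."""
    if length % 3:
        raise ValueError("cds_length must be a multiple of 3")
    codons = ["ATG"]
    bases = "ACGT"
    for _ in range(length // 3 - 2):
        while True:
            c = "".join(rng.choice(list(bases), 3))
            if c not in _STOPS:
                codons.append(c)
                break
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def generate_reference(design: CohortDesign, rng: np.random.Generator | None = None) -> Reference:
    """Genome, gene models and Alu mask for one cohort.

    Single-exon genes laid out left to right with alternating strands;
    each gene has an extractable 3'-UTR.  The Alu mask covers the middle
    half of the 3'-UTR for a design-controlled fraction of genes.
    """
    rng = rng or np.random.default_rng(design.seed)
    chrom = "chr1"
    gene_len = design.utr5_length + design.cds_length + design.utr3_length
    gap = design.intergenic_gap
    total = gap + design.n_genes * (gene_len + gap)
    genome = list("".join(rng.choice(list("ACGT"), total)))

    genes: list[Gene] = []
    layout: dict[str, dict] = {}
    alu = GenomicIntervalSet("alu")
    is_alu_gene = rng.random(design.n_genes) < design.alu_utr_fraction
    for i in range(design.n_genes):
        gid = f"G{i:04d}"
        strand = "+" if i % 2 == 0 else "-"
        start = gap + i * (gene_len + gap)
        end = start + gene_len
        if strand == "+":
            utr5 = (start, start + design.utr5_length)
            cds = (utr5[1], utr5[1] + design.cds_length)
            utr3 = (cds[1], end)
        else:
            utr3 = (start, start + design.utr3_length)
            cds = (utr3[1], utr3[1] + design.cds_length)
            utr5 = (cds[1], end)
        cds_seq = _random_cds(rng, design.cds_length)
        if strand == "-":
            cds_seq = "".join(_COMP[b] for b in reversed(cds_seq))
        genome[cds[0]:cds[1]] = list(cds_seq)
        tx = Transcript(
            f"{gid}.t1", gid, chrom, strand,
            exons=[(start, end)], cds=[cds],
            utr5=[utr5], utr3=[utr3],
        )
        genes.append(Gene(gid, gid, chrom, strand, [tx]))
        layout[gid] = {"strand": strand, "span": (start, end),
                       "utr5": utr5, "cds": cds, "utr3": utr3}
        if is_alu_gene[i]:
            quarter = design.utr3_length // 4
            alu.add(chrom, utr3[0] + quarter, utr3[1] - quarter)
    return Reference(chrom, {chrom: genome}, GeneModelSet(genes), alu, layout)


# ---------------------------------------------------------------------------
# Families


def generate_families(design: CohortDesign, rng: np.random.Generator | None = None) -> list[MiRNAFamily]:
    """miRNA families with unique seeds, 1-3 mature members each.

    Every seed contains at least one C in positions 2-7 so the 8mer
    target sequence carries a G, which is what lets an A>G edit create a
    site.
    """
    rng = rng or np.random.default_rng(design.seed + 1)
    seeds: set[str] = set()
    fams: list[MiRNAFamily] = []
    while len(fams) < design.n_families:
        seed = "".join(rng.choice(list("ACGT"), 7))
        if "C" not in seed[:6] or seed in seeds:
            continue  # duplicate or unusable seed: draw again
        seeds.add(seed)
        n_mat = int(rng.integers(1, design.matures_per_family_max + 1))
        matures = []
        for _ in range(n_mat):
            first = rng.choice(list("ACGT"))
            tail = "".join(rng.choice(list("ACGT"), design.mature_length - 8))
            matures.append(first + seed + tail)
        fams.append(MiRNAFamily(f"miR-F{len(fams):02d}", seed, tuple(matures)))
    return fams


# ---------------------------------------------------------------------------
# Cohort


def _sample_meta(design: CohortDesign) -> dict[str, SampleMeta]:
    meta: dict[str, SampleMeta] = {}
    for stage in design.stages:
        for i in range(design.n_normal_per_stage):
            sid = f"{stage}_N{i:02d}"
            meta[sid] = SampleMeta(sid, stage, "normal")
    for stage, cond in design.abnormal_groups():
        for i in range(design.n_abnormal_per_group):
            sid = f"{stage}_{cond}{i:02d}"
            meta[sid] = SampleMeta(sid, stage, cond)
    return meta


def _sample_acan(
    rng: np.random.Generator, design: CohortDesign, is_alu: bool
) -> tuple[int, int]:
    """AC/AN for one detected observation; resampled until the pair
    passes the per-call filters for its repeat context."""
    p = design.an_negbin_r / (design.an_negbin_r + design.an_mean_extra)
    min_ac = 1 if is_alu else 2
    while True:
        an = design.an_min + int(rng.negative_binomial(design.an_negbin_r, p))
        af = rng.beta(design.af_alpha, design.af_beta)
        ac = int(rng.binomial(an, af))
        if ac >= min_ac and ac / an >= 0.1:
            return ac, an


def _truncated_binomial_subset(
    rng: np.random.Generator, items: list[str], p: float,
    min_count: int | None, max_count: int | None,
) -> list[str]:
    """Bernoulli subset of ``items`` conditioned on a count window."""
    for _ in range(10_000):
        mask = rng.random(len(items)) < p
        k = int(mask.sum())
        if min_count is not None and k < min_count:
            continue
        if max_count is not None and k > max_count:
            continue
        return [s for s, m in zip(items, mask) if m]
    raise RuntimeError("truncated subset sampling did not converge")


def _plant_gain_site(
    reference: Reference,
    families: list[MiRNAFamily],
    family: MiRNAFamily,
    gene_id: str,
    rng: np.random.Generator,
    occupied: set[int],
    design: CohortDesign,
) -> int | None:
    """Engineer one MBS-gaining edit in a gene's 3'-UTR.

    Writes the family's 8mer target with its edit-position G reverted to
    A, then verifies with the seed scanner that the pre sequence has no
    site overlapping the edit and the post sequence gains one, for every
    family.  Returns the 0-based 3'-UTR offset of the edit, or None when
    no placement satisfies the constraints.
    """
    target = _revcomp_str(family.seed) + "A"  # the 8mer site sequence
    g_offsets = [i for i, b in enumerate(target) if b == "G"]
    if not g_offsets:
        return None
    utr_len = design.utr3_length
    # 20-bp spacing keeps this window clear of every previously planted
    # edit's verified +/-7 neighborhood
    starts = [s for s in range(2, utr_len - len(target) - 2)
              if all(abs((s + o) - oc) > 20 for o in g_offsets for oc in occupied)]
    rng.shuffle(starts)
    for start in starts[:40]:
        for off in g_offsets:
            pre_window = target[:off] + "A" + target[off + 1:]
            saved = [reference.transcript_base(gene_id, start + j)
                     for j in range(len(target))]
            for j, b in enumerate(pre_window):
                reference.set_transcript_base(gene_id, start + j, b)
            utr_seq = reference.utr3_sequence(gene_id)
            pos1 = start + off + 1  # 1-based on the UTR
            ok = _verify_gain(utr_seq, pos1, families, family)
            if ok:
                return start + off
            for j, b in enumerate(saved):  # restore and try elsewhere
                reference.set_transcript_base(gene_id, start + j, b)
    return None


def _revcomp_str(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _verify_gain(
    utr_seq: str, pos1: int, families: list[MiRNAFamily], family: MiRNAFamily
) -> bool:
    """The placement must classify as a clean gain: ``gain`` for the
    designated family and ``no_overlaps`` for every other family, under
    the same classifier the pipeline uses."""
    for fam in families:
        label = mbs_delta_for_edit({"t": (utr_seq, pos1)}, fam).classification
        expected = "gain" if fam.family_id == family.family_id else "no_overlaps"
        if label != expected:
            return False
    return True


def generate_cohort(
    design: CohortDesign,
    reference: Reference,
    families: list[MiRNAFamily],
    rng: np.random.Generator | None = None,
) -> tuple[list[EditCall], dict[str, SampleMeta], GroundTruthManifest]:
    """Per-sample variant tables, sample metadata and the truth manifest.

    Mutates the reference genome when planting edit bases, ADAR context
    and MBS-gain neighborhoods; call it before freezing the genome to
    FASTA.
    """
    rng = rng or np.random.default_rng(design.seed + 2)
    meta = _sample_meta(design)
    chrom = reference.chrom
    stages = list(design.stages)
    gene_ids = sorted(reference.gene_layout)

    # -- clearance gene partition (shared with generate_expression) ------
    n_maternal = int(round(design.maternal_fraction * len(gene_ids)))
    maternal = list(rng.choice(gene_ids, size=n_maternal, replace=False))
    n_targets = int(round(design.clearance_fraction * len(maternal)))
    targets = set(str(g) for g in rng.choice(maternal, size=n_targets, replace=False))
    maternal_others = set(map(str, maternal)) - targets
    non_maternal = set(gene_ids) - set(map(str, maternal))

    occupied: dict[str, set[int]] = {g: set() for g in gene_ids}  # utr3 offsets
    used_positions: set[int] = set()

    site_gene: dict[Site, str] = {}
    site_utr3_pos: dict[Site, int] = {}
    site_strand: dict[Site, str] = {}
    mbs_gain: dict[Site, str] = {}

    def place_utr3_edit(gene_id: str, want_gain_family: MiRNAFamily | None) -> Site | None:
        lay = reference.gene_layout[gene_id]
        if want_gain_family is not None:
            off = _plant_gain_site(reference, families, want_gain_family,
                                   gene_id, rng, occupied[gene_id], design)
            if off is None:
                return None
        else:
            free = [o for o in range(2, design.utr3_length - 2)
                    if all(abs(o - oc) > 10 for oc in occupied[gene_id])]
            if not free:
                return None
            off = int(rng.choice(free))
            reference.set_transcript_base(gene_id, off, "A")
            # ADAR context on the edited strand: G depleted 5', enriched 3'
            minus1 = "G" if rng.random() < design.context_g_minus1 \
                else str(rng.choice(list("ACT")))
            plus1 = "G" if rng.random() < design.context_g_plus1 \
                else str(rng.choice(list("ACT")))
            reference.set_transcript_base(gene_id, off - 1, minus1)
            reference.set_transcript_base(gene_id, off + 1, plus1)
        occupied[gene_id].add(off)
        pos = reference.utr3_offset_to_genomic(gene_id, off)
        site = (chrom, pos)
        if pos in used_positions:
            return None
        used_positions.add(pos)
        site_gene[site] = gene_id
        site_utr3_pos[site] = off + 1
        site_strand[site] = lay["strand"]
        if want_gain_family is not None:
            mbs_gain[site] = want_gain_family.family_id
        return site

    # -- plant REE sites -------------------------------------------------
    n_gain = int(round(design.mbs_gain_fraction * design.n_ree))
    ree_sites: list[Site] = []
    ree_window: dict[Site, list[str]] = {}
    target_list = sorted(targets)
    other_list = sorted(maternal_others | non_maternal)
    attempts = 0
    while len(ree_sites) < design.n_ree:
        attempts += 1
        if attempts > 50 * design.n_ree:
            raise RuntimeError(
                "could not place all recurrent edits; infeasible design "
                "(too many edits for the UTR space)"
            )
        want_gain = len(ree_sites) < n_gain
        if want_gain:
            pool = target_list if rng.random() < design.clearance_gain_bias else other_list
            fam = families[int(rng.integers(len(families)))]
        else:
            pool = gene_ids
            fam = None
        gene_id = str(pool[int(rng.integers(len(pool)))])
        site = place_utr3_edit(gene_id, fam if want_gain else None)
        if site is None:
            continue
        start = int(rng.integers(len(stages)))
        window = [stages[start]]
        while (start + len(window) < len(stages)
               and rng.random() < design.ree_persist_prob):
            window.append(stages[start + len(window)])
        ree_sites.append(site)
        ree_window[site] = window

    ree_by_stage: dict[str, set[Site]] = {s: set() for s in stages}
    for site, window in ree_window.items():
        for s in window:
            ree_by_stage[s].add(site)

    # -- dropout designation ---------------------------------------------
    groups = design.abnormal_groups()
    dropout: dict[tuple[str, str], set[Site]] = {g: set() for g in groups}
    dropout_of_site: dict[Site, tuple[str, str]] = {}
    for cond in sorted(design.dropout):
        want = design.dropout[cond]
        cond_groups = [g for g in groups if g[1] == cond]
        if not cond_groups or want == 0:
            continue
        eligible = [
            (site, g) for g in cond_groups
            for site in sorted(ree_by_stage[g[0]])
            if site not in dropout_of_site
        ]
        if len({s for s, _ in eligible}) < want:
            raise RuntimeError(f"not enough REEs to host {want} {cond} dropouts")
        picked: set[Site] = set()
        order = rng.permutation(len(eligible))
        for idx in order:
            site, g = eligible[idx]
            if site in picked or site in dropout_of_site:
                continue
            dropout[g].add(site)
            dropout_of_site[site] = g
            picked.add(site)
            if len(picked) >= want:
                break

    # -- noise edit sites -------------------------------------------------
    noise_sites: list[Site] = []
    noise_stage: dict[Site, str] = {}
    attempts = 0
    while len(noise_sites) < design.n_noise:
        attempts += 1
        if attempts > 50 * design.n_noise:
            raise RuntimeError("could not place all noise edits")
        gene_id = str(gene_ids[int(rng.integers(len(gene_ids)))])
        site = place_utr3_edit(gene_id, None)
        if site is None:
            continue
        noise_sites.append(site)
        noise_stage[site] = stages[int(rng.integers(len(stages)))]

    # -- SNP contaminants and non-A>G noise -------------------------------
    genome_list = reference.genome[chrom]
    snp_positions: set[Site] = set()
    while len(snp_positions) < design.n_snp:
        pos = int(rng.integers(1, len(genome_list) + 1))
        if pos in used_positions:
            continue
        used_positions.add(pos)
        snp_positions.add((chrom, pos))
    non_a2g_sites: set[Site] = set()
    non_a2g_change: dict[Site, tuple[str, str]] = {}
    while len(non_a2g_sites) < design.n_non_a2g_noise:
        gene_id = str(gene_ids[int(rng.integers(len(gene_ids)))])
        lay = reference.gene_layout[gene_id]
        s, e = lay["utr3"]
        pos = int(rng.integers(s + 1, e + 1))
        if pos in used_positions:
            continue
        used_positions.add(pos)
        ref_base = genome_list[pos - 1]
        alts = [b for b in "ACGT" if b != ref_base]
        alt = str(rng.choice(alts))
        # avoid creating an A>G on the transcript strand
        tref = ref_base if lay["strand"] == "+" else _COMP[ref_base]
        talt = alt if lay["strand"] == "+" else _COMP[alt]
        if tref == "A" and talt == "G":
            alt = str(rng.choice([b for b in alts if b != alt]))
        site = (chrom, pos)
        non_a2g_sites.add(site)
        non_a2g_change[site] = (ref_base, alt)
        site_gene[site] = gene_id

    # -- per-sample observations ------------------------------------------
    normals_by_stage = {
        s: sorted(x for x, m in meta.items() if m.stage == s and m.is_normal)
        for s in stages
    }
    group_samples = {
        g: sorted(x for x, m in meta.items()
                  if m.stage == g[0] and m.condition == g[1])
        for g in groups
    }
    ree_threshold = math.ceil(design.ree_fraction * design.n_normal_per_stage)
    calls: list[EditCall] = []

    def emit(sample: str, site: Site, ref: str, alt: str, is_alu: bool,
             high_af: bool = False) -> None:
        if high_af:
            an = design.an_min + int(rng.negative_binomial(
                design.an_negbin_r,
                design.an_negbin_r / (design.an_negbin_r + design.an_mean_extra)))
            ac = int(rng.binomial(an, rng.uniform(0.9, 1.0)))
            ac = max(ac, 1)
        else:
            ac, an = _sample_acan(rng, design, is_alu)
        calls.append(EditCall(sample, site[0], site[1], ref, alt, ac, an))

    def genomic_change(site: Site) -> tuple[str, str]:
        """ref/alt on the genome for an A>G edit on the transcript strand."""
        strand = site_strand[site]
        return ("A", "G") if strand == "+" else ("T", "C")

    for site in ree_sites:
        ref, alt = genomic_change(site)
        is_alu = reference.alu_mask.contains(*site)
        window = ree_window[site]
        for s_idx, stage in enumerate(stages):
            normals = normals_by_stage[stage]
            if stage in window:
                detected = _truncated_binomial_subset(
                    rng, normals, design.ree_detection_prob,
                    min_count=ree_threshold, max_count=None,
                )
            elif (s_idx > 0 and stages[s_idx - 1] == window[-1]):
                # residual detection in the stage right after the window
                detected = _truncated_binomial_subset(
                    rng, normals, design.noise_detection_prob,
                    min_count=None, max_count=ree_threshold - 1,
                )
            else:
                detected = []
            for sample in detected:
                emit(sample, site, ref, alt, is_alu)
        for g in groups:
            stage, cond = g
            if stage not in window:
                continue
            if dropout_of_site.get(site) == g:
                continue  # complete loss in the designated group
            detected = _truncated_binomial_subset(
                rng, group_samples[g], design.ree_detection_prob,
                min_count=1, max_count=None,
            )
            for sample in detected:
                emit(sample, site, ref, alt, is_alu)

    for site in noise_sites:
        ref, alt = genomic_change(site)
        is_alu = reference.alu_mask.contains(*site)
        stage = noise_stage[site]
        detected = _truncated_binomial_subset(
            rng, normals_by_stage[stage], design.noise_detection_prob,
            min_count=None, max_count=ree_threshold - 1,
        )
        for sample in detected:
            emit(sample, site, ref, alt, is_alu)
        for g in groups:
            if g[0] != stage:
                continue
            for sample in group_samples[g]:
                if rng.random() < design.noise_detection_prob:
                    emit(sample, site, ref, alt, is_alu)

    all_samples = sorted(meta)
    for site in sorted(snp_positions):
        ref = genome_list[site[1] - 1]
        alt = "G" if ref == "A" else str(rng.choice([b for b in "ACGT" if b != ref]))
        for sample in all_samples:
            if rng.random() < design.snp_presence_prob:
                emit(sample, site, ref, alt, reference.alu_mask.contains(*site),
                     high_af=True)

    for site in sorted(non_a2g_sites):
        ref, alt = non_a2g_change[site]
        stage = stages[int(rng.integers(len(stages)))]
        for sample in normals_by_stage[stage]:
            if rng.random() < design.non_a2g_detection_prob:
                emit(sample, site, ref, alt, reference.alu_mask.contains(*site))

    manifest = GroundTruthManifest(
        ree_sites_by_stage=ree_by_stage,
        noise_sites=set(noise_sites),
        non_a2g_sites=set(non_a2g_sites),
        snp_positions=snp_positions,
        dropout=dropout,
        site_gene=site_gene,
        site_utr3_pos=site_utr3_pos,
        mbs_gain=mbs_gain,
        clearance_targets=targets,
        maternal_others=maternal_others,
        non_maternal=non_maternal,
        context_params={
            "g_minus1": design.context_g_minus1,
            "g_plus1": design.context_g_plus1,
        },
    )
    calls.sort(key=lambda c: (c.sample_id, c.chrom, c.pos))
    return calls, meta, manifest


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    design: CohortDesign,
    manifest: GroundTruthManifest,
    sample_meta: Mapping[str, SampleMeta],
    rng: np.random.Generator | None = None,
    max_retries: int = 50,
) -> pd.DataFrame:
    """Gene x sample FPKM with planted maternal-decay structure.

    Clearance targets satisfy min(median GV, median MII) > 2 x median
    8-cell by construction under log-normal noise; other maternal genes
    violate it; non-maternal genes stay below the maternal threshold.
    Genes whose sampled noise breaks their planted label are re-drawn.
    """
    rng = rng or np.random.default_rng(design.seed + 3)
    samples = sorted(sample_meta)
    stages = list(design.stages)
    genes = sorted(
        manifest.clearance_targets | manifest.maternal_others | manifest.non_maternal
    )
    try:
        gv_i, mii_i, e8_i = (stages.index(s)
                             for s in ("oocyte_GV", "oocyte_MII", "8cell"))
    except ValueError:
        gv_i = mii_i = e8_i = None

    def stage_base(gene: str, base: float, stage: str) -> float:
        if gene in manifest.clearance_targets and gv_i is not None:
            idx = stages.index(stage)
            if idx <= mii_i:
                return base
            frac = min(1.0, (idx - mii_i) / max(1, e8_i - mii_i))
            return base * design.maternal_decay_fold ** (-frac)
        return base

    rows = {}
    for gene in genes:
        if gene in manifest.non_maternal:
            base = rng.uniform(0.2, 1.2)
        else:
            base = rng.uniform(5.0, 16.0)
        for attempt in range(max_retries):
            vals = np.array([
                stage_base(gene, base, sample_meta[s].stage)
                * rng.lognormal(0.0, design.expr_sigma)
                for s in samples
            ])
            series = pd.Series(vals, index=samples)
            med = {
                st: series[[s for s in samples if sample_meta[s].stage == st
                            and sample_meta[s].is_normal]].median()
                for st in ("oocyte_GV", "oocyte_MII", "8cell")
                if st in stages
            }
            if len(med) < 3:
                break  # cohort lacks the clearance stages; keep as drawn
            maternal = med["oocyte_GV"] > 2 or med["oocyte_MII"] > 2
            decays = min(med["oocyte_GV"], med["oocyte_MII"]) > 2 * med["8cell"]
            if gene in manifest.clearance_targets and maternal and decays:
                break
            if gene in manifest.maternal_others and maternal and not decays:
                break
            if gene in manifest.non_maternal and not maternal:
                break
        else:
            raise RuntimeError(f"expression for {gene} never matched its label")
        rows[gene] = series
    expr = pd.DataFrame(rows).T
    expr.index.name = "gene_id"
    return expr


# ---------------------------------------------------------------------------
# Lightweight clearance replicates


def generate_clearance_replicate(
    design: CohortDesign,
    rng: np.random.Generator,
    planted_excess: bool = True,
    n_samples_per_stage: int = 8,
):
    """One lightweight replicate for the clearance-enrichment statistics.

    Generates only what the enrichment comparison consumes: an FPKM
    matrix over the GV/MII/8-cell stages with the planted maternal-decay
    structure, and per-(gene, sample) MBS-gain counts — Poisson baseline
    everywhere, plus a Poisson excess on clearance-target pairs unless
    ``planted_excess`` is off (the null configuration).

    Returns (expression, sample_meta, pair_counts, truth_targets).
    """
    stages = ("oocyte_GV", "oocyte_MII", "8cell")
    meta: dict[str, SampleMeta] = {}
    for st in stages:
        for i in range(n_samples_per_stage):
            sid = f"{st}_N{i:02d}"
            meta[sid] = SampleMeta(sid, st, "normal")
    samples = sorted(meta)

    genes = [f"G{i:04d}" for i in range(design.n_genes)]
    n_maternal = int(round(design.maternal_fraction * len(genes)))
    maternal = genes[:n_maternal]
    n_targets = int(round(design.clearance_fraction * n_maternal))
    targets = set(maternal[:n_targets])
    others = set(maternal[n_targets:])

    data = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        if gene in targets or gene in others:
            base = rng.uniform(5.0, 16.0)
        else:
            base = rng.uniform(0.2, 1.2)
        for si, s in enumerate(samples):
            b = base
            if gene in targets and meta[s].stage == "8cell":
                b = base / design.maternal_decay_fold
            data[gi, si] = b * rng.lognormal(0.0, design.expr_sigma)
    expr = pd.DataFrame(data, index=genes, columns=samples)
    expr.index.name = "gene_id"

    rows = []
    for gene in maternal:
        lam = design.mbs_gain_baseline
        extra = design.mbs_gain_excess if (planted_excess and gene in targets) else 0.0
        counts = rng.poisson(lam + extra, size=len(samples))
        for s, c in zip(samples, counts):
            rows.append({"gene_id": gene, "sample_id": s, "gains": int(c)})
    pair_counts = pd.DataFrame(rows)
    return expr, meta, pair_counts, targets


# ---------------------------------------------------------------------------
# Driver and writers


def simulate_cohort(design: CohortDesign) -> SimulatedCohort:
    """Generate a full cohort deterministically from the design seed."""
    rng = np.random.default_rng(design.seed)
    reference = generate_reference(design, rng)
    families = generate_families(design, rng)
    calls, meta, manifest = generate_cohort(design, reference, families, rng)
    expression = generate_expression(design, manifest, meta, rng)
    return SimulatedCohort(design, reference, families, calls, meta,
                           expression, manifest)


def write_cohort(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus the truth manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ref = sim.reference
    paths["genome"] = outdir / "genome.fa"
    with open(paths["genome"], "w") as fh:
        for chrom in sorted(ref.genome):
            fh.write(f">{chrom}\n")
            fh.write(textwrap.fill(ref.sequence(chrom), 70) + "\n")

    paths["gtf"] = outdir / "model.gtf"
    with open(paths["gtf"], "w") as fh:
        for gid in sorted(ref.gene_layout):
            gene = ref.gene_models.genes[gid]
            for tx in gene.transcripts:
                s, e = tx.span
                attrs = (f'gene_id "{gid}"; transcript_id "{tx.transcript_id}"; '
                         f'gene_name "{gene.gene_name}";')
                fh.write(f"{tx.chrom}\tsim\ttranscript\t{s + 1}\t{e}\t.\t"
                         f"{tx.strand}\t.\t{attrs}\n")
                for xs, xe in tx.exons:
                    fh.write(f"{tx.chrom}\tsim\texon\t{xs + 1}\t{xe}\t.\t"
                             f"{tx.strand}\t.\t{attrs}\n")
                for cs, ce in tx.cds:
                    fh.write(f"{tx.chrom}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t"
                             f"{tx.strand}\t0\t{attrs}\n")

    paths["alu"] = outdir / "alu.bed"
    write_interval_mask(ref.alu_mask, paths["alu"])

    paths["utrs"] = outdir / "utrs.fa"
    with open(paths["utrs"], "w") as fh:
        for gid in sorted(ref.gene_layout):
            fh.write(f">{gid}.t1\n{ref.utr3_sequence(gid)}\n")

    paths["families"] = outdir / "families.tsv"
    write_family_table(sim.families, paths["families"])

    paths["meta"] = outdir / "meta.tsv"
    write_sample_meta(sim.sample_meta, paths["meta"])

    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    contigs = {c: len(ref.genome[c]) for c in ref.genome}
    by_sample: dict[str, list[EditCall]] = {}
    for call in sim.calls:
        by_sample.setdefault(call.sample_id, []).append(call)
    for sample in sorted(sim.sample_meta):
        path = calls_dir / f"{sample}.vcf"
        write_edit_calls_vcf(by_sample.get(sample, []), path, contigs)
    paths["calls"] = calls_dir

    paths["snps"] = outdir / "snps.tsv"
    pd.DataFrame(
        sorted(sim.manifest.snp_positions), columns=["chrom", "pos"]
    ).to_csv(paths["snps"], sep="\t", index=False)

    paths["fpkm"] = outdir / "fpkm.tsv"
    sim.expression.to_csv(paths["fpkm"], sep="\t")

    paths["truth"] = outdir / "truth.json"
    sim.manifest.to_json(paths["truth"])
    return paths
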