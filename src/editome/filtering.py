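"""Site-level filters turning candidate variant tables into the accepted
A-to-I editome, plus the editome QC metrics.

The per-call thresholds follow the validation settings of the adapted
identification pipeline: Alu edits need at least ``min_coverage`` reads
and an editing level of at least ``min_editing_level``; non-Alu edits
additionally need at least ``min_mismatch_reads_non_alu`` edit-supporting
reads.  Cohort-level support differs by repeat context: Alu sites count
as soon as one sample shows them, non-Alu sites need at least two normal
(or two abnormal) samples of the same stage — normal and abnormal
observations are never pooled.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import EditCall, GenomicIntervalSet, SampleMeta

__all__ = [
    "VariantChangeClass",
    "FilterConfig",
    "FilterDecision",
    "classify_change",
    "exclude_known_variants",
    "apply_site_filters",
    "apply_support_filter",
    "qc_a2g_proportion",
    "qc_alu_ratio",
    "dna_rna_concordance",
    "context_profile",
    "ContextProfile",
    "identify_editome",
    "EditomeResult",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

Site = tuple[str, int]


@dataclass(frozen=True, slots=True)
class VariantChangeClass:
    """Transcript-strand substitution label.

    Strand-definite changes carry a single label like ``A>G``; when the
    strand is unknown a change and its reverse complement collapse into
    one ambiguous class labelled e.g. ``A>G/T>C`` (the member whose
    reference base is A or C names the pair).
    """

    label: str
    definiteness: str  # strand_definite | strand_ambiguous

    @property
    def is_a2g(self) -> bool:
        return self.label in ("A>G", "A>G/T>C")


def classify_change(ref: str, alt: str, gene_strand: str = "unknown") -> VariantChangeClass:
    """Classify a substitution on the transcript strand.

    On '-' genes ref/alt are complemented before labeling; intergenic or
    strand-conflicting sites are strand-ambiguous and the label collapses
    reverse-complement pairs.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"non-ACGT change {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if gene_strand not in ("+", "-", "unknown"):
        raise ValueError(f"gene_strand must be +, - or unknown, got {gene_strand!r}")
    if gene_strand == "-":
        ref, alt = _COMP[ref], _COMP[alt]
    if gene_strand == "unknown":
        rc_ref, rc_alt = _COMP[ref], _COMP[alt]
        first, second = ((ref, alt), (rc_ref, rc_alt))
        if first[0] not in ("A", "C"):
            first, second = second, first
        return VariantChangeClass(
            f"{first[0]}>{first[1]}/{second[0]}>{second[1]}", "strand_ambiguous"
        )
    return VariantChangeClass(f"{ref}>{alt}", "strand_definite")


@dataclass
class FilterConfig:
    """Thresholds for per-call and cohort-level acceptance.

    Read-level criteria (mean base quality >= 25, mapping quality >= 20,
    PCR duplicates removed) are applied upstream of this artifact and are
    recorded here as provenance metadata only.
    """

    min_coverage: int = 2
    min_editing_level: float = 0.1
    min_mismatch_reads_non_alu: int = 2
    min_samples_alu: int = 1
    min_samples_non_alu_same_stage: int = 2
    read_level_metadata: dict = field(
        default_factory=lambda: {
            "min_mean_base_quality": 25,
            "min_mapping_quality": 20,
            "pcr_duplicates_removed": True,
        }
    )

    def __post_init__(self) -> None:
        if min(self.min_coverage, self.min_mismatch_reads_non_alu,
               self.min_samples_alu, self.min_samples_non_alu_same_stage) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0 <= self.min_editing_level <= 1:
            raise ValueError("min_editing_level must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: v for k, v in self.__dict__.items() if k != "read_level_metadata"},
                fh,
            )


@dataclass(frozen=True, slots=True)
class FilterDecision:
    accepted: bool
    reason: str | None = None  # low_coverage | low_level | few_mismatch_reads

    def __bool__(self) -> bool:
        return self.accepted


def exclude_known_variants(
    calls: Sequence[EditCall],
    *snp_sets: GenomicIntervalSet | Iterable[Site],
) -> list[EditCall]:
    """Drop every call whose (chrom, pos) appears in any known-variant set.

    Input order is preserved; an empty SNP set is legal (identity).
    """
    materialized: list = []
    for s in snp_sets:
        materialized.append(s if isinstance(s, GenomicIntervalSet) else set(s))
    out = []
    for call in calls:
        if any(call.site in s for s in materialized):
            continue
        out.append(call)
    return out


def apply_site_filters(call: EditCall, is_alu: bool, cfg: FilterConfig) -> FilterDecision:
    """Accept or reject a single call with a reason.

    Checks run in order: coverage, editing level, then (non-Alu only) the
    mismatch-read count.  Acceptance is monotone in AC at fixed AN.
    """
    if call.an < cfg.min_coverage:
        return FilterDecision(False, "low_coverage")
    if call.af < cfg.min_editing_level:
        return FilterDecision(False, "low_level")
    if not is_alu and call.ac < cfg.min_mismatch_reads_non_alu:
        return FilterDecision(False, "few_mismatch_reads")
    return FilterDecision(True)


def apply_support_filter(
    site_observations: Mapping[Site, Iterable[str]],
    sample_meta: Mapping[str, SampleMeta],
    alu_mask: GenomicIntervalSet,
    cfg: FilterConfig | None = None,
) -> set[Site]:
    """Cohort-level support rule.

    Alu sites need ``min_samples_alu`` observing samples anywhere; other
    sites need ``min_samples_non_alu_same_stage`` observations within one
    (stage, normal) group or one (stage, abnormal) group.  Normal and
    abnormal observations are never pooled.
    """
    cfg = cfg or FilterConfig()
    accepted: set[Site] = set()
    for site, samples in site_observations.items():
        samples = set(samples)
        unknown = samples - sample_meta.keys()
        if unknown:
            raise KeyError(f"unknown sample ids {sorted(unknown)} at {site}")
        if alu_mask.contains(*site):
            if len(samples) >= cfg.min_samples_alu:
                accepted.add(site)
            continue
        groups = Counter(
            (sample_meta[s].stage, sample_meta[s].is_normal) for s in samples
        )
        if groups and max(groups.values()) >= cfg.min_samples_non_alu_same_stage:
            accepted.add(site)
    return accepted


# ---------------------------------------------------------------------------
# QC metrics


def qc_a2g_proportion(variants: Iterable[VariantChangeClass]) -> float:
    """Fraction of variants that are strand-definite A>G or
    strand-ambiguous A>G/T>C."""
    variants = list(variants)
    if not variants:
        warnings.warn("qc_a2g_proportion: empty input", stacklevel=2)
        return float("nan")
    hits = sum(1 for v in variants if v.is_a2g)
    return hits / len(variants)


def qc_alu_ratio(sites: Iterable[Site], alu_mask: GenomicIntervalSet) -> float:
    """Fraction of accepted sites falling inside the Alu mask."""
    sites = list(sites)
    if not sites:
        warnings.warn("qc_alu_ratio: empty input", stacklevel=2)
        return float("nan")
    return sum(1 for s in sites if alu_mask.contains(*s)) / len(sites)


def dna_rna_concordance(
    rna_edits: Iterable[Site] | Mapping[str, Iterable[Site]],
    dna_variants: Iterable[Site],
) -> float | dict[str, float]:
    """|RNA edits overlapping DNA variants| / |RNA edits|.

    A mapping of sample -> sites yields a per-sample dictionary; a flat
    site collection yields a single ratio.  A stringent pipeline applied
    after known-variant exclusion should drive this to zero.
    """
    dna = set(dna_variants)
    if isinstance(rna_edits, Mapping):
        return {
            sample: dna_rna_concordance(set(sites), dna)
            for sample, sites in rna_edits.items()
        }
    rna = set(rna_edits)
    if not rna:
        warnings.warn("dna_rna_concordance: empty RNA edit set", stacklevel=2)
        return float("nan")
    return len(rna & dna) / len(rna)


@dataclass
class ContextProfile:
    """Per-position nucleotide frequencies around edited adenosines,
    oriented along the edited strand (the ADAR-motif summary)."""

    frequencies: pd.DataFrame  # index: offset -flank..+flank; columns ACGT
    n_sites: int
    n_skipped: int


def context_profile(
    edit_sites: Iterable[tuple[str, int, str]],
    genome,
    flank: int = 3,
) -> ContextProfile:
    """Nucleotide frequency table in a window around each edited base.

    ``edit_sites`` yields (chrom, 1-based pos, strand); minus-strand sites
    are reverse-complemented so the center base reads A on the edited
    strand.  Sites too close to a contig edge are skipped with a warning
    and counted in the report.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    counts = np.zeros((2 * flank + 1, 4), dtype=float)
    order = "ACGT"
    comp = str.maketrans("ACGT", "TGCA")
    n_used = n_skipped = 0
    for chrom, pos, strand in edit_sites:
        contig = genome[chrom]
        start, end = pos - 1 - flank, pos + flank
        if start < 0 or end > len(contig):
            n_skipped += 1
            continue
        window = str(contig[start:end]).upper()
        if strand == "-":
            window = window.translate(comp)[::-1]
        if any(b not in order for b in window):
            n_skipped += 1
            continue
        for i, base in enumerate(window):
            counts[i, order.index(base)] += 1
        n_used += 1
    if n_skipped:
        warnings.warn(f"context_profile: skipped {n_skipped} site(s) near contig edges",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, index=range(-flank, flank + 1), columns=list(order))
    return ContextProfile(df, n_used, n_skipped)


# ---------------------------------------------------------------------------
# Pipeline glue


@dataclass
class EditomeResult:
    """Accepted editome for a cohort."""

    per_sample_edits: dict[str, set[Site]]  # sites passing per-call filters
    accepted_sites: set[Site]               # sites also passing cohort support
    change_classes: list[VariantChangeClass]
    counts: dict[str, int]

    def accepted_per_sample(self) -> dict[str, set[Site]]:
        """Per-sample detections restricted to cohort-accepted sites."""
        return {
            s: sites & self.accepted_sites
            for s, sites in self.per_sample_edits.items()
        }


def identify_editome(
    calls: Sequence[EditCall],
    sample_meta: Mapping[str, SampleMeta],
    alu_mask: GenomicIntervalSet,
    snp_sets: Sequence[GenomicIntervalSet | Iterable[Site]] = (),
    gene_models=None,
    cfg: FilterConfig | None = None,
) -> EditomeResult:
    """Run the candidate-to-editome filter cascade for a whole cohort.

    Steps: known-variant exclusion; transcript-strand classification
    (keeping strand-definite A>G plus strand-ambiguous A>G/T>C); per-call
    coverage/level/mismatch filters; cohort support filter.
    """
    cfg = cfg or FilterConfig()
    counts = {"input": len(calls)}
    calls = exclude_known_variants(calls, *snp_sets)
    counts["after_snp_exclusion"] = len(calls)

    change_classes: list[VariantChangeClass] = []
    a2g_calls: list[EditCall] = []
    for call in calls:
        strand = (
            gene_models.strand_at(call.chrom, call.pos)
            if gene_models is not None else "unknown"
        )
        vc = classify_change(call.ref, call.alt, strand)
        change_classes.append(vc)
        if vc.is_a2g:
            a2g_calls.append(call)
    counts["a2g_candidates"] = len(a2g_calls)

    per_sample: dict[str, set[Site]] = defaultdict(set)
    observations: dict[Site, set[str]] = defaultdict(set)
    for call in a2g_calls:
        if apply_site_filters(call, alu_mask.contains(*call.site), cfg):
            per_sample[call.sample_id].add(call.site)
            observations[call.site].add(call.sample_id)
    counts["after_site_filters"] = sum(len(v) for v in per_sample.values())

    accepted = apply_support_filter(observations, sample_meta, alu_mask, cfg)
    counts["accepted_sites"] = len(accepted)
    return EditomeResult(dict(per_sample), accepted, change_classes, counts)
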