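"""Region classification and protein recoding effects for edits.

Each edit is classified per transcript and then reduced to a single site
label by the fixed priority

    CDS > 5'-UTR > 3'-UTR > non-coding exonic > intronic > intergenic.

Per-gene reduced classes are retained alongside the site-level label so
that gene-level analyses can use either resolution.  Recoding effects are
computed from the standard codon table with A->G substituted on the
coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .io_formats import GeneModelSet, Transcript

__all__ = [
    "REGION_PRIORITY",
    "RegionClass",
    "RecodingEffect",
    "reduce_region_classes",
    "classify_region",
    "recoding_effect",
]

#: fixed reduction order, highest priority first
REGION_PRIORITY: tuple[str, ...] = (
    "CDS",
    "UTR5",
    "UTR3",
    "noncoding_exonic",
    "intronic",
    "intergenic",
)
_PRIORITY_INDEX = {c: i for i, c in enumerate(REGION_PRIORITY)}


@dataclass(frozen=True, slots=True)
class RegionClass:
    """Reduced region label for a site plus the per-transcript and
    per-gene classes it was reduced from."""

    site_class: str
    per_transcript: Mapping[str, str] = field(default_factory=dict)
    per_gene: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True, slots=True)
class RecodingEffect:
    gene_id: str
    transcript_id: str
    codon_before: str | None
    codon_after: str | None
    aa_before: str | None
    aa_after: str | None
    effect: str  # missense | synonymous | stop_gained | stop_lost | none


def reduce_region_classes(classes: Iterable[str]) -> str:
    """Reduce per-transcript classes to the highest-priority one.

    Order-independent; an empty collection reduces to intergenic.
    """
    best = len(REGION_PRIORITY) - 1
    for c in classes:
        if c not in _PRIORITY_INDEX:
            raise ValueError(f"unknown region class {c!r}")
        best = min(best, _PRIORITY_INDEX[c])
    return REGION_PRIORITY[best]


def _point_in(blocks: list[tuple[int, int]], p0: int) -> bool:
    return any(s <= p0 < e for s, e in blocks)


def _classify_on_transcript(tx: Transcript, p0: int) -> str:
    if _point_in(tx.cds, p0):
        return "CDS"
    if _point_in(tx.utr5, p0):
        return "UTR5"
    if _point_in(tx.utr3, p0):
        return "UTR3"
    if _point_in(tx.exons, p0):
        return "noncoding_exonic"
    return "intronic"  # inside transcript span but in no exon


def classify_region(chrom: str, pos: int, gene_models: GeneModelSet) -> RegionClass:
    """Region class of a 1-based site, per transcript, per gene and reduced.

    Reduction is applied across all overlapping gene loci; a site with no
    overlapping transcript is intergenic.
    """
    p0 = pos - 1
    per_tx: dict[str, str] = {}
    per_gene_classes: dict[str, list[str]] = {}
    for tx in gene_models.transcripts_at(chrom, pos):
        c = _classify_on_transcript(tx, p0)
        per_tx[tx.transcript_id] = c
        per_gene_classes.setdefault(tx.gene_id, []).append(c)
    per_gene = {g: reduce_region_classes(cs) for g, cs in per_gene_classes.items()}
    return RegionClass(reduce_region_classes(per_tx.values()), per_tx, per_gene)


def _cds_offset(tx: Transcript, p0: int) -> int | None:
    """Offset of a genomic position within the CDS in transcript
    orientation (0-based), or None if outside the CDS."""
    blocks = tx.cds if tx.strand == "+" else list(reversed(tx.cds))
    offset = 0
    for s, e in blocks:
        if s <= p0 < e:
            within = (p0 - s) if tx.strand == "+" else (e - 1 - p0)
            return offset + within
        offset += e - s
    return None


def recoding_effect(
    chrom: str,
    pos: int,
    gene_models: GeneModelSet,
    genome,
) -> list[RecodingEffect]:
    """Protein effect of the A->G edit at a CDS site, per transcript.

    The codon is read in transcript orientation; the edited base must be
    adenosine on the coding strand (i.e. thymine on the genome for genes
    on the minus strand).  Transcripts whose CDS length is not a multiple
    of three are skipped with a warning.  Transcripts not covering the
    site in their CDS contribute an effect of ``none``.
    """
    p0 = pos - 1
    out: list[RecodingEffect] = []
    for tx in gene_models.transcripts_at(chrom, pos):
        off = _cds_offset(tx, p0)
        if off is None:
            out.append(RecodingEffect(tx.gene_id, tx.transcript_id,
                                      None, None, None, None, "none"))
            continue
        cds_seq = tx.cds_sequence(genome)
        if len(cds_seq) % 3 != 0:
            warnings.warn(
                f"transcript {tx.transcript_id}: CDS length {len(cds_seq)} not "
                f"divisible by 3; recoding skipped",
                stacklevel=2,
            )
            continue
        if cds_seq[off] != "A":
            warnings.warn(
                f"transcript {tx.transcript_id}: coding-strand base at "
                f"{chrom}:{pos} is {cds_seq[off]}, not A; recoding skipped",
                stacklevel=2,
            )
            continue
        codon_i = off // 3
        codon = cds_seq[codon_i * 3: codon_i * 3 + 3]
        within = off % 3
        edited = codon[:within] + "G" + codon[within + 1:]
        aa_before = str(Seq(codon).translate())
        aa_after = str(Seq(edited).translate())
        if aa_before == aa_after:
            effect = "synonymous"
        elif aa_after == "*":
            effect = "stop_gained"
        elif aa_before == "*":
            effect = "stop_lost"
        else:
            effect = "missense"
        out.append(RecodingEffect(tx.gene_id, tx.transcript_id,
                                  codon, edited, aa_before, aa_after, effect))
    return out
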