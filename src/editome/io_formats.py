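"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (BED arithmetic).  Every
user-facing edit position — in :class:`EditCall`, result tables, and the
VCF dialect — is 1-based, matching how editing sites are reported in the
literature (e.g. ``chr8:28190741``).

The VCF dialect is deliberately narrow: CHROM, POS, REF, ALT and the
reserved INFO fields ``AC`` (edit-supporting reads) and ``AN`` (read
coverage at the site).  Editing frequency (AF) is always recomputed as
AC/AN; an AF value present in an input file is ignored.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "ParseError",
    "ValidationError",
    "EditCall",
    "SampleMeta",
    "GenomicIntervalSet",
    "Transcript",
    "Gene",
    "GeneModelSet",
    "DEFAULT_STAGES",
    "CONDITIONS",
    "read_edit_calls",
    "write_edit_calls_vcf",
    "read_sample_meta",
    "write_sample_meta",
    "read_interval_mask",
    "write_interval_mask",
    "read_gene_model",
    "write_results_table",
    "read_results_table",
    "RESULT_SCHEMAS",
]


class ParseError(ValueError):
    """A record could not be parsed at all."""


class ValidationError(ValueError):
    """A record parsed but violates a domain invariant."""


DEFAULT_STAGES: tuple[str, ...] = (
    "oocyte_GV",
    "oocyte_MII",
    "zygote",
    "2cell",
    "4cell",
    "8cell",
    "morula",
)

#: normal plus the abnormal conditions (uniparental disomy, elder mothers,
#: non-control treatment)
CONDITIONS: frozenset[str] = frozenset(
    {"normal", "AG", "PG", "elder_mother", "treated"}
)

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class EditCall:
    """One candidate or accepted editing event in one sample.

    ``pos`` is 1-based.  ``ac`` is the number of reads supporting the
    edited base, ``an`` the read coverage at the site; the editing level
    (AF) is their ratio and is never stored separately.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValidationError(
                f"ref/alt must be one of A,C,G,T: got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.an < 1:
            raise ValidationError(f"AN must be >= 1, got {self.an}")
        if not 0 <= self.ac <= self.an:
            raise ValidationError(
                f"AC must satisfy 0 <= AC <= AN, got AC={self.ac}, AN={self.an}"
            )

    @property
    def af(self) -> float:
        """Editing level AC/AN, recomputed on access."""
        return self.ac / self.an

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Sample identity: developmental stage plus phenotypic condition."""

    sample_id: str
    stage: str
    condition: str = "normal"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"unknown condition {self.condition!r} for sample {self.sample_id}"
            )

    @property
    def is_normal(self) -> bool:
        return self.condition == "normal"


class GenomicIntervalSet:
    """A named set of genomic intervals with 0-based half-open storage.

    Houses the Alu mask and known-genomic-variant regions.  Point queries
    take 1-based positions: position ``p`` hits interval ``[start, end)``
    iff ``start < p <= end`` in BED coordinates.
    """

    def __init__(self, name: str = "intervals") -> None:
        self.name = name
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)

    def add(self, chrom: str, start: int, end: int, strand: str | None = None) -> None:
        if start >= end:
            raise ValidationError(
                f"interval start must be < end: {chrom}:{start}-{end}"
            )
        self._trees[chrom].addi(start, end, strand)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls inside any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield (chrom, iv.begin, iv.end)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __contains__(self, site: tuple[str, int]) -> bool:
        return self.contains(*site)


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class Transcript:
    """One transcript: ordered exons plus typed sub-intervals.

    All intervals are genomic, 0-based half-open, sorted by start.  UTRs
    are oriented by strand: on '-' the 3'-UTR is the genomically left-most
    UTR block set.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def _blocks_seq(self, genome, blocks: Sequence[tuple[int, int]]) -> str:
        seq = "".join(str(genome[self.chrom][s:e]) for s, e in blocks).upper()
        if self.strand == "-":
            seq = _revcomp(seq)
        return seq

    def cds_sequence(self, genome) -> str:
        """CDS in transcript orientation (starts with the start codon)."""
        return self._blocks_seq(genome, self.cds)

    def utr3_sequence(self, genome) -> str:
        """3'-UTR 5'->3' in transcript orientation."""
        return self._blocks_seq(genome, self.utr3)

    def genomic_to_utr3(self, pos: int) -> int | None:
        """Map a 1-based genomic position to a 1-based 3'-UTR coordinate.

        Returns None when the position is not inside the 3'-UTR.
        """
        p0 = pos - 1
        blocks = self.utr3 if self.strand == "+" else list(reversed(self.utr3))
        offset = 0
        for s, e in blocks:
            if s <= p0 < e:
                within = (p0 - s) if self.strand == "+" else (e - 1 - p0)
                return offset + within + 1
            offset += e - s
        return None


@dataclass
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))


class GeneModelSet:
    """Collection of genes indexed for fast point queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {g.gene_id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {
            t.transcript_id: t for g in self.genes.values() for t in g.transcripts
        }
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for t in self.transcripts.values():
            s, e = t.span
            self._trees[t.chrom].addi(s, e, t.transcript_id)

    def transcripts_at(self, chrom: str, pos: int) -> list[Transcript]:
        """Transcripts whose span contains the 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.at(pos - 1)]
        return sorted(hits, key=lambda t: t.transcript_id)

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        seen: dict[str, Gene] = {}
        for t in self.transcripts_at(chrom, pos):
            seen.setdefault(t.gene_id, self.genes[t.gene_id])
        return [seen[k] for k in sorted(seen)]

    def strand_at(self, chrom: str, pos: int) -> str:
        """Gene strand at a site: '+', '-', or 'unknown'.

        Sites overlapping genes on both strands, and intergenic sites, are
        strand-unknown.
        """
        strands = {g.strand for g in self.genes_at(chrom, pos)}
        if len(strands) == 1:
            return strands.pop()
        return "unknown"

    def __len__(self) -> int:
        return len(self.genes)


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Edit-call IO


def read_edit_calls(
    path: str | Path,
    dialect: str = "tsv",
    sample_id: str | None = None,
    normalize_chr: str | None = None,
) -> list[EditCall]:
    """Read per-sample candidate variant calls.

    Parameters
    ----------
    dialect:
        ``"tsv"`` expects columns chrom, pos, ref, alt, AC, AN and
        optionally sample_id; ``"vcf"`` expects a VCF with AC/AN in INFO.
    sample_id:
        Overrides (tsv) or supplies (vcf) the sample identity; for VCF it
        defaults to the file stem.
    normalize_chr:
        ``"strip"`` removes a leading ``chr``; ``"add"`` prepends it.
        Default leaves chromosome names verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        calls = _read_edit_calls_tsv(path, sample_id)
    elif dialect in ("vcf", "vcf_subset"):
        calls = _read_edit_calls_vcf(path, sample_id or path.stem.split(".")[0])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if normalize_chr == "strip":
        calls = [dataclasses.replace(c, chrom=c.chrom.removeprefix("chr")) for c in calls]
    elif normalize_chr == "add":
        calls = [
            dataclasses.replace(c, chrom=c.chrom if c.chrom.startswith("chr") else "chr" + c.chrom)
            for c in calls
        ]
    return calls


def _read_edit_calls_tsv(path: Path, sample_id: str | None) -> list[EditCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse TSV: {exc}") from exc
    df.columns = [c.lower() for c in df.columns]
    required = {"chrom", "pos", "ref", "alt", "ac", "an"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls: list[EditCall] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        sid = sample_id or getattr(row, "sample_id", None)
        if sid is None:
            raise ParseError(f"{path}:{line_no}: no sample_id column or argument")
        try:
            calls.append(
                EditCall(
                    sample_id=str(sid),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=str(row.ref).upper(),
                    alt=str(row.alt).upper(),
                    ac=int(row.ac),
                    an=int(row.an),
                )
            )
        except (TypeError, ValueError) as exc:
            kind = ValidationError if isinstance(exc, ValidationError) else ParseError
            raise kind(f"{path}:{line_no}: {exc}") from exc
    return calls


def _read_edit_calls_vcf(path: Path, sample_id: str) -> list[EditCall]:
    try:
        vf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: cannot open VCF: {exc}") from exc
    calls: list[EditCall] = []
    with vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            label = f"{path}: record {i + 1} ({rec.chrom}:{rec.pos})"
            if "AC" not in rec.info or "AN" not in rec.info:
                raise ParseError(f"{label}: missing INFO AC/AN")
            ac_values = rec.info["AC"]
            if not isinstance(ac_values, tuple):
                ac_values = (ac_values,)
            an = int(rec.info["AN"])
            alts = rec.alts or ()
            if len(ac_values) != len(alts):
                raise ParseError(f"{label}: AC count does not match ALT count")
            for alt, ac in zip(alts, ac_values):
                try:
                    calls.append(
                        EditCall(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=str(rec.ref).upper(),
                            alt=str(alt).upper(),
                            ac=int(ac),
                            an=an,
                        )
                    )
                except ValidationError as exc:
                    raise ValidationError(f"{label}: {exc}") from exc
    return calls


def write_edit_calls_vcf(
    calls: Sequence[EditCall],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls for one sample as a minimal VCF with AC/AN in INFO."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AC,Number=A,Type=Integer,Description="Edit-supporting read count">')
    header.add_line('##INFO=<ID=AN,Number=1,Type=Integer,Description="Read coverage at site">')
    if contigs is None:
        contigs = {c.chrom: max(x.pos for x in calls if x.chrom == c.chrom) + 1000
                   for c in calls}
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=c.chrom, start=c.pos - 1, stop=c.pos,
                alleles=(c.ref, c.alt),
            )
            rec.info["AC"] = (c.ac,)
            rec.info["AN"] = c.an
            out.write(rec)


# ---------------------------------------------------------------------------
# Sample metadata


def read_sample_meta(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    required = {"sample_id", "stage", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    meta: dict[str, SampleMeta] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        if row.sample_id in meta:
            raise ValidationError(
                f"{path}:{idx + 2}: duplicate sample_id {row.sample_id!r}"
            )
        meta[row.sample_id] = SampleMeta(row.sample_id, row.stage, row.condition)
    return meta


def write_sample_meta(meta: Mapping[str, SampleMeta], path: str | Path) -> None:
    rows = [
        {"sample_id": m.sample_id, "stage": m.stage, "condition": m.condition}
        for m in sorted(meta.values(), key=lambda m: m.sample_id)
    ]
    pd.DataFrame(rows, columns=["sample_id", "stage", "condition"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED interval masks


def read_interval_mask(path: str | Path, name: str | None = None) -> GenomicIntervalSet:
    """Read a BED3+ file (0-based half-open) into a GenomicIntervalSet."""
    path = Path(path)
    ivs = GenomicIntervalSet(name or path.stem)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns")
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            start, end = int(row[1]), int(row[2])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{idx + 1}: non-integer coordinates") from exc
        strand = row[5] if df.shape[1] >= 6 else None
        try:
            ivs.add(str(row[0]), start, end, strand)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{idx + 1}: {exc}") from exc
    return ivs


def write_interval_mask(ivs: GenomicIntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in ivs.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Gene models (GTF / GFF3)

_EXON_TYPES = {"exon"}
_CDS_TYPES = {"CDS"}
_UTR5_TYPES = {"five_prime_utr", "five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_utr", "three_prime_UTR", "3UTR"}
_GENERIC_UTR = {"UTR"}


def read_gene_model(path: str | Path) -> GeneModelSet:
    """Parse a GTF/GFF3 subset into gene models.

    Exon and CDS features are required for coding transcripts; UTRs are
    taken from explicit UTR lines when present and otherwise derived as
    exon-minus-CDS, split into 5'/3' by position relative to the CDS on
    the transcript strand.
    """
    import gffutils
    from gffutils.iterators import DataIterator

    path = Path(path)
    per_tx: dict[str, dict[str, list]] = defaultdict(
        lambda: {"exon": [], "cds": [], "utr5": [], "utr3": [], "utr": []}
    )
    tx_info: dict[str, tuple[str, str, str, str]] = {}
    gene_names: dict[str, str] = {}
    for feat in DataIterator(str(path)):
        ftype = feat.featuretype
        if ftype in ("gene", "transcript"):
            if "gene_id" in feat.attributes:
                gid = feat.attributes["gene_id"][0]
                if "gene_name" in feat.attributes:
                    gene_names[gid] = feat.attributes["gene_name"][0]
            continue
        bucket = None
        if ftype in _EXON_TYPES:
            bucket = "exon"
        elif ftype in _CDS_TYPES:
            bucket = "cds"
        elif ftype in _UTR5_TYPES:
            bucket = "utr5"
        elif ftype in _UTR3_TYPES:
            bucket = "utr3"
        elif ftype in _GENERIC_UTR:
            bucket = "utr"
        if bucket is None:
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise ParseError(
                f"{path}: {ftype} feature at {feat.seqid}:{feat.start} lacks "
                f"transcript_id/gene_id"
            ) from exc
        if feat.strand not in ("+", "-"):
            raise ValidationError(
                f"{path}: {ftype} at {feat.seqid}:{feat.start} has no strand"
            )
        tx_info[tid] = (gid, feat.seqid, feat.strand,
                        feat.attributes.get("gene_name", [gid])[0])
        per_tx[tid][bucket].append((feat.start - 1, feat.end))

    genes: dict[str, Gene] = {}
    for tid in sorted(per_tx):
        gid, chrom, strand, gname = tx_info[tid]
        parts = per_tx[tid]
        exons = _merge_blocks(parts["exon"])
        cds = _merge_blocks(parts["cds"])
        if cds and not exons:
            raise ValidationError(f"transcript {tid}: CDS present but no exons")
        if not exons:
            raise ValidationError(f"transcript {tid}: no exon features")
        explicit5 = _merge_blocks(parts["utr5"])
        explicit3 = _merge_blocks(parts["utr3"])
        generic = _merge_blocks(parts["utr"])
        if generic and cds:
            g5, g3 = _split_generic_utr(generic, cds, strand)
            explicit5 = _merge_blocks(explicit5 + g5)
            explicit3 = _merge_blocks(explicit3 + g3)
        if cds and not (explicit5 or explicit3):
            utr5, utr3 = _derive_utrs(exons, cds, strand)
        else:
            utr5, utr3 = explicit5, explicit3
        tx = Transcript(tid, gid, chrom, strand, exons, cds, utr5, utr3)
        if gid not in genes:
            genes[gid] = Gene(gid, gene_names.get(gid, gname), chrom, strand)
        genes[gid].transcripts.append(tx)
    return GeneModelSet(genes.values())


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge abutting/overlapping 0-based half-open blocks."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_blocks(
    blocks: list[tuple[int, int]], minus: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in blocks:
        cur = [(s, e)]
        for ms, me in minus:
            nxt: list[tuple[int, int]] = []
            for cs, ce in cur:
                if me <= cs or ms >= ce:
                    nxt.append((cs, ce))
                    continue
                if cs < ms:
                    nxt.append((cs, ms))
                if me < ce:
                    nxt.append((me, ce))
            cur = nxt
        out.extend(cur)
    return _merge_blocks(out)


def _derive_utrs(
    exons: list[tuple[int, int]], cds: list[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    utr = _subtract_blocks(exons, cds)
    cds_start, cds_end = cds[0][0], cds[-1][1]
    left = [b for b in utr if b[1] <= cds_start]
    right = [b for b in utr if b[0] >= cds_end]
    if strand == "+":
        return left, right
    return right, left


def _split_generic_utr(
    generic: list[tuple[int, int]], cds: list[tuple[int, int]], strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    cds_start, cds_end = cds[0][0], cds[-1][1]
    left = [b for b in generic if b[1] <= cds_start]
    right = [b for b in generic if b[0] >= cds_end]
    if strand == "+":
        return left, right
    return right, left


# ---------------------------------------------------------------------------
# Result tables

#: registered result schemas: name -> (columns, sort keys)
RESULT_SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "sites": (
        ["chrom", "pos", "n_samples", "region", "gene_id"],
        ["chrom", "pos"],
    ),
    "ree": (
        ["stage", "chrom", "pos", "fraction", "gene_id"],
        ["stage", "chrom", "pos"],
    ),
    "loss_scan": (
        ["stage", "condition", "chrom", "pos", "n_group_samples", "n_detected"],
        ["stage", "condition", "chrom", "pos"],
    ),
    "mbs_delta": (
        ["chrom", "pos", "gene_id", "family_id", "classification",
         "introduced", "removed"],
        ["chrom", "pos", "gene_id", "family_id"],
    ),
    "stats": (
        ["test", "group", "n_x", "n_y", "statistic", "p_value", "p_adjusted",
         "estimate", "conf_lower", "note"],
        ["test", "group"],
    ),
}

_INT_COLUMNS = {"pos", "n_samples", "n_group_samples", "n_detected",
                "introduced", "removed", "n_x", "n_y"}


def write_results_table(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    schema_name: str,
) -> None:
    """Write records under a registered schema: TSV, fixed column order,
    deterministic row sort (ties broken by the full column tuple)."""
    if schema_name not in RESULT_SCHEMAS:
        raise ValueError(f"unknown result schema {schema_name!r}")
    columns, sort_keys = RESULT_SCHEMAS[schema_name]
    df = pd.DataFrame(list(records) if not isinstance(records, pd.DataFrame) else records)
    if df.empty:
        df = pd.DataFrame(columns=columns)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"records missing schema columns {sorted(missing)}")
    df = df[columns]
    if len(df):
        df = df.sort_values(by=sort_keys + [c for c in columns if c not in sort_keys],
                            kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    if schema_name not in RESULT_SCHEMAS:
        raise ValueError(f"unknown result schema {schema_name!r}")
    columns, _ = RESULT_SCHEMAS[schema_name]
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing schema columns {sorted(missing)}")
    for col in df.columns:
        if col in _INT_COLUMNS and len(df):
            df[col] = df[col].astype(int)
    return df
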