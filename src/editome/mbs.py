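"""MicroRNA binding sites (MBSs) on 3'-UTRs and the effect of A->G edits
on them.

Two stand-in predictors sit behind one prediction interface: a seed-match
scanner (family-level, like multi-species seed predictors) and a
seed-anchored local aligner over the full mature sequence.  Alignment
predictions are collapsed to the miRNA-family level on the 4-property
key (family, target UTR, site type, start/end) and the two predictors
are intersected on the same key.  The per-(gene, family) effect of an
edit is then classified into five mutually exclusive categories —
no_overlaps, site_unchanged, gain, lost, mixed — by comparing, per
transcript, the sites the edit introduces with those it removes.

Site types follow the canonical seed-match taxonomy: a 6mer is the exact
reverse complement of seed positions 2-7; a 7mer-m8 extends the match to
position 8; a 7mer-A1 is the 6mer plus an adenosine opposite miRNA
position 1 (the 3' end of the site); an 8mer has both.  Only exact
Watson-Crick matches count — wobble pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

__all__ = [
    "MiRNAFamily",
    "MBSPrediction",
    "AlignmentPrediction",
    "AlignScoring",
    "MBSDelta",
    "read_family_table",
    "write_family_table",
    "seed_sites",
    "align_mature",
    "collapse_predictions",
    "intersect_predictions",
    "predict_mbs",
    "apply_edit",
    "classify_delta_counts",
    "mbs_delta_for_edit",
    "per_pair_mbs_table",
    "SITE_TYPES",
]

_COMP = str.maketrans("ACGT", "TGCA")

SITE_TYPES: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _dna(seq: str) -> str:
    """Canonical DNA alphabet: U and T interchangeable on input."""
    return seq.upper().replace("U", "T")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True, slots=True)
class MiRNAFamily:
    """A miRNA family: its 7-nt seed (mature positions 2-8) and member
    mature sequences."""

    family_id: str
    seed: str
    matures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seed", _dna(self.seed))
        object.__setattr__(self, "matures", tuple(_dna(m) for m in self.matures))
        if len(self.seed) != 7:
            raise ValueError(f"family {self.family_id}: seed must be 7 nt")
        for m in self.matures:
            if m[1:8] != self.seed:
                raise ValueError(
                    f"family {self.family_id}: mature {m} positions 2-8 "
                    f"({m[1:8]}) differ from seed {self.seed}"
                )


@dataclass(frozen=True, slots=True, order=True)
class MBSPrediction:
    """Family-level binding-site claim on a 3'-UTR.

    ``start``/``end`` are 1-based inclusive on the UTR, 5'->3' in
    transcript orientation.
    """

    family_id: str
    utr_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        expected = {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8}
        if self.site_type not in expected:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if length != expected[self.site_type]:
            raise ValueError(
                f"{self.site_type} site must span {expected[self.site_type]} nt, "
                f"got {length}"
            )

    @property
    def key(self) -> tuple[str, str, str, int, int]:
        return (self.family_id, self.utr_id, self.site_type, self.start, self.end)

    def overlaps(self, utr_pos: int) -> bool:
        return self.start <= utr_pos <= self.end


@dataclass(frozen=True, slots=True)
class AlignmentPrediction:
    """One mature-sequence alignment carrying its derived seed site."""

    mature_seq: str
    utr_id: str
    start: int
    end: int
    site_type: str
    score: float


@dataclass(frozen=True, slots=True)
class AlignScoring:
    """Scoring for the seed-anchored local aligner.

    The default minimum score asks for roughly twelve net matched bases
    of a ~22-nt mature sequence beyond the seed anchor.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    min_score: float = 24.0


# ---------------------------------------------------------------------------
# Family table IO


def read_family_table(path: str | Path) -> list[MiRNAFamily]:
    """TSV columns: family_id, seed, mature_id, mature_seq."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "seed", "mature_seq"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    fams: list[MiRNAFamily] = []
    for fid, sub in df.groupby("family_id", sort=True):
        seeds = set(sub["seed"])
        if len(seeds) != 1:
            raise ValueError(f"{path}: family {fid} has multiple seeds {seeds}")
        fams.append(MiRNAFamily(fid, seeds.pop(), tuple(sub["mature_seq"])))
    return fams


def write_family_table(families: Sequence[MiRNAFamily], path: str | Path) -> None:
    rows = []
    for fam in families:
        for i, m in enumerate(fam.matures, 1):
            rows.append({
                "family_id": fam.family_id, "seed": fam.seed,
                "mature_id": f"{fam.family_id}-{i}", "mature_seq": m,
            })
    pd.DataFrame(rows, columns=["family_id", "seed", "mature_id", "mature_seq"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictors


def seed_sites(
    utr_seq: str,
    family: MiRNAFamily,
    utr_id: str = "utr",
) -> list[MBSPrediction]:
    """Scan a 3'-UTR for seed-match sites of one family.

    Every position whose 6-nt window reverse-complements seed positions
    2-7 yields exactly one site, reported as the longest matching type at
    that position (8mer > 7mer-m8 > 7mer-A1 > 6mer), so nested types are
    not double-counted.
    """
    seq = _dna(utr_seq)
    seed = family.seed
    core = _revcomp(seed[:6])          # target match to seed positions 2-7
    m8_base = seed[6].translate(_COMP)  # target base pairing seed position 8
    n = len(seq)
    out: list[MBSPrediction] = []
    for i in range(n - 5):
        if seq[i:i + 6] != core:
            continue
        has_m8 = i >= 1 and seq[i - 1] == m8_base
        has_a1 = i + 6 < n and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site = MBSPrediction(family.family_id, utr_id, i, i + 7, "8mer")
        elif has_m8:
            site = MBSPrediction(family.family_id, utr_id, i, i + 6, "7mer-m8")
        elif has_a1:
            site = MBSPrediction(family.family_id, utr_id, i + 1, i + 7, "7mer-A1")
        else:
            site = MBSPrediction(family.family_id, utr_id, i + 1, i + 6, "6mer")
        out.append(site)
    return out


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_mature(
    utr_seq: str,
    mature_seq: str,
    scoring: AlignScoring | None = None,
    utr_id: str = "utr",
) -> list[AlignmentPrediction]:
    """Seed-anchored local alignment of a full mature sequence.

    Candidate sites are the exact seed-region complements on the UTR;
    around each, the reverse complement of the mature sequence is aligned
    locally and the prediction is kept when the alignment score reaches
    ``min_score``.  Each prediction carries the seed-site coordinates and
    type so it can enter family-level collapsing.
    """
    scoring = scoring or AlignScoring()
    mature = _dna(mature_seq)
    if len(mature) < 8:
        raise ValueError("mature sequence must be at least 8 nt")
    seq = _dna(utr_seq)
    family = MiRNAFamily("_tmp", mature[1:8], (mature,))
    candidates = seed_sites(seq, family, utr_id)
    if not candidates:
        return []
    aligner = _make_aligner(scoring)
    query = _revcomp(mature)
    out: list[AlignmentPrediction] = []
    pad = len(mature)
    for site in candidates:
        lo = max(0, site.start - 1 - pad)
        hi = min(len(seq), site.end + pad)
        score = aligner.score(seq[lo:hi], query)
        if score >= scoring.min_score:
            out.append(AlignmentPrediction(
                mature, utr_id, site.start, site.end, site.site_type, score,
            ))
    return out


def collapse_predictions(
    alignment_predictions: Iterable[AlignmentPrediction],
    families: Sequence[MiRNAFamily],
) -> list[MBSPrediction]:
    """Collapse mature-level alignments to family level.

    Predictions sharing (family, target UTR, site type, start/end) merge
    into a single family-level prediction; predictions differing in any
    of the four properties stay distinct.
    """
    mature_to_family: dict[str, str] = {}
    for fam in families:
        for m in fam.matures:
            mature_to_family[m] = fam.family_id
    seen: dict[tuple, MBSPrediction] = {}
    for pred in alignment_predictions:
        fid = mature_to_family.get(_dna(pred.mature_seq))
        if fid is None:
            raise ValueError(
                f"mature sequence {pred.mature_seq} is not in any family"
            )
        site = MBSPrediction(fid, pred.utr_id, pred.start, pred.end, pred.site_type)
        seen.setdefault(site.key, site)
    return sorted(seen.values())


def intersect_predictions(
    set_a: Iterable[MBSPrediction],
    set_b: Iterable[MBSPrediction],
) -> list[MBSPrediction]:
    """Predictions whose 4-property key appears in both sets.

    Commutative, idempotent, and a subset of each input.
    """
    keys_b = {p.key for p in set_b}
    seen: dict[tuple, MBSPrediction] = {}
    for p in set_a:
        if p.key in keys_b:
            seen.setdefault(p.key, p)
    return sorted(seen.values())


def predict_mbs(
    utr_seq: str,
    families: Sequence[MiRNAFamily],
    utr_id: str = "utr",
    scoring: AlignScoring | None = None,
) -> list[MBSPrediction]:
    """The intersected family-level MBS annotation of one UTR.

    Runs the seed scanner and the collapsed mature-sequence aligner for
    every family and intersects them on the 4-property key.
    """
    seed_preds: list[MBSPrediction] = []
    align_preds: list[AlignmentPrediction] = []
    for fam in families:
        seed_preds.extend(seed_sites(utr_seq, fam, utr_id))
        for m in fam.matures:
            align_preds.extend(align_mature(utr_seq, m, scoring, utr_id))
    collapsed = collapse_predictions(align_preds, families)
    return intersect_predictions(seed_preds, collapsed)


# ---------------------------------------------------------------------------
# Edits


def apply_edit(utr_seq: str, utr_pos: int) -> str:
    """Replace the adenosine at 1-based ``utr_pos`` with guanosine."""
    seq = _dna(utr_seq)
    if not 1 <= utr_pos <= len(seq):
        raise IndexError(
            f"utr_pos {utr_pos} out of range for sequence of length {len(seq)}"
        )
    if seq[utr_pos - 1] != "A":
        raise ValueError(
            f"base at utr_pos {utr_pos} is {seq[utr_pos - 1]}, expected A"
        )
    return seq[: utr_pos - 1] + "G" + seq[utr_pos:]


@dataclass(frozen=True, slots=True)
class MBSDelta:
    """Effect of one edit on one (gene, family) pair."""

    gene_id: str
    family_id: str
    classification: str  # no_overlaps | site_unchanged | gain | lost | mixed
    introduced: Mapping[str, int] = field(default_factory=dict)
    removed: Mapping[str, int] = field(default_factory=dict)

    @property
    def total_introduced(self) -> int:
        return sum(self.introduced.values())

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())


def classify_delta_counts(
    introduced: Mapping[str, int],
    removed: Mapping[str, int],
    overlaps_any: bool,
) -> str:
    """The five-clause decision cascade over per-transcript counts.

    ``introduced[t]`` / ``removed[t]`` count sites overlapping the edit
    that exist only after / only before the edit on transcript ``t``;
    ``overlaps_any`` says whether the edit falls inside any pre-existing
    site or introduces any new site on any transcript.  Evaluated in
    order: no_overlaps, site_unchanged, gain, lost, mixed — the
    categories are exhaustive and mutually exclusive.
    """
    if set(introduced) != set(removed):
        raise ValueError("introduced and removed must cover the same transcripts")
    if not overlaps_any:
        if any(introduced.values()) or any(removed.values()):
            raise ValueError("overlaps_any is False but counts are nonzero")
        return "no_overlaps"
    diffs = [introduced[t] - removed[t] for t in introduced]
    if all(d == 0 for d in diffs):
        return "site_unchanged"
    if all(d >= 0 for d in diffs):
        return "gain"
    if all(d <= 0 for d in diffs):
        return "lost"
    return "mixed"


def mbs_delta_for_edit(
    utr_variants: Mapping[str, tuple[str, int | None]],
    family: MiRNAFamily,
    gene_id: str = "gene",
    predictor=None,
    whole_transcript: bool = False,
) -> MBSDelta:
    """Classify one edit's MBS effect for one (gene, family) pair.

    ``utr_variants`` maps transcript id -> (3'-UTR sequence, 1-based edit
    position on that UTR, or None when the edit does not fall in that
    transcript's UTR).  ``predictor`` defaults to the seed scanner; pass
    :func:`predict_mbs` partials for the intersected annotation.

    Introduced/removed sites are the pre/post multiset difference of
    site keys.  The default restricts the comparison to sites whose span
    intersects the edit's +/-7 nt neighborhood — every window a single
    substitution can alter — which provably equals the whole-transcript
    difference for window-local predictors; ``whole_transcript`` runs
    the unrestricted comparison for sensitivity analysis.
    """
    if predictor is None:
        predictor = seed_sites
    introduced: dict[str, int] = {}
    removed: dict[str, int] = {}
    overlaps_any = False
    for tid, (seq, pos) in utr_variants.items():
        if pos is None:
            introduced[tid] = removed[tid] = 0
            continue
        pre = predictor(seq, family, tid)
        post = predictor(apply_edit(seq, pos), family, tid)
        if whole_transcript:
            pre_keys = {p.key for p in pre}
            post_keys = {p.key for p in post}
        else:
            lo, hi = pos - 7, pos + 7
            pre_keys = {p.key for p in pre if p.end >= lo and p.start <= hi}
            post_keys = {p.key for p in post if p.end >= lo and p.start <= hi}
        introduced[tid] = len(post_keys - pre_keys)
        removed[tid] = len(pre_keys - post_keys)
        if any(p.overlaps(pos) for p in pre) or any(p.overlaps(pos) for p in post):
            overlaps_any = True
    label = classify_delta_counts(introduced, removed, overlaps_any)
    return MBSDelta(gene_id, family.family_id, label, introduced, removed)


# ---------------------------------------------------------------------------
# Cohort summary


def per_pair_mbs_table(
    classified_deltas: Mapping[tuple[tuple[str, int], str, str], str],
    per_sample_edits: Mapping[str, Iterable[tuple[str, int]]],
    dense_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(gene, sample) MBS gain/loss counts.

    ``classified_deltas`` maps (edit site, gene, family) -> classification.
    For each sample, every (edit, family) delta whose edit the sample
    observes contributes to its gene's row: gains count ``gain`` deltas,
    losses count ``lost`` deltas, net = gains - losses.  With
    ``dense_genes`` the table includes zero rows for every listed gene in
    every sample.
    """
    site_deltas: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for (site, gene, _family), label in classified_deltas.items():
        site_deltas.setdefault(site, []).append((gene, label))
    rows: dict[tuple[str, str], dict] = {}

    def row(gene: str, sample: str) -> dict:
        return rows.setdefault(
            (gene, sample),
            {"gene_id": gene, "sample_id": sample, "gains": 0, "losses": 0},
        )

    for sample in sorted(per_sample_edits):
        for site in set(per_sample_edits[sample]):
            for gene, label in site_deltas.get(site, ()):
                r = row(gene, sample)
                if label == "gain":
                    r["gains"] += 1
                elif label == "lost":
                    r["losses"] += 1
    if dense_genes is not None:
        for sample in per_sample_edits:
            for gene in dense_genes:
                row(gene, sample)
    df = pd.DataFrame(
        list(rows.values()) or [],
        columns=["gene_id", "sample_id", "gains", "losses"],
    )
    df["net"] = df["gains"] - df["losses"]
    return df.sort_values(["gene_id", "sample_id"], kind="mergesort").reset_index(drop=True)
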