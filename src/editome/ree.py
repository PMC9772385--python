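"""Recurrent Embryonic Edits (REEs): per-stage detection, REE-targeted
genes, stage-transition persistence, editing-expression correlation, and
phenotype-specific complete-loss scans.

An REE is an accepted edit observed in at least ``ree_fraction`` (default
50%) of a stage's normal samples.  A gene is REE-targeted in a stage when
at least one of its REEs is observed in at least ``gene_fraction``
(default 80%) of that stage's normal samples, with the union taken over
the gene's REEs within each sample.  The loss scan examines, for each of
12 (stage, abnormal-condition) groups, which of the stage's REEs were
never detected in that group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SampleMeta

__all__ = [
    "REESet",
    "StageFlow",
    "LossScanResult",
    "DEFAULT_GROUP_SPECS",
    "detect_rees",
    "detect_ree_targeted_genes",
    "stage_flow",
    "ree_expression_correlation",
    "scan_loss",
]

Site = tuple[str, int]

#: the 12 (stage, condition) comparisons of the complete-loss scan
DEFAULT_GROUP_SPECS: tuple[tuple[str, str], ...] = (
    ("oocyte_GV", "elder_mother"),
    ("oocyte_MII", "elder_mother"),
    ("zygote", "AG"),
    ("zygote", "PG"),
    ("2cell", "AG"),
    ("2cell", "PG"),
    ("4cell", "AG"),
    ("4cell", "PG"),
    ("8cell", "AG"),
    ("8cell", "PG"),
    ("morula", "AG"),
    ("morula", "PG"),
)


@dataclass
class REESet:
    """Per-stage REEs with their observation fractions."""

    stage: str
    fractions: dict[Site, float]
    ree_fraction: float
    n_samples: int  # normal samples of the stage

    @property
    def sites(self) -> set[Site]:
        return set(self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)

    def __contains__(self, site: Site) -> bool:
        return site in self.fractions


@dataclass(frozen=True, slots=True)
class StageFlow:
    """Fate of one stage's REEs at the next stage; counts conserve."""

    source_stage: str
    target_stage: str
    remained_ree: int
    detected_not_ree: int
    not_detected: int

    @property
    def total(self) -> int:
        return self.remained_ree + self.detected_not_ree + self.not_detected


@dataclass(frozen=True, slots=True)
class LossScanResult:
    """One REE reported lost (or nearly lost) in one abnormal group."""

    site: Site
    stage: str
    condition: str
    n_group_samples: int
    n_detected: int


def _normal_samples(sample_meta: Mapping[str, SampleMeta], stage: str) -> list[str]:
    return sorted(
        s for s, m in sample_meta.items() if m.stage == stage and m.is_normal
    )


def detect_rees(
    per_sample_edits: Mapping[str, Iterable[Site]],
    sample_meta: Mapping[str, SampleMeta],
    stage: str,
    ree_fraction: float = 0.5,
) -> REESet:
    """Sites observed in >= ``ree_fraction`` of the stage's normal samples.

    Abnormal samples are excluded from both numerator and denominator.
    The denominator is all normal samples of the stage regardless of
    per-site read coverage.
    """
    if not 0 < ree_fraction <= 1:
        raise ValueError("ree_fraction must be in (0, 1]")
    normals = _normal_samples(sample_meta, stage)
    if not normals:
        raise ValueError(f"stage {stage!r} has no normal samples")
    counts: dict[Site, int] = {}
    for sample in normals:
        for site in set(per_sample_edits.get(sample, ())):
            counts[site] = counts.get(site, 0) + 1
    n = len(normals)
    fractions = {
        site: c / n for site, c in counts.items() if c / n >= ree_fraction
    }
    return REESet(stage, fractions, ree_fraction, n)


def detect_ree_targeted_genes(
    rees: REESet,
    per_sample_edits: Mapping[str, Iterable[Site]],
    sample_meta: Mapping[str, SampleMeta],
    site_to_gene: Mapping[Site, str | Iterable[str]],
    gene_fraction: float = 0.8,
) -> dict[str, float]:
    """Genes edited by >= 1 REE in >= ``gene_fraction`` of the stage's
    normal samples; returns gene -> fraction for the targeted genes.

    Within each sample, the union over the gene's REEs counts: a sample
    observing any one of them marks the gene edited in that sample.
    """
    if not 0 < gene_fraction <= 1:
        raise ValueError("gene_fraction must be in (0, 1]")
    gene_rees: dict[str, set[Site]] = {}
    for site in rees.sites:
        genes = site_to_gene.get(site)
        if genes is None:
            continue
        if isinstance(genes, str):
            genes = (genes,)
        for g in genes:
            gene_rees.setdefault(g, set()).add(site)
    normals = _normal_samples(sample_meta, rees.stage)
    n = len(normals)
    observed = {s: set(per_sample_edits.get(s, ())) for s in normals}
    out: dict[str, float] = {}
    for gene, sites in gene_rees.items():
        hit = sum(1 for s in normals if observed[s] & sites)
        frac = hit / n
        if frac >= gene_fraction:
            out[gene] = frac
    return out


def stage_flow(
    rees_source: REESet,
    rees_target: REESet,
    per_sample_edits_target: Mapping[str, Iterable[Site]],
    sample_meta: Mapping[str, SampleMeta],
) -> StageFlow:
    """Classify each source-stage REE at the target stage.

    remained_REE: in the target REE set; detected_not_REE: observed in at
    least one target-stage normal sample but below threshold;
    not_detected: otherwise.  Counts sum to the source REE set size.
    """
    target_normals = _normal_samples(sample_meta, rees_target.stage)
    detected_union: set[Site] = set()
    for s in target_normals:
        detected_union |= set(per_sample_edits_target.get(s, ()))
    remained = detected = lost = 0
    for site in rees_source.sites:
        if site in rees_target:
            remained += 1
        elif site in detected_union:
            detected += 1
        else:
            lost += 1
    return StageFlow(rees_source.stage, rees_target.stage, remained, detected, lost)


def ree_expression_correlation(
    ree_af: pd.DataFrame,
    fpkm: pd.DataFrame,
    site_to_gene: Mapping[Site, str],
    samples: Sequence[str] | None = None,
    method: str = "spearman",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Correlate per-sample editing level of each REE with the expression
    of its targeted gene.

    ``ree_af`` is indexed by site (rows) with samples as columns (NaN
    where undetected); ``fpkm`` is gene x sample.  The default is a rank
    (Spearman) correlation.  Rows with fewer than ``min_pairs`` paired
    observations, or constant AF/FPKM, are reported undefined with a
    reason.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for site in ree_af.index:
        gene = site_to_gene.get(tuple(site) if not isinstance(site, tuple) else site)
        rec = {"chrom": site[0], "pos": site[1], "gene_id": gene,
               "coefficient": np.nan, "p_value": np.nan, "n": 0, "note": ""}
        if gene is None or gene not in fpkm.index:
            rec["note"] = "no_gene_mapping"
            rows.append(rec)
            continue
        af = ree_af.loc[[site]].iloc[0]
        expr = fpkm.loc[gene]
        common = af.dropna().index.intersection(expr.dropna().index)
        if samples is not None:
            common = common.intersection(samples)
        x = af[common].to_numpy(dtype=float)
        y = expr[common].to_numpy(dtype=float)
        rec["n"] = len(common)
        if len(common) < min_pairs:
            rec["note"] = "too_few_pairs"
        elif np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rec["note"] = "constant_input"
        else:
            res = corr_fn(x, y)
            rec["coefficient"] = float(res.statistic)
            rec["p_value"] = float(res.pvalue)
        rows.append(rec)
    return pd.DataFrame(rows)


def scan_loss(
    rees_by_stage: Mapping[str, REESet],
    per_sample_edits: Mapping[str, Iterable[Site]],
    sample_meta: Mapping[str, SampleMeta],
    group_specs: Sequence[tuple[str, str]] | None = None,
    max_detection_fraction: float = 0.0,
) -> list[LossScanResult]:
    """Scan for REEs lost in abnormal groups.

    For each (stage, condition) group, report the stage's REEs detected
    in at most ``max_detection_fraction`` of the group's samples (the
    default 0 demands complete loss).  "Detected" mirrors the normal-
    sample definition: the site passed per-call filters in that sample.
    Groups with no samples are skipped with a warning.
    """
    if group_specs is None:
        group_specs = DEFAULT_GROUP_SPECS
    results: list[LossScanResult] = []
    for stage, condition in group_specs:
        group = sorted(
            s for s, m in sample_meta.items()
            if m.stage == stage and m.condition == condition
        )
        if not group:
            warnings.warn(
                f"loss scan: no samples for group ({stage}, {condition}); skipped",
                stacklevel=2,
            )
            continue
        rees = rees_by_stage.get(stage)
        if rees is None:
            continue
        observed = {s: set(per_sample_edits.get(s, ())) for s in group}
        for site in sorted(rees.sites):
            n_det = sum(1 for s in group if site in observed[s])
            if n_det / len(group) <= max_detection_fraction:
                results.append(
                    LossScanResult(site, stage, condition, len(group), n_det)
                )
    return results
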