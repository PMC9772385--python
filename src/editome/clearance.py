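"""Maternal-gene and clearance-target annotation plus the rank-based
enrichment statistics.

A gene is maternal when its median FPKM exceeds 2 in at least one of the
oocyte (GV) and oocyte (MII) stages (strict inequality, normal samples
only).  A maternal gene is a clearance target ("decay at 8-cell") when
the smaller of its GV/MII medians is more than twice its 8-cell median.

The tests are a chi-square independence test on MBS-gaining frequency
(REE vs non-REE among MBS-overlapping edits), a one-tailed paired
signed-rank test of per-(gene, sample) gains vs losses, and one-tailed
unpaired rank-sum tests comparing the per-pair MBS-gain statistic
between clearance targets and other maternal genes.  Families of raw p
values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleMeta

__all__ = [
    "MaternalAnnotation",
    "TestResult",
    "annotate_maternal",
    "annotate_clearance",
    "chi_square_mbs_gain",
    "wilcoxon_paired_one_tailed",
    "wilcoxon_unpaired_one_tailed",
    "bh_adjust",
]


@dataclass(frozen=True, slots=True)
class MaternalAnnotation:
    gene_id: str
    median_gv: float
    median_mii: float
    median_8cell: float
    maternal: bool
    clearance_group: str  # decay_at_8cell | others | not_maternal


@dataclass(slots=True)
class TestResult:
    """One statistical comparison with its estimate and bound."""

    test: str
    statistic: float
    alternative: str
    p_value: float
    n: tuple[int, ...]
    p_adjusted: float | None = None
    estimate: float | None = None
    conf_lower: float | None = None
    note: str = ""


def _stage_samples(
    sample_meta: Mapping[str, SampleMeta], stage: str, columns
) -> list[str]:
    return [
        s for s, m in sample_meta.items()
        if m.stage == stage and m.is_normal and s in columns
    ]


def annotate_maternal(
    expr: pd.DataFrame,
    sample_meta: Mapping[str, SampleMeta],
    fpkm_cut: float = 2.0,
    gv_stage: str = "oocyte_GV",
    mii_stage: str = "oocyte_MII",
    eight_cell_stage: str = "8cell",
) -> pd.DataFrame:
    """Per-gene stage medians and the maternal flag.

    ``expr`` is gene x sample FPKM.  Maternal iff the median over normal
    GV samples or over normal MII samples is strictly greater than
    ``fpkm_cut``.  Raises when any of the three required stages has no
    normal sample in the matrix.
    """
    medians = {}
    for label, stage in (("median_gv", gv_stage), ("median_mii", mii_stage),
                         ("median_8cell", eight_cell_stage)):
        cols = _stage_samples(sample_meta, stage, expr.columns)
        if not cols:
            raise ValueError(f"no normal {stage} samples in expression matrix")
        medians[label] = expr[cols].median(axis=1)
    out = pd.DataFrame(medians, index=expr.index)
    out.index.name = "gene_id"
    out["maternal"] = (out["median_gv"] > fpkm_cut) | (out["median_mii"] > fpkm_cut)
    return out


def annotate_clearance(
    maternal_df: pd.DataFrame,
    decay_fold: float = 2.0,
) -> pd.DataFrame:
    """Assign clearance groups to annotated genes.

    A maternal gene is ``decay_at_8cell`` iff
    min(median_gv, median_mii) > decay_fold * median_8cell (strict);
    other maternal genes are ``others``; the rest ``not_maternal``.
    """
    df = maternal_df.copy()
    smaller = df[["median_gv", "median_mii"]].min(axis=1)
    decays = smaller > decay_fold * df["median_8cell"]
    df["clearance_group"] = np.where(
        ~df["maternal"], "not_maternal",
        np.where(decays, "decay_at_8cell", "others"),
    )
    return df


# ---------------------------------------------------------------------------
# Tests


def chi_square_mbs_gain(
    edits: pd.DataFrame,
    correction: bool = False,
) -> list[TestResult]:
    """Per-stage chi-square test of MBS-gaining frequency, REE vs non-REE.

    ``edits`` needs boolean columns ``is_ree`` and ``is_gain`` plus a
    ``stage`` column, one row per MBS-overlapping edit.  The null is that
    being MBS-gaining is independent of REE status; the partition is the
    disjoint REE vs non-REE split (a valid 2x2 independence test).
    Stages with a zero margin are skipped with a reason; p values are BH
    adjusted across the tested stages.
    """
    required = {"stage", "is_ree", "is_gain"}
    if missing := required - set(edits.columns):
        raise ValueError(f"edits table missing columns {sorted(missing)}")
    results: list[TestResult] = []
    tested: list[TestResult] = []
    for stage, sub in edits.groupby("stage", sort=True):
        table = np.asarray([
            [int(((sub.is_ree) & (sub.is_gain)).sum()),
             int(((sub.is_ree) & (~sub.is_gain)).sum())],
            [int(((~sub.is_ree) & (sub.is_gain)).sum()),
             int(((~sub.is_ree) & (~sub.is_gain)).sum())],
        ])
        res = TestResult(
            test="chi_square_mbs_gain", statistic=float("nan"),
            alternative="two-sided", p_value=float("nan"),
            n=tuple(int(x) for x in table.sum(axis=1)), note=str(stage),
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            res.note = f"{stage}: skipped (zero margin)"
            results.append(res)
            continue
        chi2 = stats.chi2_contingency(table, correction=correction)
        res.statistic = float(chi2.statistic)
        res.p_value = float(chi2.pvalue)
        results.append(res)
        tested.append(res)
    if tested:
        adjusted = bh_adjust([r.p_value for r in tested])
        for r, adj in zip(tested, adjusted):
            r.p_adjusted = float(adj)
    return results


def _signrank_cdf(k: float, n: int) -> float:
    """Exact P(W+ <= k) for the signed-rank statistic, by counting subset
    sums of {1..n}."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()
    return counts[: int(np.floor(k)) + 1].sum() / total


def _signrank_quantile(alpha: float, n: int) -> int:
    """Largest k with exact P(W+ <= k) <= alpha (0 when none)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    cdf = np.cumsum(counts) / counts.sum()
    ks = np.nonzero(cdf <= alpha)[0]
    return int(ks[-1]) if len(ks) else 0


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    pair = (d[:, None] + d[None, :]) / 2.0
    iu = np.triu_indices(len(d))
    return np.sort(pair[iu])


def wilcoxon_paired_one_tailed(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "wilcox",
    conf_level: float = 0.95,
) -> TestResult:
    """Paired one-tailed signed-rank test, alternative: x greater than y.

    Implemented as the one-sample signed-rank test on the differences.
    Zero differences are dropped by default (``wilcox``); ``pratt`` keeps
    them in the ranking.  Exact p for n <= 25 without ties; normal
    approximation with tie correction otherwise.  Reports the
    Hodges-Lehmann pseudomedian of the differences and the one-sided
    lower confidence bound derived from the signed-rank distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align on the same pairs")
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    d = x - y
    nonzero = d[d != 0]
    result = TestResult(
        test="wilcoxon_paired", statistic=float("nan"), alternative="greater",
        p_value=1.0, n=(len(d),),
    )
    if len(nonzero) == 0:
        result.note = "degenerate: all differences zero"
        result.estimate = 0.0
        return result
    n_eff = len(nonzero)
    has_ties = len(np.unique(np.abs(nonzero))) < n_eff
    use_exact = n_eff <= 25 and not has_ties and (zero_method == "wilcox" or len(d) == n_eff)
    res = stats.wilcoxon(
        d, zero_method=zero_method, alternative="greater",
        method="exact" if use_exact else "approx",
    )
    result.statistic = float(res.statistic)
    result.p_value = float(res.pvalue)

    walsh = _walsh_averages(nonzero)
    result.estimate = float(np.median(walsh))
    alpha = 1.0 - conf_level
    if n_eff <= 25:
        qu = _signrank_quantile(alpha, n_eff)
    else:
        mean = n_eff * (n_eff + 1) / 4.0
        sd = np.sqrt(n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0)
        qu = max(0, int(np.floor(mean + stats.norm.ppf(alpha) * sd)))
    qu = min(qu, len(walsh) - 1)
    result.conf_lower = float(walsh[qu])
    return result


def wilcoxon_unpaired_one_tailed(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    conf_level: float = 0.95,
    max_pairs: int = 4_000_000,
) -> TestResult:
    """One-tailed rank-sum (Mann-Whitney) test, alternative: x greater.

    Exact p for small untied samples, normal approximation with tie
    correction otherwise.  Reports the Hodges-Lehmann shift estimate
    (median of pairwise differences) and the one-sided lower confidence
    bound.  With ``y=None`` the comparison degenerates to a one-sample
    signed-rank test of x against a 0 baseline.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        res = wilcoxon_paired_one_tailed(x, np.zeros_like(x), conf_level=conf_level)
        res.test = "wilcoxon_one_sample_vs_zero"
        return res
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    mw = stats.mannwhitneyu(x, y, alternative="greater", method="auto")
    result = TestResult(
        test="wilcoxon_unpaired", statistic=float(mw.statistic),
        alternative="greater", p_value=float(mw.pvalue), n=(len(x), len(y)),
    )
    n, m = len(x), len(y)
    rng = np.random.default_rng(0)
    if n * m <= max_pairs:
        diffs = np.sort((x[:, None] - y[None, :]).ravel())
    else:  # subsample pairs for the estimate on very large inputs
        xi = rng.choice(x, size=2000)
        yi = rng.choice(y, size=2000)
        diffs = np.sort((xi[:, None] - yi[None, :]).ravel())
    result.estimate = float(np.median(diffs))
    alpha = 1.0 - conf_level
    mean = n * m / 2.0
    sd = np.sqrt(n * m * (n + m + 1) / 12.0)
    k = int(np.floor(mean + stats.norm.ppf(alpha) * sd))
    k = min(max(k, 0), len(diffs) - 1)
    result.conf_lower = float(diffs[k])
    return result


def clearance_enrichment(
    annotated: pd.DataFrame,
    pair_counts: pd.DataFrame,
    value_column: str = "gains",
) -> list[TestResult]:
    """Compare the per-(gene, sample) MBS-gain statistic between
    clearance targets and other maternal genes.

    ``annotated`` is the output of :func:`annotate_clearance`;
    ``pair_counts`` needs columns gene_id, sample_id and the value
    column.  Returns the one-tailed decay-vs-others rank-sum test and
    the decay-vs-zero-baseline signed-rank comparison.
    """
    groups = annotated["clearance_group"]
    decay_genes = set(groups.index[groups == "decay_at_8cell"])
    other_genes = set(groups.index[groups == "others"])
    x = pair_counts.loc[pair_counts["gene_id"].isin(decay_genes), value_column]
    y = pair_counts.loc[pair_counts["gene_id"].isin(other_genes), value_column]
    res_pair = wilcoxon_unpaired_one_tailed(x.to_numpy(float), y.to_numpy(float))
    res_pair.note = "decay_at_8cell vs others"
    res_zero = wilcoxon_unpaired_one_tailed(x.to_numpy(float), None)
    res_zero.note = "decay_at_8cell vs 0 baseline"
    return [res_pair, res_zero]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order.

    Sort ascending, multiply p(i) by m/i, enforce monotonicity by the
    cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
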