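import numpy as np
import pandas as pd
import pytest

from editome.io_formats import SampleMeta
from editome.ree import (
    REESet,
    detect_ree_targeted_genes,
    detect_rees,
    ree_expression_correlation,
    scan_loss,
    stage_flow,
)

S1 = ("chr1", 100)
S2 = ("chr1", 200)
S3 = ("chr1", 300)


def _meta(n_normal=10, stage="zygote", n_abnormal=0, cond="AG"):
    meta = {}
    for i in range(n_normal):
        sid = f"{stage}_N{i}"
        meta[sid] = SampleMeta(sid, stage, "normal")
    for i in range(n_abnormal):
        sid = f"{stage}_{cond}{i}"
        meta[sid] = SampleMeta(sid, stage, cond)
    return meta


def _edits(meta, site_in_first_k, site=S1, stage=None):
    """site observed in the first k samples (sorted) of the stage."""
    samples = sorted(meta)
    return {s: {site} if i < site_in_first_k else set()
            for i, s in enumerate(samples)}


class TestDetectRees:
    def test_half_of_samples_is_enough(self):
        meta = _meta(10)
        per = _edits(meta, 5)
        rees = detect_rees(per, meta, "zygote")
        assert S1 in rees and rees.fractions[S1] == 0.5

    def test_below_threshold_excluded(self):
        meta = _meta(10)
        assert S1 not in detect_rees(_edits(meta, 4), meta, "zygote")

    def test_threshold_is_configurable_and_monotone(self):
        meta = _meta(10)
        per = _edits(meta, 7)
        assert S1 in detect_rees(per, meta, "zygote", ree_fraction=0.5)
        assert S1 not in detect_rees(per, meta, "zygote", ree_fraction=0.8)

    def test_abnormal_samples_excluded_from_both_sides(self):
        meta = _meta(4, n_abnormal=6)
        # observed in 2 of 4 normals and all 6 abnormals
        per = {s: {S1} for s in meta if "AG" in s}
        per.update({f"zygote_N{i}": {S1} if i < 2 else set() for i in range(4)})
        rees = detect_rees(per, meta, "zygote")
        assert rees.n_samples == 4 and rees.fractions[S1] == 0.5

    def test_stage_without_normals_is_error(self):
        meta = _meta(0, n_abnormal=3)
        with pytest.raises(ValueError, match="no normal samples"):
            detect_rees({}, meta, "zygote")

    def test_ree_set_shrinks_as_threshold_rises(self):
        rng = np.random.default_rng(5)
        meta = _meta(12)
        sites = [("chr1", int(p)) for p in range(10, 400, 10)]
        per = {s: {site for site in sites if rng.random() < 0.6}
               for s in meta}
        previous = None
        for frac in (0.3, 0.5, 0.7, 0.9):
            current = detect_rees(per, meta, "zygote", frac).sites
            if previous is not None:
                assert current <= previous
            previous = current


class TestTargetedGenes:
    def test_single_ree_fraction_thresholds(self):
        meta = _meta(10)
        mapping = {S1: "G1"}
        rees = detect_rees(_edits(meta, 8), meta, "zygote")
        hit = detect_ree_targeted_genes(rees, _edits(meta, 8), meta, mapping)
        assert hit == {"G1": 0.8}
        rees7 = detect_rees(_edits(meta, 7), meta, "zygote")
        assert detect_ree_targeted_genes(rees7, _edits(meta, 7), meta, mapping) == {}

    def test_per_sample_union_over_gene_rees(self):
        meta = _meta(10)
        samples = sorted(meta)
        # r1 in samples 0-5 (6/10), r2 in samples 4-8 (5/10); union covers 9
        per = {s: set() for s in samples}
        for i in range(0, 6):
            per[samples[i]].add(S1)
        for i in range(4, 9):
            per[samples[i]].add(S2)
        rees = detect_rees(per, meta, "zygote")
        assert rees.sites == {S1, S2}
        hit = detect_ree_targeted_genes(rees, per, meta, {S1: "G1", S2: "G1"})
        assert hit == {"G1": 0.9}
        # neither REE alone reaches 80%
        assert detect_ree_targeted_genes(rees, per, meta, {S1: "G1"}) == {}


class TestStageFlow:
    def test_three_fates_and_conservation(self):
        meta_t = _meta(12, stage="2cell")
        source = REESet("zygote", {S1: 0.9, S2: 0.8, S3: 0.7}, 0.5, 10)
        target = REESet("2cell", {S1: 0.6}, 0.5, 12)
        per_t = {s: set() for s in meta_t}
        per_t["2cell_N0"] = {S2}  # S2 seen once: detected but not REE
        flow = stage_flow(source, target, per_t, meta_t)
        assert (flow.remained_ree, flow.detected_not_ree, flow.not_detected) == (1, 1, 1)
        assert flow.total == len(source)

    def test_conservation_on_fuzzed_cohorts(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            meta_s = _meta(8, stage="zygote")
            meta_t = _meta(8, stage="2cell")
            sites = [("chr1", int(p)) for p in rng.choice(5000, 40, replace=False)]
            per_s = {s: {x for x in sites if rng.random() < 0.5} for s in meta_s}
            per_t = {s: {x for x in sites if rng.random() < 0.3} for s in meta_t}
            src = detect_rees(per_s, meta_s, "zygote")
            tgt = detect_rees(per_t, meta_t, "2cell")
            flow = stage_flow(src, tgt, per_t, meta_t)
            assert flow.total == len(src)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        af = pd.DataFrame([[0.1, 0.2, 0.3]], index=[S1], columns=list("abc"))
        fpkm = pd.DataFrame([[30.0, 20.0, 10.0]], index=["G1"], columns=list("abc"))
        out = ree_expression_correlation(af, fpkm, {S1: "G1"})
        assert out.loc[0, "coefficient"] == pytest.approx(-1.0)

    def test_degenerate_inputs_reported_undefined(self):
        af = pd.DataFrame([[0.1, 0.2, 0.3]], index=[S1], columns=list("abc"))
        flat = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G1"], columns=list("abc"))
        out = ree_expression_correlation(af, flat, {S1: "G1"})
        assert np.isnan(out.loc[0, "coefficient"])
        assert out.loc[0, "note"] == "constant_input"
        short = pd.DataFrame([[0.1, np.nan, np.nan]], index=[S1], columns=list("abc"))
        out = ree_expression_correlation(short, flat, {S1: "G1"})
        assert out.loc[0, "note"] == "too_few_pairs"

    def test_planted_negative_coupling_recovered(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(20)]
        sites = [("chr1", 10 * i) for i in range(15)]
        af = pd.DataFrame(rng.uniform(0.05, 0.95, (15, 20)),
                          index=sites, columns=samples)
        fpkm = pd.DataFrame(
            50.0 - 40.0 * af.values + rng.normal(0, 2.0, (15, 20)),
            index=[f"G{i}" for i in range(15)], columns=samples)
        out = ree_expression_correlation(
            af, fpkm, {s: f"G{i}" for i, s in enumerate(sites)})
        assert out["coefficient"].median() < -0.5


class TestScanLoss:
    def _cohort(self):
        meta = {}
        for i in range(6):
            sid = f"zygote_N{i}"
            meta[sid] = SampleMeta(sid, "zygote", "normal")
        for cond in ("AG", "PG"):
            for i in range(4):
                sid = f"zygote_{cond}{i}"
                meta[sid] = SampleMeta(sid, "zygote", cond)
        per = {s: {S1, S2} for s in meta if "N" in s}
        for s in meta:
            if "AG" in s:
                per[s] = {S2}          # S1 completely lost in AG
            elif "PG" in s:
                per[s] = {S1, S2} if s.endswith("0") else set()
        return meta, per

    def test_complete_loss_reported_with_group_label(self):
        meta, per = self._cohort()
        rees = {"zygote": detect_rees(per, meta, "zygote")}
        with pytest.warns(UserWarning):  # other groups have no samples
            results = scan_loss(rees, per, meta)
        assert {(r.site, r.stage, r.condition) for r in results} == {
            (S1, "zygote", "AG"),
        }
        (row,) = results
        assert row.n_detected == 0 and row.n_group_samples == 4

    def test_single_detection_blocks_default_report(self):
        meta, per = self._cohort()
        rees = {"zygote": detect_rees(per, meta, "zygote")}
        results = scan_loss(rees, per, meta,
                            group_specs=[("zygote", "PG")])
        assert results == []  # S1/S2 each seen once in PG
        near = scan_loss(rees, per, meta, group_specs=[("zygote", "PG")],
                         max_detection_fraction=0.25)
        assert {r.site for r in near} == {S1, S2}

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(21)
        meta, per = self._cohort()
        sites = [("chr1", int(p)) for p in range(1000, 1200, 10)]
        for s in meta:
            per[s] = {x for x in sites if rng.random() < (0.7 if "N" in s else 0.2)}
        rees = {"zygote": detect_rees(per, meta, "zygote")}
        results = scan_loss(rees, per, meta,
                            group_specs=[("zygote", "AG"), ("zygote", "PG")])
        for cond in ("AG", "PG"):
            group_union = set()
            for s in meta:
                if cond in s:
                    group_union |= per[s]
            expected = {x for x in rees["zygote"].sites if x not in group_union}
            got = {r.site for r in results if r.condition == cond}
            assert got == expected
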