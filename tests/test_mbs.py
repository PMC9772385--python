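import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editome.mbs import (
    AlignScoring,
    AlignmentPrediction,
    MBSPrediction,
    MiRNAFamily,
    align_mature,
    apply_edit,
    classify_delta_counts,
    collapse_predictions,
    intersect_predictions,
    mbs_delta_for_edit,
    per_pair_mbs_table,
    predict_mbs,
    seed_sites,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracle: base-pairing simulation, no shared code

_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


def _pairs(mirna_base: str, target_base: str) -> bool:
    return (mirna_base, target_base) in _PAIR


def oracle_scan(utr: str, seed: str):
    """Enumerate seed-match sites by simulating antiparallel pairing of
    miRNA positions 2-8 against every target window."""
    utr = utr.upper().replace("U", "T")
    seed = seed.upper().replace("U", "T")
    n = len(utr)
    sites = []
    for i in range(n - 5):
        # target base at offset k pairs miRNA seed position 7-k
        if not all(_pairs(seed[5 - k], utr[i + k]) for k in range(6)):
            continue
        m8 = i >= 1 and _pairs(seed[6], utr[i - 1])
        a1 = i + 6 < n and utr[i + 6] == "A"
        if m8 and a1:
            sites.append(("8mer", i, i + 7))
        elif m8:
            sites.append(("7mer-m8", i, i + 6))
        elif a1:
            sites.append(("7mer-A1", i + 1, i + 7))
        else:
            sites.append(("6mer", i + 1, i + 6))
    return sites


def oracle_delta(utr: str, pos: int, seed: str) -> str:
    """Independent five-clause classification for one transcript via a
    full pre/post window scan (global multiset difference)."""
    assert utr[pos - 1] == "A"
    post = utr[: pos - 1] + "G" + utr[pos:]
    pre_all = set(oracle_scan(utr, seed))
    post_all = set(oracle_scan(post, seed))
    introduced = len(post_all - pre_all)
    removed = len(pre_all - post_all)
    falls_into = any(s[1] <= pos <= s[2] for s in pre_all | post_all)
    if not falls_into:
        return "no_overlaps"
    if introduced == removed:
        return "site_unchanged"
    if introduced > removed:
        return "gain"
    return "lost"


def _random_utr_with_motifs(rng, family, length):
    """Random UTR sometimes seeded with near-site motifs so every
    category is exercised."""
    seq = list(rng.choice(list("ACGT"), length))
    target = "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[b]
                     for b in reversed(family.seed)) + "A"
    for _ in range(rng.integers(0, 3)):
        start = int(rng.integers(0, length - len(target)))
        motif = list(target)
        if rng.random() < 0.6:  # break a position so the edit can matter
            j = int(rng.integers(len(motif)))
            motif[j] = str(rng.choice(list("ACGT")))
        seq[start:start + len(target)] = motif
    return "".join(seq)


LET7 = MiRNAFamily("let-7", "GAGGUAG",
                   ("UGAGGUAGUAGGUUGUAUAGUU",))


class TestSeedSites:
    def test_let7_8mer_site(self):
        utr = "AAAA" + "CTACCTCA" + "GGGG"
        (site,) = seed_sites(utr, LET7)
        assert site.site_type == "8mer"
        assert (site.start, site.end) == (5, 12)
        assert utr[site.start - 1: site.end] == "CTACCTCA"

    @pytest.mark.parametrize(
        "left,right,expected",
        [
            ("C", "A", "8mer"),      # m8 match (C pairs seed position 8 G) and A1
            ("C", "G", "7mer-m8"),
            ("G", "A", "7mer-A1"),
            ("G", "G", "6mer"),
        ],
    )
    def test_site_type_taxonomy(self, left, right, expected):
        # core TACCTC pairs let-7 seed positions 2-7; the base 5' of it
        # pairs seed position 8 (G) only when it is C; a 3' A is the A1
        utr = "CCCC" + left + "TACCTC" + right + "CCCC"
        (site,) = seed_sites(utr, LET7)
        assert site.site_type == expected

    def test_degenerate_sequences(self):
        assert seed_sites("", LET7) == []
        assert seed_sites("AAAAAAAAAAAA", LET7) == []
        assert seed_sites("ACGT", LET7) == []

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_pairing_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(6, 200))
        utr = _random_utr_with_motifs(rng, LET7, length)
        got = {(s.site_type, s.start, s.end) for s in seed_sites(utr, LET7)}
        assert got == set(oracle_scan(utr, LET7.seed))


class TestAlignMature:
    def test_perfect_complement_recovers_seed_site(self):
        mature = LET7.matures[0]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
        target = "".join(comp[b] for b in reversed(mature))
        utr = "CCCCC" + target + "CCCCC"
        preds = align_mature(utr, mature)
        assert preds
        seed_based = seed_sites(utr, LET7)
        assert {(p.start, p.end, p.site_type) for p in preds} >= {
            (s.start, s.end, s.site_type) for s in seed_based
        }

    def test_no_seed_complement_means_no_predictions(self):
        assert align_mature("CCCCCCCCCCCCCCCC", LET7.matures[0]) == []

    def test_unreachable_min_score_empty(self):
        mature = LET7.matures[0]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
        utr = "".join(comp[b] for b in reversed(mature))
        scoring = AlignScoring(min_score=2.0 * len(mature) + 1)
        assert align_mature(utr, mature, scoring) == []


class TestCollapseAndIntersect:
    def test_family_members_collapse_on_shared_key(self):
        fam = MiRNAFamily("F", "GAGGTAG", ("TGAGGTAGAAAAAAAAAAAAA",
                                           "AGAGGTAGCCCCCCCCCCCCC"))
        preds = [
            AlignmentPrediction(fam.matures[0], "utr1", 5, 11, "7mer-m8", 30),
            AlignmentPrediction(fam.matures[1], "utr1", 5, 11, "7mer-m8", 28),
        ]
        assert len(collapse_predictions(preds, [fam])) == 1

    def test_differing_site_type_or_coordinates_stay_distinct(self):
        fam = MiRNAFamily("F", "GAGGTAG", ("TGAGGTAGAAAAAAAAAAAAA",))
        m = fam.matures[0]
        preds = [
            AlignmentPrediction(m, "utr1", 5, 11, "7mer-m8", 30),
            AlignmentPrediction(m, "utr1", 6, 12, "7mer-A1", 30),
            AlignmentPrediction(m, "utr1", 8, 14, "7mer-m8", 30),
        ]
        assert len(collapse_predictions(preds, [fam])) == 3

    def test_unknown_mature_sequence_is_error(self):
        fam = MiRNAFamily("F", "GAGGTAG", ("TGAGGTAGAAAAAAAAAAAAA",))
        stranger = AlignmentPrediction("TTTTTTTTTTTTTTTTTTTTT", "u", 1, 6, "6mer", 30)
        with pytest.raises(ValueError, match="not in any family"):
            collapse_predictions([stranger], [fam])

    def test_intersection_properties(self):
        a = [MBSPrediction("F", "u", 1, 6, "6mer"),
             MBSPrediction("F", "u", 9, 14, "6mer"),
             MBSPrediction("G", "u", 1, 7, "7mer-m8")]
        b = [MBSPrediction("F", "u", 9, 14, "6mer"),
             MBSPrediction("H", "u", 3, 8, "6mer")]
        inter = intersect_predictions(a, b)
        assert inter == [MBSPrediction("F", "u", 9, 14, "6mer")]
        assert intersect_predictions(b, a) == inter           # commutative
        assert intersect_predictions(inter, inter) == inter   # idempotent
        assert set(inter) <= set(a) and set(inter) <= set(b)  # subset
        assert intersect_predictions(a, []) == []

    def test_predict_mbs_agrees_with_seed_scan_on_full_complements(self):
        mature = LET7.matures[0]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
        utr = "CCCCC" + "".join(comp[b] for b in reversed(mature)) + "CCCCC"
        combined = predict_mbs(utr, [LET7])
        assert combined
        assert {(p.start, p.end, p.site_type) for p in combined} == {
            (s.start, s.end, s.site_type) for s in seed_sites(utr, LET7)
        }

    def test_seed_only_match_filtered_by_aligner(self):
        # a bare seed complement scores below the aligner threshold, so
        # the intersected annotation drops it
        utr = "CCCC" + "CTACCTCA" + "CCCC"
        assert seed_sites(utr, LET7)
        assert predict_mbs(utr, [LET7]) == []


class TestApplyEdit:
    def test_single_base_replacement(self):
        assert apply_edit("CCACC", 3) == "CCGCC"

    def test_out_of_range_and_non_a(self):
        with pytest.raises(IndexError):
            apply_edit("CCACC", 6)
        with pytest.raises(ValueError):
            apply_edit("CCGCC", 3)


class TestClassifyCascade:
    def test_cascade_clause_examples(self):
        zero = {"t1": 0, "t2": 0}
        assert classify_delta_counts(zero, zero, overlaps_any=False) == "no_overlaps"
        assert classify_delta_counts({"t1": 1, "t2": 0}, {"t1": 1, "t2": 0},
                                     True) == "site_unchanged"
        assert classify_delta_counts({"t1": 1, "t2": 0}, {"t1": 0, "t2": 0},
                                     True) == "gain"
        assert classify_delta_counts({"t1": 0}, {"t1": 2}, True) == "lost"
        assert classify_delta_counts({"t1": 1, "t2": 0}, {"t1": 0, "t2": 1},
                                     True) == "mixed"

    def test_transcript_set_mismatch_is_error(self):
        with pytest.raises(ValueError):
            classify_delta_counts({"t1": 1}, {"t2": 1}, True)

    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 4)),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_cascade_exhaustive_and_mutually_exclusive(self, counts):
        introduced = {f"t{i}": c[0] for i, c in enumerate(counts)}
        removed = {f"t{i}": c[1] for i, c in enumerate(counts)}
        any_nonzero = any(introduced.values()) or any(removed.values())
        label = classify_delta_counts(introduced, removed, overlaps_any=True)
        # re-derive each clause independently and demand exactly one match
        diffs = [introduced[t] - removed[t] for t in introduced]
        clauses = {
            "site_unchanged": all(d == 0 for d in diffs),
            "gain": all(d >= 0 for d in diffs) and any(d > 0 for d in diffs),
            "lost": all(d <= 0 for d in diffs) and any(d < 0 for d in diffs),
            "mixed": any(d > 0 for d in diffs) and any(d < 0 for d in diffs),
        }
        assert sum(clauses.values()) == 1
        assert clauses[label]
        if not any_nonzero:
            assert classify_delta_counts(introduced, removed, False) == "no_overlaps"


class TestDeltaForEdit:
    def test_engineered_gain(self):
        fam = MiRNAFamily("F", "TACCTCA")  # 8mer target: TGAGGTA + A
        utr = "CCCC" + "TGAGATA" + "ACCCC"  # A at position 9 should be G
        delta = mbs_delta_for_edit({"t1": (utr, 9)}, fam, "G1")
        assert delta.classification == "gain"
        assert delta.total_introduced == 1 and delta.total_removed == 0

    def test_edit_outside_all_sites_is_no_overlaps(self):
        fam = MiRNAFamily("F", "TACCTCA")
        utr = "CCCCACCCCCCCCCC"
        delta = mbs_delta_for_edit({"t1": (utr, 5)}, fam, "G1")
        assert delta.classification == "no_overlaps"

    def test_transcript_without_edit_contributes_zero(self):
        fam = MiRNAFamily("F", "TACCTCA")
        utr = "CCCC" + "TGAGATA" + "ACCCC"
        delta = mbs_delta_for_edit(
            {"t1": (utr, 9), "t2": ("CCCCCCCC", None)}, fam, "G1")
        assert delta.classification == "gain"
        assert delta.introduced["t2"] == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_oracle_and_revert_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        fam = LET7
        length = int(rng.integers(20, 200))
        utr = _random_utr_with_motifs(rng, fam, length)
        a_positions = [i + 1 for i, b in enumerate(utr) if b == "A"]
        if not a_positions:
            return
        pos = int(rng.choice(a_positions))
        delta = mbs_delta_for_edit({"t1": (utr, pos)}, fam, "G")
        assert delta.classification == oracle_delta(utr, pos, fam.seed)
        # reverting the edit swaps gain and lost and fixes the rest
        post = apply_edit(utr, pos)
        rev_pre = {s.key for s in seed_sites(post, fam)}
        rev_post = {s.key for s in seed_sites(utr, fam)}
        falls_into = any(
            s.overlaps(pos)
            for s in seed_sites(post, fam) + seed_sites(utr, fam)
        )
        rev_label = classify_delta_counts(
            {"t1": len(rev_post - rev_pre)}, {"t1": len(rev_pre - rev_post)},
            falls_into,
        )
        expected = {"gain": "lost", "lost": "gain"}.get(
            delta.classification, delta.classification)
        assert rev_label == expected

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_locality_whole_transcript_mode_agrees(self, seed):
        rng = np.random.default_rng(seed)
        utr = _random_utr_with_motifs(rng, LET7, int(rng.integers(20, 150)))
        a_positions = [i + 1 for i, b in enumerate(utr) if b == "A"]
        if not a_positions:
            return
        pos = int(rng.choice(a_positions))
        local = mbs_delta_for_edit({"t": (utr, pos)}, LET7)
        full = mbs_delta_for_edit({"t": (utr, pos)}, LET7, whole_transcript=True)
        assert local.classification == full.classification


class TestPerPairTable:
    def test_gain_counts_per_gene_sample(self):
        deltas = {
            (("chr1", 10), "G1", "F"): "gain",
            (("chr1", 20), "G1", "F"): "lost",
            (("chr1", 30), "G2", "F"): "gain",
        }
        per_sample = {
            "s1": {("chr1", 10), ("chr1", 20)},
            "s2": {("chr1", 10), ("chr1", 30)},
            "s3": set(),
        }
        df = per_pair_mbs_table(deltas, per_sample)
        records = {(r.gene_id, r.sample_id): (r.gains, r.losses, r.net)
                   for r in df.itertuples()}
        assert records == {
            ("G1", "s1"): (1, 1, 0),
            ("G1", "s2"): (1, 0, 1),
            ("G2", "s2"): (1, 0, 1),
        }
        dense = per_pair_mbs_table(deltas, per_sample, dense_genes=["G1", "G2"])
        assert len(dense) == 6
        assert dense.loc[(dense.gene_id == "G2") & (dense.sample_id == "s3"),
                         "gains"].item() == 0
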