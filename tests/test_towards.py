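"""Scoring (movement score), homogenization, normalization, aggregation, summaries."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from towardsig.shm import sh_scan
from towardsig.towards import (
    RawList,
    ScoredList,
    aggregate,
    build_raw_list,
    clan_summary,
    functionality_summary,
    homogenize,
    movement_score,
    normalize_list,
    score_list,
    subset_clan_clustering,
)

from conftest import make_allele, make_db, make_rearr


def _sl(pid: str, scores: dict[str, float]) -> ScoredList:
    return ScoredList(patient_id=pid, sbm_allele="IGHV1-1*01", subset=None,
                      m_i=max(1, len(scores)), scores=dict(scores))


# ---------------------------------------------------------------------------
# movement score


def test_movement_score_worked_case():
    # SH=2, M=4, maxSH=5, selSc=1 -> (2*2)/(4*5*1) = 0.2
    assert movement_score(2, 4, 5, 1) == Fraction(1, 5)


@pytest.mark.parametrize("sh_num,sh_den,m,max_num,max_den,sel", [
    (1, 1, 1, 1, 1, 1), (2, 1, 4, 5, 1, 1), (3, 2, 5, 7, 3, 2), (1, 3, 9, 2, 1, 3),
    (5, 1, 10, 5, 2, 1), (7, 4, 8, 9, 4, 2), (1, 2, 3, 1, 2, 4), (4, 3, 6, 8, 3, 1),
    (2, 5, 7, 3, 5, 5), (6, 1, 6, 6, 1, 6), (1, 7, 2, 2, 7, 1), (9, 2, 11, 5, 3, 2),
    (3, 1, 3, 1, 1, 3), (8, 5, 13, 7, 5, 1), (2, 3, 4, 5, 6, 2), (5, 4, 9, 3, 2, 3),
    (1, 1, 100, 50, 1, 1), (10, 3, 12, 11, 3, 4), (4, 7, 5, 6, 7, 2), (7, 2, 14, 7, 2, 7),
])
def test_movement_score_exact_rationals(sh_num, sh_den, m, max_num, max_den, sel):
    sh = Fraction(sh_num, sh_den)
    mx = Fraction(max_num, max_den)
    expected = sh * sh / (Fraction(m) * mx * Fraction(sel))  # independent evaluation
    got = movement_score(sh, m, mx, sel)
    assert got == expected
    assert abs(float(got) - float(expected)) < 1e-12


def test_movement_score_rejects_degenerate_inputs():
    for bad in (dict(m_i=0), dict(max_sh=0), dict(sel_sc=0)):
        kwargs = dict(sh=1, m_i=2, max_sh=3, sel_sc=1) | bad
        with pytest.raises(ValueError):
            movement_score(**kwargs)


# ---------------------------------------------------------------------------
# score_list through a constructed scenario


@pytest.fixture
def scoring_db():
    """sBm gene IGHV1-1; single-allele candidate IGHV2-1 differing at 5 positions."""
    sbm = "AAAAAAAAAACCCCCCCCCCGGGGGGGGGG"
    cand = "TTTTTAAAAACCCCCCCCCCGGGGGGGGGG"  # 5 diffs at positions 1..5
    return make_db([make_allele("IGHV1-1*01", sbm), make_allele("IGHV2-1*01", cand)])


def test_score_list_hand_case(scoring_db):
    # patient: 2 SH toward IGHV2-1 (positions 1,2) + 2 non-SH (G at C columns 11,12)
    patient = "TTAAAAAAAAGGCCCCCCCCGGGGGGGGGG"
    r = make_rearr("P1", "IGHV1-1*01", patient)
    sh, nonsh = sh_scan([r], scoring_db)
    raw = build_raw_list(r, sh, scoring_db)
    assert raw.m_i == 4 and raw.elements == [(2, "IGHV2-1*01")]
    sl = score_list(raw, scoring_db)
    # SH=2, M=4, maxSH=5, selSc=1 -> 0.2
    assert sl.scores == {"IGHV2-1": pytest.approx(0.2, abs=1e-15)}


def test_selectivity_ties_halve_scores():
    sbm = "AAAAAAAAAA" * 3
    c1 = "TTAAAAAAAA" + "A" * 20  # 2 diffs (pos 1,2)
    c2 = "AATTAAAAAA" + "A" * 20  # 2 diffs (pos 3,4)
    db = make_db([
        make_allele("IGHV1-1*01", sbm),
        make_allele("IGHV2-1*01", c1),
        make_allele("IGHV3-1*01", c2),
    ])
    patient = "TATAAAAAAA" + "A" * 20  # SH pos1 toward c1, SH pos4 toward c2
    r = make_rearr("P1", "IGHV1-1*01", patient)
    sh, _ = sh_scan([r], db)
    raw = build_raw_list(r, sh, db)
    sl = score_list(raw, db)
    # both genes SH=1 -> selSc=2 each; score = 1/(2*2*2) = 0.125
    assert sl.scores["IGHV2-1"] == pytest.approx(1 / (2 * 2 * 2))
    assert sl.scores["IGHV3-1"] == pytest.approx(1 / (2 * 2 * 2))
    # removing the tie doubles the survivor's score
    db1 = make_db([make_allele("IGHV1-1*01", sbm), make_allele("IGHV2-1*01", c1)])
    sh1, _ = sh_scan([make_rearr("P1", "IGHV1-1*01", patient)], db1)
    raw1 = build_raw_list(make_rearr("P1", "IGHV1-1*01", patient), sh1, db1)
    sl1 = score_list(raw1, db1)
    assert sl1.scores["IGHV2-1"] == pytest.approx(2 * sl.scores["IGHV2-1"])


def test_gene_sh_is_mean_over_alleles():
    sbm = "A" * 30
    a1 = "T" + "A" * 29          # 1 diff
    a2 = "TT" + "A" * 28         # 2 diffs
    db = make_db([
        make_allele("IGHV1-1*01", sbm),
        make_allele("IGHV2-1*01", a1),
        make_allele("IGHV2-1*02", a2),
    ])
    patient = "T" + "A" * 29  # one mutation, shared by both alleles of IGHV2-1
    r = make_rearr("P1", "IGHV1-1*01", patient)
    sh, _ = sh_scan([r], db)
    sl = score_list(build_raw_list(r, sh, db), db)
    # SH = mean(1,1) = 1; maxSH = mean(1,2) = 1.5; M=1; selSc=1 -> 1/1.5
    assert sl.scores["IGHV2-1"] == pytest.approx(float(Fraction(2, 3)))


def test_score_list_refuses_mutation_free_voter(scoring_db):
    raw = RawList("P0", "IGHV1-1*01", None, 0, [])
    assert not raw.is_voter
    with pytest.raises(ValueError, match="M_i"):
        score_list(raw, scoring_db)


def test_exclude_sbm_gene_default(toy_db):
    # the only SH is toward the sBm's own other allele: excluded at gene level
    r = make_rearr("P1", "IGHV1-1*01", "ACGTACGAACGT")
    sh, _ = sh_scan([r], toy_db)
    raw = build_raw_list(r, sh, toy_db)
    assert raw.elements == [(1, "IGHV1-1*02")]
    assert score_list(raw, toy_db).scores == {}
    included = score_list(raw, toy_db, exclude_sbm_gene=False)
    assert "IGHV1-1" in included.scores


# ---------------------------------------------------------------------------
# homogenize / normalize / aggregate


def test_homogenize_union_and_zero_fill():
    lists = [_sl("P1", {"A": 1.0}), _sl("P2", {"B": 2.0})]
    out = homogenize(lists)
    assert [sorted(sl.scores) for sl in out] == [["A", "B"], ["A", "B"]]
    assert out[0].scores["B"] == 0.0 and out[1].scores["A"] == 0.0
    # identical gene sets: unchanged values
    same = homogenize([_sl("P1", {"A": 1.0, "B": 0.5})])
    assert same[0].scores == {"A": 1.0, "B": 0.5}
    # union size equals brute-force set union
    tri = [_sl("P1", {"A": 1, "B": 1}), _sl("P2", {"B": 1, "C": 1}), _sl("P3", {"C": 1, "A": 1})]
    out3 = homogenize(tri)
    assert set(out3[0].scores) == {"A", "B"} | {"B", "C"} | {"C", "A"}


def test_normalize_hand_case_and_fixed_points():
    out = normalize_list(_sl("P", {"A": 0.0, "B": 0.1, "C": 0.2}))
    assert out.scores == pytest.approx({"A": 0.0, "B": 0.5, "C": 1.0})
    assert normalize_list(_sl("P", {"A": 0.0, "B": 0.0})).scores == {"A": 0.0, "B": 0.0}
    assert normalize_list(_sl("P", {"A": 0.0, "B": 1.0})).scores == {"A": 0.0, "B": 1.0}
    # non-zero constant list -> all ones
    assert normalize_list(_sl("P", {"A": 0.4, "B": 0.4})).scores == {"A": 1.0, "B": 1.0}


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=30))
def test_normalize_contract_property(values):
    sl = _sl("P", {f"G{i}": v for i, v in enumerate(values)})
    out = normalize_list(sl)
    vals = list(out.scores.values())
    if len(set(values)) > 1:
        assert min(vals) == 0.0 and max(vals) == 1.0
        assert all(0.0 <= v <= 1.0 for v in vals)
    elif values[0] == 0.0:
        assert set(vals) == {0.0}


def test_aggregate_examples_and_oracle():
    one = [_sl("P1", {"A": 0.3, "B": 0.7})]
    cr = aggregate(one)
    assert cr.mean_scores() == one[0].scores and cr.n_voters == 1
    # symmetry: ((1,0),(0,1)) -> both 0.5, pct 50/50
    cr2 = aggregate([_sl("P1", {"A": 1.0, "B": 0.0}), _sl("P2", {"A": 0.0, "B": 1.0})])
    assert cr2.mean_scores() == {"A": 0.5, "B": 0.5}
    assert [p for _, _, p in cr2.elements] == [pytest.approx(50.0)] * 2
    # ties broken lexicographically
    assert [g for g, _, _ in cr2.elements] == ["A", "B"]
    # matrix-mean oracle on random instances up to 10 x 10
    rng = np.random.default_rng(11)
    for _ in range(30):
        n, k = int(rng.integers(1, 11)), int(rng.integers(1, 11))
        M = rng.random((n, k))
        genes = [f"G{j}" for j in range(k)]
        lists = [_sl(f"P{i}", dict(zip(genes, M[i]))) for i in range(n)]
        cr = aggregate(lists)
        want = M.mean(axis=0)
        for j, g in enumerate(genes):
            assert cr.mean_scores()[g] == pytest.approx(want[j], rel=1e-12)
        if want.sum() > 0:
            assert sum(p for _, _, p in cr.elements) == pytest.approx(100.0, abs=1e-9)


def test_voter_duplication_leaves_consensus_unchanged():
    lists = [_sl("P1", {"A": 1.0, "B": 0.2}), _sl("P2", {"A": 0.1, "B": 0.9})]
    cr = aggregate(lists)
    cr2 = aggregate(lists + lists)
    assert cr.mean_scores() == pytest.approx(cr2.mean_scores())


def test_scale_freeness_of_normalization():
    base = {"A": 0.0, "B": 0.3, "C": 0.9}
    scaled = {g: 7.5 * v for g, v in base.items()}
    assert normalize_list(_sl("P", base)).scores == pytest.approx(
        normalize_list(_sl("P", scaled)).scores
    )


def test_aggregate_requires_homogenized_lists():
    with pytest.raises(ValueError, match="homogenized"):
        aggregate([_sl("P1", {"A": 1.0}), _sl("P2", {"B": 1.0})])
    with pytest.raises(ValueError):
        aggregate([])


def test_all_nonsh_voter_contributes_zeros():
    """A voter with mutations but no SH dilutes the consensus (traced by hand)."""
    lists = homogenize([_sl("P1", {"A": 0.4}), _sl("P2", {})])
    normalized = [normalize_list(sl) for sl in lists]
    cr = aggregate(normalized)
    assert cr.mean_scores()["A"] == pytest.approx(0.5)  # (1 + 0) / 2


# ---------------------------------------------------------------------------
# summaries and clustering


def test_clan_summary_hand_cases(toy_db):
    # toy_db genes: IGHV1-1 (clan I), IGHV2-1 (clan II), IGHV3-1 (clan III)
    cr = aggregate([_sl("P1", {"IGHV1-1": 0.4, "IGHV2-1": 0.0, "IGHV3-1": 0.0})])
    assert clan_summary(cr, toy_db) == pytest.approx({"I": 100.0, "II": 0.0, "III": 0.0})
    cr2 = aggregate([_sl("P1", {"IGHV1-1": 0.2, "IGHV2-1": 0.1, "IGHV3-1": 0.1})])
    assert clan_summary(cr2, toy_db) == pytest.approx({"I": 50.0, "II": 25.0, "III": 25.0})
    assert sum(clan_summary(cr2, toy_db).values()) == pytest.approx(100.0, abs=1e-9)
    # avg mode divides by the clan's gene count in the union
    db = make_db([
        make_allele("IGHV1-1*01", "ACGT"), make_allele("IGHV1-2*01", "ACGA"),
        make_allele("IGHV2-1*01", "ACGC"),
    ])
    cr3 = aggregate([_sl("P1", {"IGHV1-1": 0.2, "IGHV1-2": 0.0, "IGHV2-1": 0.1})])
    s = clan_summary(cr3, db, mode="avg")
    assert s["I"] == pytest.approx(50.0) and s["II"] == pytest.approx(50.0)
    s_sum = clan_summary(cr3, db, mode="sum")
    assert s_sum["I"] == pytest.approx(200.0 / 3)


def test_clan_summary_unknown_gene_is_hard_error(toy_db):
    cr = aggregate([_sl("P1", {"IGHV9-9": 1.0})])
    with pytest.raises(KeyError):
        clan_summary(cr, toy_db)


def test_functionality_summary(toy_db):
    # allele-level lists; toy_db functionality: 1-1*01/*02 F, 2-1*01 P, 3-1*01 ORF
    lists = [
        _sl("P1", {"IGHV2-1*01": 0.5, "IGHV3-1*01": 0.5}),
        _sl("P2", {"IGHV2-1*01": 0.5, "IGHV3-1*01": 0.5}),
    ]
    s = functionality_summary(lists, toy_db)
    assert s == pytest.approx({"F": 0.0, "P": 50.0, "ORF": 50.0})
    assert sum(s.values()) == pytest.approx(100.0, abs=1e-9)
    only_f = functionality_summary([_sl("P1", {"IGHV1-1*02": 0.9})], toy_db)
    assert only_f == pytest.approx({"F": 100.0, "P": 0.0, "ORF": 0.0})


def test_subset_clan_clustering():
    # identical vectors merge at height 0
    res = subset_clan_clustering({"a": (50, 25, 25), "b": (50, 25, 25)})
    assert res.linkage[0, 2] == pytest.approx(0.0)
    # nearest pair merges first (pairwise-distance oracle)
    res3 = subset_clan_clustering(
        {"s1": (100, 0, 0), "s2": (0, 100, 0), "s3": (99, 1, 0)}
    )
    first = sorted(res3.linkage[0, :2].astype(int))
    assert [res3.labels[i] for i in first] == ["s1", "s3"]
    nwk = res3.to_newick()
    assert nwk.endswith(";") and all(lbl in nwk for lbl in res3.labels)
    # n subsets -> n - 1 merges
    vecs = {f"s{i}": (i, 100 - i, 0) for i in range(5)}
    assert subset_clan_clustering(vecs).linkage.shape[0] == 4
    with pytest.raises(ValueError):
        subset_clan_clustering({"only": (1, 2, 3)})
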