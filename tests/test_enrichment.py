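import numpy as np
import pandas as pd
import pytest

from stressqtl import enrichment as en
from stressqtl.enrichment import (
    EnrichmentResult,
    RankedList,
    build_ranked_list,
    cgsea,
    enrichment_score,
    gsea,
    results_to_frame,
)
from stressqtl.gwas import WindowVariance


def _ranked(scores, prefix="g"):
    return RankedList(
        genes=[f"{prefix}{i}" for i in range(len(scores))],
        scores=np.asarray(scores, dtype=float),
    )


def _brute_force_es(scores_desc, hit_mask, p=1.0):
    """Textbook running-sum ES for a descending score vector."""
    w = np.abs(scores_desc) ** p
    w = np.where(hit_mask, w, 0.0)
    inc = w / w.sum()
    dec = (~hit_mask).astype(float) / (~hit_mask).sum()
    walk = np.cumsum(inc - dec)
    return walk[np.argmax(np.abs(walk))]


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------

def test_ranked_list_sorted_descending_ties_by_id():
    r = RankedList(genes=["b", "a", "c"], scores=np.array([1.0, 1.0, 3.0]))
    assert r.genes == ["c", "a", "b"]
    assert list(r.scores) == [3.0, 1.0, 1.0]


def test_ranked_list_rejects_duplicates_and_nonfinite():
    with pytest.raises(ValueError, match="duplicate"):
        RankedList(genes=["a", "a"], scores=np.array([1.0, 2.0]))
    with pytest.raises(ValueError, match="finite"):
        RankedList(genes=["a", "b"], scores=np.array([1.0, np.nan]))


def _wv(window, egv):
    return WindowVariance(
        window=window, chrom="chr1", start=0, end=10, n_markers=1,
        egv_pct=egv, egv_sd=0.0, p_egv_gt1=0.0, marker_indices=np.zeros(0, int),
    )


def test_build_ranked_list_single_mode():
    wins = [_wv("w0", 0.2), _wv("w1", 5.0), _wv("w2", 0.8)]
    gw = pd.Series({"gA": "w0", "gB": "w1", "gC": "w2", "gD": "w9"})
    r = build_ranked_list(wins, gw, mode="single")
    assert set(r.genes) == {"gA", "gB", "gC"}  # gD's window not on the grid
    assert r.genes[0] == "gB" and r.scores[0] == 5.0


def test_build_ranked_list_excludes_qtl_windows():
    wins = [_wv("w0", 0.2), _wv("w1", 5.0), _wv("w2", 0.8)]
    gw = pd.Series({"gA": "w0", "gB": "w1", "gC": "w2"})
    r = build_ranked_list(wins, gw, mode="single", exclude_qtl=True)
    assert set(r.genes) == {"gA", "gC"}


def test_build_ranked_list_difference_mode():
    w_is = [_wv("w0", 0.4), _wv("w1", 0.9)]
    w_nis = [_wv("w0", 0.1), _wv("w1", 0.95)]
    gw = pd.Series({"gA": "w0", "gB": "w1"})
    r = build_ranked_list((w_is, w_nis), gw, mode="difference")
    assert r.genes[0] == "gA"
    assert r.scores[0] == pytest.approx(0.3)
    assert r.scores[1] == pytest.approx(-0.05)


def test_build_ranked_list_errors():
    wins = [_wv("w0", 0.2)]
    gw = pd.Series({"gA": "w0"})
    with pytest.raises(ValueError, match="single mode"):
        build_ranked_list((wins, wins), gw, mode="single")
    with pytest.raises(ValueError, match="difference mode"):
        build_ranked_list(wins, gw, mode="difference")
    with pytest.raises(ValueError, match="different window grids"):
        build_ranked_list((wins, [_wv("other", 0.1)]), gw, mode="difference")
    with pytest.raises(ValueError, match="unknown mode"):
        build_ranked_list(wins, gw, mode="banana")
    with pytest.raises(ValueError, match="no gene"):
        build_ranked_list(wins, pd.Series({"gA": "nowhere"}))


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def test_es_brute_force_oracle_top_three_of_ten():
    scores = np.arange(10, 0, -1, dtype=float)  # already descending
    r = _ranked(scores)
    top3 = {r.genes[0], r.genes[1], r.genes[2]}
    es, profile = enrichment_score(r, top3)
    hit = np.array([g in top3 for g in r.genes])
    assert es == pytest.approx(_brute_force_es(scores, hit, p=1.0))
    assert es > 0.5
    assert profile.size == 10


def test_es_unweighted_matches_ks_oracle():
    scores = np.arange(10, 0, -1, dtype=float)
    r = _ranked(scores)
    top3 = {r.genes[0], r.genes[1], r.genes[2]}
    es, _ = enrichment_score(r, top3, p=0.0)
    hit = np.array([g in top3 for g in r.genes])
    assert es == pytest.approx(_brute_force_es(scores, hit, p=0.0))
    # unweighted, all hits first: ES = 1 - n_hit/n at the third position
    assert es == pytest.approx(1.0)


def test_es_bottom_set_is_negative():
    scores = np.arange(10, 0, -1, dtype=float)
    r = _ranked(scores)
    bottom3 = set(r.genes[-3:])
    es, _ = enrichment_score(r, bottom3)
    assert es < -0.5


def test_es_reversing_scores_negates_top_set():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=20)
    r = _ranked(scores)
    top = set(r.genes[:4])
    es_top, _ = enrichment_score(r, top, p=0.0)
    rev = RankedList(genes=list(r.genes), scores=-r.scores)
    es_rev, _ = enrichment_score(rev, top, p=0.0)
    assert es_rev == pytest.approx(-es_top, abs=1e-12)


def test_es_monotone_rescale_invariant_unweighted():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=30)
    r1 = _ranked(scores)
    r2 = RankedList(genes=list(r1.genes), scores=3.0 * r1.scores + 0.0)
    gs = set(r1.genes[2:8])
    assert enrichment_score(r1, gs, p=0.0)[0] == pytest.approx(
        enrichment_score(r2, gs, p=0.0)[0]
    )


def test_es_all_genes_degenerate():
    r = _ranked([3.0, 2.0, 1.0])
    es, _ = enrichment_score(r, set(r.genes))
    assert es == pytest.approx(1.0)


def test_es_disjoint_set_raises():
    r = _ranked([3.0, 2.0, 1.0])
    with pytest.raises(ValueError, match="intersect"):
        enrichment_score(r, {"zz"})


def test_es_walk_returns_to_zero():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=25)
    r = _ranked(scores)
    gs = set(r.genes[::3])
    _, profile = enrichment_score(r, gs, p=0.0)
    assert profile[-1] == pytest.approx(0.0, abs=1e-12)


def test_es_all_zero_hit_scores_fallback():
    scores = np.r_[np.ones(5), np.zeros(5)]
    r = _ranked(scores)
    zero_genes = set(r.genes[-3:])
    es, _ = enrichment_score(r, zero_genes)  # |score|^p weights all zero
    assert np.isfinite(es) and es < 0


def test_es_matches_gseapy_reference():
    pytest.importorskip("gseapy")
    from gseapy.algorithm import enrichment_score as gp_es

    rng = np.random.default_rng(3)
    scores = np.sort(rng.normal(size=40))[::-1]
    r = _ranked(scores)
    gs = list(r.genes[5:15])
    es_ours, _ = enrichment_score(r, gs, p=1.0)
    # gseapy's reference module predates NumPy 2 (np.in1d was renamed np.isin)
    had_in1d = hasattr(np, "in1d")
    if not had_in1d:
        np.in1d = np.isin
    try:
        out = gp_es(
            gene_list=r.genes,
            correl_vector=r.scores,
            gene_set=gs,
            weight=1.0,
            nperm=100,
            seed=1,
            single=False,
            scale=False,
        )
    finally:
        if not had_in1d:
            del np.in1d
    assert es_ours == pytest.approx(float(out[0]), abs=1e-9)


# ---------------------------------------------------------------------------
# gsea
# ---------------------------------------------------------------------------

def _random_library(genes, n_sets, size, rng):
    return {
        f"set{k}": list(rng.choice(genes, size=size, replace=False))
        for k in range(n_sets)
    }


def test_gsea_deterministic():
    rng = np.random.default_rng(4)
    r = _ranked(rng.normal(size=80))
    lib = _random_library(r.genes, 10, 8, rng)
    a = results_to_frame(gsea(r, lib, n_perm=200, seed=5))
    b = results_to_frame(gsea(r, lib, n_perm=200, seed=5))
    pd.testing.assert_frame_equal(a, b)


def test_gsea_planted_set_detected():
    rng = np.random.default_rng(6)
    scores = rng.normal(size=120)
    scores[:10] += 4.0  # strong planted signal
    genes = [f"g{i}" for i in range(120)]
    lib = {"planted": genes[:10]}
    lib.update(_random_library(genes, 12, 10, rng))
    r = RankedList(genes=genes, scores=scores)
    res = {x.set_name: x for x in gsea(r, lib, n_perm=300, seed=7)}
    assert res["planted"].es > 0
    assert res["planted"].fdr_q <= 0.25
    assert res["planted"].p_value == min(x.p_value for x in res.values())


def test_gsea_null_fdr_calibrated():
    rng = np.random.default_rng(8)
    scores = rng.normal(size=300)
    genes = [f"g{i}" for i in range(300)]
    r = RankedList(genes=genes, scores=scores)
    lib = _random_library(genes, 200, 10, np.random.default_rng(9))
    res = gsea(r, lib, n_perm=200, seed=10)
    frac_sig = np.mean([x.fdr_q <= 0.25 for x in res])
    assert frac_sig <= 0.35


def test_gsea_size_filter_and_guards():
    r = _ranked(np.arange(50, 0, -1, dtype=float))
    lib = {"tiny": list(r.genes[:2]), "ok": list(r.genes[:8])}
    res = gsea(r, lib, n_perm=100, seed=0)
    assert [x.set_name for x in res] == ["ok"]
    with pytest.raises(ValueError, match="at least 100"):
        gsea(r, lib, n_perm=10)
    with pytest.raises(ValueError, match="empty"):
        gsea(r, {"tiny": list(r.genes[:2])}, n_perm=100)


def test_gsea_difference_mode_tail_labels():
    rng = np.random.default_rng(11)
    scores = rng.normal(size=60)
    r = _ranked(scores)
    lib = {
        "top": list(r.genes[:8]),
        "bottom": list(r.genes[-8:]),
    }
    res = {x.set_name: x for x in gsea(r, lib, n_perm=100, seed=12, difference_mode=True)}
    assert res["top"].tail == "WPD" and res["top"].es > 0
    assert res["bottom"].tail == "WND" and res["bottom"].es < 0
    assert res["bottom"].signed_q <= 0


def test_gsea_q_monotone_in_each_pool():
    rng = np.random.default_rng(13)
    r = _ranked(rng.normal(size=150))
    lib = _random_library(r.genes, 30, 10, rng)
    res = gsea(r, lib, n_perm=150, seed=14)
    for sign in (1, -1):
        grp = sorted(
            (x for x in res if (x.es >= 0) == (sign == 1)),
            key=lambda x: -abs(x.nes),
        )
        qs = [x.fdr_q for x in grp]
        assert qs == sorted(qs)


# ---------------------------------------------------------------------------
# cgsea
# ---------------------------------------------------------------------------

def _res(name, es, q):
    return EnrichmentResult(
        set_name=name, es=es, nes=es, p_value=0.5, fdr_q=q,
        signed_q=q if es >= 0 else -q, tail="WPD" if es >= 0 else "WND",
        n_genes=10,
    )


def test_cgsea_categories():
    diff = [_res("a", 2.0, 0.01), _res("b", -1.5, 0.02), _res("c", 0.5, 0.9),
            _res("d", 1.0, 0.01), _res("e", 0.2, 0.8)]
    is_ = [_res("a", 1.0, 0.01), _res("b", 1.0, 0.9), _res("c", 1.0, 0.05),
           _res("d", 1.0, 0.9), _res("e", 1.0, 0.9)]
    nis = [_res("a", 1.0, 0.01), _res("b", 1.0, 0.05), _res("c", 1.0, 0.9),
           _res("d", 1.0, 0.9), _res("e", 1.0, 0.9)]
    cats = {c.set_name: c.category for c in cgsea(diff, is_, nis)}
    assert cats["a"] == "WPD[v_IS+NIS]"
    assert cats["b"] == "WND[v_NIS-only]"
    assert cats["c"] == "not-significant-in-cGSEA[IS-only]"
    assert cats["d"] == "WPD[v_notIS/NIS]"
    assert cats["e"] == "not-significant"


def test_cgsea_assigns_every_set_exactly_once():
    rng = np.random.default_rng(15)
    names = [f"s{i}" for i in range(20)]
    mk = lambda: [_res(n, rng.normal(), rng.uniform()) for n in names]
    cats = cgsea(mk(), mk(), mk())
    assert sorted(c.set_name for c in cats) == sorted(names)


def test_cgsea_library_mismatch_rejected():
    with pytest.raises(ValueError, match="different gene-set libraries"):
        cgsea([_res("a", 1.0, 0.01)], [_res("b", 1.0, 0.01)], [_res("a", 1.0, 0.01)])
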