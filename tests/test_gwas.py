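import numpy as np
import pandas as pd
import pytest

from stressqtl import gwas
from stressqtl.gwas import (
    GwasPosterior,
    JointGwasPosterior,
    McmcConfig,
    WindowVariance,
    adjust_for_baseline,
    call_qtl,
    conditional_scan,
    pleiotropy_ad,
    run_bayesb,
    run_bivariate_bayes,
    window_variance,
)
from stressqtl.io import GenotypeMatrix, make_windows
from stressqtl.simulate import qtl_marker_index, scaled_preset, simulate_cohort
from stressqtl.varcomp import compute_grm

from conftest import log_trait


def _unlinked(n, m, seed, mafs=None):
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(0.2, 0.5, size=m)
    d = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    mm = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(m) * 1_000_000 + 500_000,  # one marker per 1Mb window
            "id": [f"s{j}" for j in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=d, marker_map=mm, sample_ids=[f"i{i}" for i in range(n)])


def _short_cfg(**kw):
    base = dict(chain_length=1200, burn_in=200, thin=2, seed=7)
    base.update(kw)
    return McmcConfig(**base)


def _fake_post(G, samples, pip=None):
    m = len(G.marker_map)
    if pip is None:
        pip = np.abs(samples).mean(axis=0) > 0
    return GwasPosterior(
        marker_ids=list(G.marker_map["id"]),
        effects=samples.mean(axis=0),
        pip=np.asarray(pip, float),
        samples=samples,
        fixed_effects=np.zeros(1),
        fixed_names=["intercept"],
        sigma2e_trace=np.ones(samples.shape[0]),
        pen_var_trace=np.zeros(samples.shape[0]),
        n_included_trace=(samples != 0).sum(axis=1),
        genetic_var_trace=np.ones(samples.shape[0]),
        psrf_sigma2e=1.0,
        psrf_genetic_var=1.0,
        config=McmcConfig(),
    )


# ---------------------------------------------------------------------------
# sampler behaviour
# ---------------------------------------------------------------------------

def test_strong_single_marker_detected():
    G = _unlinked(200, 30, seed=1)
    rng = np.random.default_rng(2)
    z = G.dosage_float()[:, 5]
    y = 1.0 * z + 0.05 * rng.normal(size=200)
    post = run_bayesb(y, None, G, _short_cfg())
    assert post.pip[5] > 0.95
    assert post.effects[5] == pytest.approx(1.0, abs=0.05)
    grid = make_windows(G.marker_map, 1_000_000)
    wins = window_variance(post, grid, G)
    focal = next(w for w in wins if 5 in w.marker_indices)
    assert focal.egv_pct > 95.0


def test_determinism_and_seed_sensitivity():
    G = _unlinked(100, 20, seed=3)
    rng = np.random.default_rng(4)
    y = G.dosage_float()[:, 2] * 0.5 + rng.normal(size=100)
    a = run_bayesb(y, None, G, _short_cfg(seed=11))
    b = run_bayesb(y, None, G, _short_cfg(seed=11))
    c = run_bayesb(y, None, G, _short_cfg(seed=12))
    np.testing.assert_array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


def test_pi_controls_model_size():
    G = _unlinked(120, 40, seed=5)
    y = np.random.default_rng(6).normal(size=120)
    sizes = []
    for pi in (0.5, 0.9, 0.99):
        post = run_bayesb(y, None, G, _short_cfg(pi=pi, seed=8))
        sizes.append(float(post.n_included_trace.mean()))
    assert sizes[0] > sizes[1] > sizes[2]


def test_chain_length_stability():
    G = _unlinked(150, 20, seed=9)
    rng = np.random.default_rng(10)
    y = G.dosage_float()[:, 7] * 0.8 + 0.3 * rng.normal(size=150)
    grid = make_windows(G.marker_map, 1_000_000)
    egvs = []
    for chain, burn in ((1600, 300), (3200, 600)):
        post = run_bayesb(
            y, None, G, McmcConfig(chain_length=chain, burn_in=burn, thin=2, seed=13)
        )
        wins = window_variance(post, grid, G)
        egvs.append(next(w for w in wins if 7 in w.marker_indices).egv_pct)
    assert abs(egvs[0] - egvs[1]) < 0.1 * max(egvs)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        McmcConfig(chain_length=100, burn_in=200).validate()
    with pytest.raises(ValueError):
        McmcConfig(pi=1.0).validate()
    with pytest.raises(ValueError):
        McmcConfig(chain_length=102, burn_in=1, thin=2).validate()
    with pytest.raises(ValueError):
        McmcConfig(effect_df=2.0).validate()


# ---------------------------------------------------------------------------
# window variance on hand-built posteriors
# ---------------------------------------------------------------------------

def test_window_variance_single_effect_window_takes_all():
    G = _unlinked(80, 6, seed=14)
    samples = np.zeros((50, 6))
    samples[:, 2] = 0.7
    grid = make_windows(G.marker_map, 1_000_000)
    wins = window_variance(_fake_post(G, samples), grid, G)
    focal = next(w for w in wins if 2 in w.marker_indices)
    assert focal.egv_pct == pytest.approx(100.0)
    assert sum(w.egv_pct for w in wins) == pytest.approx(100.0)


def test_window_variance_sums_near_100_unlinked():
    G = _unlinked(400, 12, seed=15)
    rng = np.random.default_rng(16)
    samples = rng.normal(size=(60, 12)) * 0.3
    grid = make_windows(G.marker_map, 1_000_000)
    wins = window_variance(_fake_post(G, samples), grid, G)
    assert 90.0 <= sum(w.egv_pct for w in wins) <= 110.0


def test_window_variance_zero_iterations_contribute_zero():
    G = _unlinked(50, 4, seed=17)
    samples = np.zeros((20, 4))
    samples[:10, 1] = 0.5  # half the iterations have no genetic variance at all
    grid = make_windows(G.marker_map, 1_000_000)
    wins = window_variance(_fake_post(G, samples), grid, G)
    focal = next(w for w in wins if 1 in w.marker_indices)
    assert focal.egv_pct == pytest.approx(50.0)


def test_window_variance_requires_samples():
    G = _unlinked(30, 4, seed=18)
    post = _fake_post(G, np.zeros((5, 4)))
    post.samples = np.zeros((0, 4))
    with pytest.raises(ValueError):
        window_variance(post, make_windows(G.marker_map, 1_000_000), G)


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

def _wv(window, egv, idx):
    return WindowVariance(
        window=window, chrom="chr1", start=0, end=10, n_markers=len(idx),
        egv_pct=egv, egv_sd=0.0, p_egv_gt1=0.0, marker_indices=np.asarray(idx),
    )


def test_call_qtl_threshold_is_strict():
    G = _unlinked(30, 3, seed=19)
    post = _fake_post(G, np.ones((5, 3)), pip=[0.9, 0.9, 0.9])
    wins = [_wv("w0", 0.9, [0]), _wv("w1", 1.0, [1]), _wv("w2", 1.0001, [2])]
    calls = call_qtl(wins, post, egv_threshold=1.0)
    assert [c.window for c in calls] == ["w2"]
    calls09 = call_qtl(wins, post, egv_threshold=0.9)
    assert [c.window for c in calls09] == ["w2", "w1"]  # 0.9 itself excluded


def test_call_qtl_sorted_and_lead_snps_filtered():
    G = _unlinked(30, 4, seed=20)
    post = _fake_post(G, np.ones((5, 4)), pip=[0.5, 0.009, 0.01, 0.2])
    wins = [_wv("a", 5.0, [0, 1]), _wv("b", 40.0, [2, 3])]
    calls = call_qtl(wins, post)
    assert [c.window for c in calls] == ["b", "a"]
    # PIP threshold is inclusive at 0.01; leads sorted by PIP descending
    assert calls[0].lead_snps == [("s3", 0.2), ("s2", 0.01)]
    assert calls[1].lead_snps == [("s0", 0.5)]


# ---------------------------------------------------------------------------
# conditional scan
# ---------------------------------------------------------------------------

def test_conditional_scan_removes_focal_signal():
    G = _unlinked(250, 25, seed=21)
    rng = np.random.default_rng(22)
    z = G.dosage_float()[:, 10]
    y = 0.9 * z + 0.5 * rng.normal(size=250)
    grid = make_windows(G.marker_map, 1_000_000)
    cfg = _short_cfg(seed=23)
    marg = window_variance(run_bayesb(y, None, G, cfg), grid, G)
    cond_post = conditional_scan(y, None, z, G, cfg, exclude_markers=["s10"])
    cond = window_variance(cond_post, grid, G)
    focal_m = next(w for w in marg if 10 in w.marker_indices).egv_pct
    focal_c = next(w for w in cond if 10 in w.marker_indices).egv_pct
    assert focal_m > 50.0
    assert focal_c <= 2.0


def test_conditional_scan_constant_covariate_rejected():
    G = _unlinked(60, 10, seed=24)
    y = np.random.default_rng(25).normal(size=60)
    with pytest.raises(ValueError, match="constant"):
        conditional_scan(y, None, np.ones(60), G, _short_cfg())


# ---------------------------------------------------------------------------
# baseline adjustment
# ---------------------------------------------------------------------------

def test_adjust_for_baseline_recovers_unit_slope(small_cnur):
    grm = compute_grm(small_cnur.genotypes, method="standardized")
    rng = np.random.default_rng(26)
    y_nis = rng.normal(size=150)
    y_is = 1.0 * y_nis + 0.3 * rng.normal(size=150)
    adj = adjust_for_baseline(y_is, y_nis, None, grm)
    assert adj.coefficient == pytest.approx(1.0, abs=0.15)
    assert adj.p_value < 1e-6
    np.testing.assert_allclose(adj.adjusted, y_is - adj.coefficient * y_nis)


def test_adjust_for_baseline_independent_traits_near_zero(small_cnur):
    grm = compute_grm(small_cnur.genotypes, method="standardized")
    rng = np.random.default_rng(27)
    adj = adjust_for_baseline(
        rng.normal(size=150), rng.normal(size=150), None, grm
    )
    assert abs(adj.coefficient) < 0.25


def test_adjust_for_baseline_requires_overlap(small_cnur):
    grm = compute_grm(small_cnur.genotypes, method="standardized")
    y1 = np.r_[np.ones(75), np.full(75, np.nan)]
    y2 = np.r_[np.full(75, np.nan), np.ones(75)]
    with pytest.raises(ValueError, match="both traits"):
        adjust_for_baseline(y1, y2, None, grm)


# ---------------------------------------------------------------------------
# pleiotropy AD
# ---------------------------------------------------------------------------

def _fake_joint(G, samples1, samples2):
    return JointGwasPosterior(
        marker_ids=list(G.marker_map["id"]),
        effects1=samples1.mean(axis=0),
        effects2=samples2.mean(axis=0),
        pip=np.zeros(samples1.shape[1]),
        samples1=samples1,
        samples2=samples2,
        fixed_effects1=np.zeros(1),
        fixed_effects2=np.zeros(1),
        fixed_names=["intercept"],
        residual_cov_trace=np.zeros((samples1.shape[0], 3)),
        config=McmcConfig(),
    )


def test_pleiotropy_ad_hand_counts():
    G = _unlinked(40, 2, seed=28)
    n_save = 100
    s1 = np.zeros((n_save, 2))
    s2 = np.zeros((n_save, 2))
    s1[:, 0] = 1.0
    s2[:75, 0] = 1.0   # 75 positive-covariance iterations
    s2[75:, 0] = -1.0  # 25 negative
    res = pleiotropy_ad(_fake_joint(G, s1, s2), make_windows(G.marker_map, 1_000_000), G)
    focal = res[0]
    assert focal.p_pos == pytest.approx(0.75)
    assert focal.p_neg == pytest.approx(0.25)
    assert focal.ad == pytest.approx(0.5)
    assert focal.pleiotropic is True


def test_pleiotropy_ad_threshold_is_strict():
    G = _unlinked(40, 2, seed=29)
    s1 = np.zeros((100, 2))
    s2 = np.zeros((100, 2))
    s1[:, 0] = 1.0
    s2[:75, 0] = 1.0
    s2[75:, 0] = -1.0  # AD = 0.5 exactly
    res = pleiotropy_ad(
        _fake_joint(G, s1, s2), make_windows(G.marker_map, 1_000_000), G,
        threshold=0.5,
    )
    assert res[0].ad == 0.5 and res[0].pleiotropic is False


def test_pleiotropy_ad_excluded_iterations_count_neither_sign():
    G = _unlinked(40, 2, seed=30)
    s1 = np.zeros((100, 2))
    s2 = np.zeros((100, 2))
    s1[:50, 0] = 1.0
    s2[:50, 0] = 1.0   # half positive, half excluded (zero effect)
    res = pleiotropy_ad(_fake_joint(G, s1, s2), make_windows(G.marker_map, 1_000_000), G)
    assert res[0].p_pos == pytest.approx(0.5)
    assert res[0].p_neg == 0.0
    assert res[0].ad == pytest.approx(0.5)


def test_pleiotropy_ad_marker_mismatch_rejected():
    G = _unlinked(40, 3, seed=31)
    joint = _fake_joint(G, np.zeros((10, 3)), np.zeros((10, 3)))
    G2 = _unlinked(40, 2, seed=32)
    with pytest.raises(ValueError, match="marker"):
        pleiotropy_ad(joint, make_windows(G2.marker_map, 1_000_000), G2)


# ---------------------------------------------------------------------------
# bivariate sampler
# ---------------------------------------------------------------------------

def test_bivariate_shared_qtl_detected():
    G = _unlinked(250, 20, seed=33)
    rng = np.random.default_rng(34)
    z = G.dosage_float()[:, 4]
    y1 = 0.8 * z + 0.5 * rng.normal(size=250)
    y2 = 0.6 * z + 0.5 * rng.normal(size=250)
    joint = run_bivariate_bayes(y1, y2, None, G, _short_cfg(seed=35))
    assert joint.pip[4] > 0.9
    assert joint.effects1[4] > 0.5 and joint.effects2[4] > 0.3
    # residual correlation should be near zero here
    r12 = joint.residual_cov_trace[:, 1].mean()
    r11 = joint.residual_cov_trace[:, 0].mean()
    r22 = joint.residual_cov_trace[:, 2].mean()
    assert abs(r12 / np.sqrt(r11 * r22)) < 0.25


def test_bivariate_missing_individuals_dropped():
    G = _unlinked(120, 10, seed=36)
    rng = np.random.default_rng(37)
    y1 = rng.normal(size=120)
    y2 = rng.normal(size=120)
    y1[:15] = np.nan
    joint = run_bivariate_bayes(y1, y2, None, G, _short_cfg(seed=38))
    assert joint.samples1.shape[1] == 10


def test_bivariate_too_few_overlapping_rejected():
    G = _unlinked(20, 5, seed=39)
    y1 = np.full(20, np.nan)
    y1[:5] = 1.0
    y2 = np.ones(20)
    with pytest.raises(ValueError, match="too few"):
        run_bivariate_bayes(y1, y2, None, G, _short_cfg())


# ---------------------------------------------------------------------------
# end-to-end on the simulated cohort
# ---------------------------------------------------------------------------

def test_cohort_qtl_is_top_call(small_cnur):
    co = small_cnur
    y = log_trait(co, "CL_IS")
    grid = make_windows(co.genotypes.marker_map, 1_000_000)
    post = run_bayesb(
        y, None, co.genotypes, _short_cfg(seed=40), pen=co.phenotypes["pen"].to_numpy()
    )
    wins = window_variance(post, grid, co.genotypes)
    calls = call_qtl(wins, post)
    assert calls, "no QTL called on a cohort with a planted QTL"
    qidx = co.truth.qtl_index
    top = calls[0]
    focal = next(w for w in wins if qidx in w.marker_indices)
    assert top.window == focal.window
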