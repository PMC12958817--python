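import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from stressqtl import varcomp as vc
from stressqtl.io import GenotypeMatrix
from stressqtl.simulate import scaled_preset, simulate_cohort, simulate_genotypes

from conftest import log_trait


def _toy_matrix(dosages):
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    mm = pd.DataFrame(
        {
            "chrom": ["chr1"] * m,
            "pos": np.arange(100, 100 + 100 * m, 100),
            "id": [f"s{j}" for j in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=d, marker_map=mm, sample_ids=[f"i{i}" for i in range(n)])


# ---------------------------------------------------------------------------
# GRM
# ---------------------------------------------------------------------------

def test_grm_vanraden1_hand_example():
    G = _toy_matrix([[0, 2], [1, 1], [2, 0]])
    A = vc.compute_grm(G, method="vanraden1").matrix
    # p = 0.5 for both markers; W = G - 1; denom = 2*(0.25+0.25) = 1
    expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
    np.testing.assert_allclose(A, expected, atol=1e-12)


def test_grm_row_sums_zero():
    cfg = scaled_preset("cl_cnur", n_individuals=60, n_markers=200)
    G = simulate_genotypes(cfg, seed=21)
    for method in ("vanraden1", "standardized"):
        A = vc.compute_grm(G, method=method).matrix
        np.testing.assert_allclose(A.sum(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(A, A.T, atol=1e-12)


def test_grm_standardized_mean_diag_near_one():
    cfg = scaled_preset("cl_cnur", n_individuals=100, n_markers=400)
    G = simulate_genotypes(cfg, seed=22)
    A = vc.compute_grm(G, method="standardized").matrix
    assert abs(np.mean(np.diag(A)) - 1.0) < 0.15


def test_grm_monomorphic_markers_dropped():
    G = _toy_matrix([[0, 2, 1], [1, 2, 0], [2, 2, 2]])
    g = vc.compute_grm(G, method="vanraden1")
    assert g.n_markers == 2  # the all-2 marker is excluded


def test_grm_unknown_method():
    G = _toy_matrix([[0, 2], [1, 1], [2, 0]])
    with pytest.raises(ValueError):
        vc.compute_grm(G, method="vanraden7")


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------

def test_build_design_drops_aliased():
    n = 12
    batch = np.repeat(["a", "b", "c"], 4)
    dup = np.repeat(["a", "b", "c"], 4)  # identical factor: fully aliased
    X, names = vc.build_design(n, factors={"batch": batch, "dup": dup})
    assert np.linalg.matrix_rank(X) == X.shape[1] == 3
    assert names[0] == "intercept"


def test_design_from_table_matches_build_design():
    tbl = pd.DataFrame(
        {"batch": ["a", "a", "b", "b"], "age": [40.0, 50.0, 45.0, 55.0]}
    )
    X1, n1 = vc.design_from_table(tbl, factors=["batch"], covariates=["age"])
    X2, n2 = vc.build_design(
        4, factors={"batch": tbl["batch"].to_numpy()},
        covariates={"age": tbl["age"].to_numpy()},
    )
    np.testing.assert_allclose(X1, X2)
    assert n1 == n2


def test_gls_matches_ols_under_identity():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    y = X @ [1.0, 2.0] + rng.normal(size=30)
    b, cov = vc.gls_fixed_effects(y, X, np.eye(30))
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(b, ols, atol=1e-10)


# ---------------------------------------------------------------------------
# univariate REML: grid oracle
# ---------------------------------------------------------------------------

def _profile_restricted_loglik(y, X, A, h2):
    """Restricted log-likelihood with the phenotypic variance profiled out."""
    n, p = X.shape
    K = h2 * A + (1.0 - h2) * np.eye(n)
    Kinv = linalg.inv(K)
    XtKX = X.T @ Kinv @ X
    P = Kinv - Kinv @ X @ linalg.inv(XtKX) @ X.T @ Kinv
    s2 = float(y @ P @ y) / (n - p)
    sign, logdetK = np.linalg.slogdet(K)
    sign2, logdetX = np.linalg.slogdet(XtKX)
    return -0.5 * ((n - p) * (np.log(s2) + 1.0) + logdetK + logdetX)


def test_reml_grid_oracle_small():
    rng = np.random.default_rng(77)
    cfg = scaled_preset("cl_cnur", n_individuals=30, n_markers=100)
    G = simulate_genotypes(cfg, seed=30)
    grm = vc.compute_grm(G, method="standardized")
    A = grm.matrix
    L = np.linalg.cholesky(A + 1e-6 * np.eye(30))
    y = 0.8 * (L @ rng.normal(size=30)) + rng.normal(size=30)
    fit = vc.fit_univariate(y, None, grm)
    X = np.ones((30, 1))
    grid = np.linspace(0.001, 0.999, 50)
    grid_ll = max(_profile_restricted_loglik(y, X, A, h) for h in grid)
    fit_ll = _profile_restricted_loglik(y, X, A, min(max(fit.h2, 1e-6), 1 - 1e-6))
    assert fit_ll >= grid_ll - 1e-6


def test_reml_null_heritability_near_zero():
    cfg = scaled_preset("cl_cnur", n_individuals=200, n_markers=400)
    G = simulate_genotypes(cfg, seed=31)
    grm = vc.compute_grm(G, method="standardized")
    rng = np.random.default_rng(5)
    h2s = [
        vc.fit_univariate(rng.normal(size=200), None, grm).h2 for _ in range(10)
    ]
    assert np.mean(h2s) <= 0.08


def test_reml_recovers_planted_heritability():
    cfg = scaled_preset("cl_cnur", n_individuals=300, n_markers=600)
    G = simulate_genotypes(cfg, seed=32)
    grm = vc.compute_grm(G, method="standardized")
    L = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(300))
    rng = np.random.default_rng(6)
    h2s = []
    for _ in range(8):
        g = L @ rng.normal(size=300) * np.sqrt(0.4)
        y = g + rng.normal(size=300) * np.sqrt(0.6)
        h2s.append(vc.fit_univariate(y, None, grm).h2)
    assert abs(np.mean(h2s) - 0.4) < 0.12


def test_fit_univariate_missing_phenotypes_dropped(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS").copy()
    y[:10] = np.nan
    fit = vc.fit_univariate(y, None, grm, pen=small_cnur.phenotypes["pen"])
    assert fit.n == 140
    assert 0.0 <= fit.h2 <= 1.0


def test_pen_component_estimated(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS")
    fit = vc.fit_univariate(y, None, grm, pen=small_cnur.phenotypes["pen"])
    assert set(fit.variances) == {"genetic", "pen", "residual"}
    assert all(v >= 0 for v in fit.variances.values())
    assert fit.phenotypic_variance() == pytest.approx(sum(fit.variances.values()))


# ---------------------------------------------------------------------------
# bivariate REML
# ---------------------------------------------------------------------------

def test_bivariate_duplicate_trait_rg_near_one(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS")
    rng = np.random.default_rng(9)
    y2 = y + 0.05 * rng.normal(size=y.size)
    fit = vc.fit_bivariate(y, y2, grm=grm)
    assert fit.rg > 0.9


def test_bivariate_independent_traits_rg_near_zero():
    cfg = scaled_preset("cl_cnur", n_individuals=250, n_markers=500)
    G = simulate_genotypes(cfg, seed=33)
    grm = vc.compute_grm(G, method="standardized")
    L = np.linalg.cholesky(grm.matrix + 1e-6 * np.eye(250))
    rng = np.random.default_rng(12)
    rgs = []
    for _ in range(6):
        g1 = L @ rng.normal(size=250) * np.sqrt(0.4)
        g2 = L @ rng.normal(size=250) * np.sqrt(0.4)
        y1 = g1 + rng.normal(size=250) * np.sqrt(0.6)
        y2 = g2 + rng.normal(size=250) * np.sqrt(0.6)
        rgs.append(vc.fit_bivariate(y1, y2, grm=grm).rg)
    assert abs(np.mean(rgs)) < 0.25


def test_bivariate_matches_univariate_variances(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS")
    uni = vc.fit_univariate(y, None, grm)
    rng = np.random.default_rng(3)
    y2 = rng.permutation(y)
    biv = vc.fit_bivariate(y, y2, grm=grm)
    assert biv.genetic[0, 0] == pytest.approx(uni.variances["genetic"], rel=0.25, abs=0.01)
    assert biv.residual[0, 0] == pytest.approx(uni.variances["residual"], rel=0.25, abs=0.01)


def test_bivariate_overlap_guard():
    y1 = np.r_[np.ones(60), np.full(60, np.nan)] + np.random.default_rng(1).normal(size=120)
    y2 = np.r_[np.full(60, np.nan), np.ones(60)] + np.random.default_rng(2).normal(size=120)
    with pytest.raises(ValueError, match="both traits"):
        vc.fit_bivariate(y1, y2, grm=np.eye(120))


def test_lrt_genetic_correlation_strong_signal(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS")
    rng = np.random.default_rng(14)
    y2 = y + 0.1 * rng.normal(size=y.size)
    full = vc.fit_bivariate(y, y2, grm=grm)
    stat, p = vc.lrt_genetic_correlation(y, y2, grm=grm, full_fit=full)
    assert stat > 3.84 and p < 0.05


# ---------------------------------------------------------------------------
# fixed-effect LRT
# ---------------------------------------------------------------------------

def test_lrt_fixed_effect_identical_designs(small_cnur):
    grm = vc.compute_grm(small_cnur.genotypes, method="standardized")
    y = log_trait(small_cnur, "CL_IS")
    X, _ = vc.design_from_table(small_cnur.phenotypes, factors=["batch"])
    stat, p = vc.lrt_fixed_effect(y, X, X, grm)
    assert stat == 0.0 and p == 1.0


def test_lrt_fixed_effect_strong_factor():
    cfg = scaled_preset("cl_cnur", n_individuals=150, n_markers=300)
    G = simulate_genotypes(cfg, seed=34)
    grm = vc.compute_grm(G, method="standardized")
    rng = np.random.default_rng(15)
    group = np.repeat([0, 1], 75)
    y = 2.0 * group + rng.normal(size=150)
    Xw = np.column_stack([np.ones(150), group.astype(float)])
    Xo = np.ones((150, 1))
    stat, p = vc.lrt_fixed_effect(y, Xw, Xo, grm)
    assert p < 1e-3


def test_lrt_fixed_effect_rejects_non_nested():
    rng = np.random.default_rng(16)
    y = rng.normal(size=40)
    Xw = np.column_stack([np.ones(40), rng.normal(size=40)])
    Xo = np.column_stack([np.ones(40), rng.normal(size=40)])
    with pytest.raises(ValueError, match="nested"):
        vc.lrt_fixed_effect(y, Xw, Xo, np.eye(40))


def test_lrt_fixed_effect_null_type_one_error():
    cfg = scaled_preset("cl_cnur", n_individuals=80, n_markers=200)
    G = simulate_genotypes(cfg, seed=35)
    grm = vc.compute_grm(G, method="standardized")
    rng = np.random.default_rng(17)
    Xo = np.ones((80, 1))
    rejections = 0
    n_tests = 60
    for _ in range(n_tests):
        y = rng.normal(size=80)
        Xw = np.column_stack([np.ones(80), rng.normal(size=80)])
        _, p = vc.lrt_fixed_effect(y, Xw, Xo, grm)
        rejections += p < 0.05
    # binomial(60, 0.05): >= 10 rejections has probability < 1e-3
    assert rejections <= 9
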