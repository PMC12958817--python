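"""Single-variant effect estimation and group contrasts around a called QTL.

All effect models are two-stage: variance components are estimated once by
REML (GRM + optional pen + residual), then the SNP terms are fit by
generalized least squares with that covariance held fixed.  Effects are
reported per extra copy of the minor allele, on the log scale and in
phenotypic standard deviations (PSD) of the fixed-effect-adjusted log
trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .varcomp import Grm, fit_univariate, gls_fixed_effects

__all__ = [
    "SnpEffect",
    "LdPair",
    "GroupEffects",
    "allele_substitution_effect",
    "percent_change",
    "percent_reduction",
    "ld_r2",
    "effect_by_group",
]

logger = logging.getLogger(__name__)


@dataclass
class SnpEffect:
    marker_id: str
    beta_log: float          # per extra copy of the minor allele, log scale
    se_log: float
    beta_psd: float          # beta_log / SD of the adjusted log trait
    se_psd: float
    p_value: float
    maf: float


@dataclass
class LdPair:
    marker_a: str
    marker_b: str
    r2: float


@dataclass
class GroupEffects:
    effects: dict[str, SnpEffect]     # estimable groups only
    inestimable: list[str]            # groups monomorphic for the marker
    common: SnpEffect                 # pooled single-slope fit
    lrt_stat: float
    lrt_df: int
    p_interaction: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _minor_dosage(dosage: np.ndarray) -> tuple[np.ndarray, float]:
    """Dosage counting the minor allele, plus its sample frequency."""
    d = np.asarray(dosage, dtype=float)
    p = d.mean() / 2.0
    if p > 0.5:
        d = 2.0 - d
        p = 1.0 - p
    return d, float(p)


def _fixed_covariance(y, X, grm: Grm, pen) -> tuple[np.ndarray, float]:
    """REML covariance matrix of y given X, and the adjusted phenotypic SD."""
    fit = fit_univariate(y, X, grm, pen=pen)
    n = y.shape[0]
    structures: dict[str, np.ndarray] = {"genetic": grm.matrix, "residual": np.eye(n)}
    if pen is not None:
        labels, codes = np.unique(np.asarray(pen), return_inverse=True)
        Zp = np.zeros((n, labels.size))
        Zp[np.arange(n), codes] = 1.0
        structures["pen"] = Zp @ Zp.T
    V = fit.covariance_matrix({k: structures[k] for k in fit.variances})
    # PSD denominator: SD of the log trait after fixed-effect adjustment
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    dof = max(n - np.linalg.matrix_rank(X), 1)
    psd = float(np.sqrt(resid @ resid / dof))
    return V, psd


def _gls_quadform(y, X, V):
    """GLS coefficients, their covariance, and the residual quadratic form."""
    b, cov_b = gls_fixed_effects(y, X, V)
    r = y - X @ b
    cf = linalg.cho_factor(V, lower=True)
    quad = float(r @ linalg.cho_solve(cf, r))
    return b, cov_b, quad


def _with_intercept(fixed, n: int) -> np.ndarray:
    if fixed is None:
        return np.ones((n, 1))
    X = np.asarray(fixed, dtype=float)
    return X if X.ndim == 2 else X[:, None]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def allele_substitution_effect(
    y: np.ndarray,
    dosage: np.ndarray,
    fixed: np.ndarray | None,
    grm: Grm,
    pen: np.ndarray | None = None,
    marker_id: str = "snp",
) -> SnpEffect:
    """GLS allele-substitution effect with GRM covariance fixed at REML.

    The effect is per extra copy of the minor allele; `p_value` is the
    two-sided Wald test.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    d, maf = _minor_dosage(np.asarray(dosage, dtype=float)[ok])
    if np.var(d) == 0.0:
        raise ValueError("dosage is monomorphic in the analyzed individuals")
    n = y.shape[0]
    X = _with_intercept(fixed, ok.size)[ok]
    if not ok.all():
        idx = ok.nonzero()[0]
        grm = Grm(matrix=grm.matrix[np.ix_(idx, idx)],
                  n_markers=grm.n_markers, method=grm.method)
        if pen is not None:
            pen = np.asarray(pen)[ok]

    V, psd = _fixed_covariance(y, X, grm, pen)
    Xd = np.column_stack([X, d - d.mean()])
    b, cov_b, _ = _gls_quadform(y, Xd, V)
    beta = float(b[-1])
    se = float(np.sqrt(max(cov_b[-1, -1], 0.0)))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    return SnpEffect(
        marker_id=marker_id,
        beta_log=beta,
        se_log=se,
        beta_psd=beta / psd,
        se_psd=se / psd,
        p_value=p,
        maf=maf,
    )


def percent_change(beta_log: float) -> float:
    """Signed percent change on the original hormone scale."""
    if not np.isfinite(beta_log):
        raise ValueError("beta must be finite")
    return float(100.0 * (np.exp(beta_log) - 1.0))


def percent_reduction(beta_log: float) -> float:
    """Magnitude of a reduction: 100*(1 - exp(beta)) for beta < 0."""
    return float(abs(100.0 * (1.0 - np.exp(beta_log))))


def ld_r2(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    marker_a: str = "a",
    marker_b: str = "b",
) -> LdPair:
    """Composite LD: squared Pearson correlation of unphased dosages."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        raise ValueError("zero-variance dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return LdPair(marker_a=marker_a, marker_b=marker_b, r2=float(r * r))


def effect_by_group(
    y: np.ndarray,
    dosage: np.ndarray,
    group: np.ndarray,
    fixed: np.ndarray | None,
    grm: Grm,
    pen: np.ndarray | None = None,
    marker_id: str = "snp",
) -> GroupEffects:
    """Group-nested allele-substitution slopes with an interaction LRT.

    Both models contain group main effects; the null model has one common
    dosage slope, the alternative one slope per group in which the marker
    segregates.  Monomorphic groups are excluded from the slope contrast
    (reported as inestimable) but keep their main effect.  The LRT uses the
    GLS log-likelihood with the REML covariance held fixed, so the log|V|
    terms cancel.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    y = y[ok]
    group = np.asarray(group)[ok]
    d, maf = _minor_dosage(np.asarray(dosage, dtype=float)[ok])
    X0 = _with_intercept(fixed, ok.size)[ok]
    if pen is not None:
        pen = np.asarray(pen)[ok]
    if not ok.all():
        idx = ok.nonzero()[0]
        grm = Grm(matrix=grm.matrix[np.ix_(idx, idx)],
                  n_markers=grm.n_markers, method=grm.method)

    levels = [lev for lev in np.unique(group)]
    estimable, inestimable = [], []
    for lev in levels:
        if np.var(d[group == lev]) > 0.0:
            estimable.append(lev)
        else:
            inestimable.append(str(lev))
            logger.info("group %r is monomorphic for %s; slope inestimable", lev, marker_id)
    if len(estimable) == 0:
        raise ValueError("marker is monomorphic in every group")

    # shared base design: fixed effects + group main effects (treatment
    # coding); aliased columns dropped in case the caller's design already
    # encodes the group factor
    from .varcomp import drop_aliased

    base = [X0] + [(group == lev).astype(float)[:, None] for lev in levels[1:]]
    Xb, _ = drop_aliased(np.column_stack(base))
    dc = d - d.mean()
    in_est = np.isin(group, estimable)
    d_common = np.where(in_est, dc, 0.0)

    V, psd = _fixed_covariance(y, Xb, grm, pen)

    X_null = np.column_stack([Xb, d_common])
    b0, cov0, q0 = _gls_quadform(y, X_null, V)
    beta_c = float(b0[-1])
    se_c = float(np.sqrt(max(cov0[-1, -1], 0.0)))
    common = SnpEffect(
        marker_id=marker_id,
        beta_log=beta_c,
        se_log=se_c,
        beta_psd=beta_c / psd,
        se_psd=se_c / psd,
        p_value=float(2.0 * stats.norm.sf(abs(beta_c) / se_c)) if se_c > 0 else 0.0,
        maf=maf,
    )

    slope_cols = [
        np.where(group == lev, dc, 0.0)[:, None] for lev in estimable
    ]
    X_alt = np.column_stack([Xb] + slope_cols)
    b1, cov1, q1 = _gls_quadform(y, X_alt, V)

    k = Xb.shape[1]
    effects: dict[str, SnpEffect] = {}
    for i, lev in enumerate(estimable):
        beta = float(b1[k + i])
        se = float(np.sqrt(max(cov1[k + i, k + i], 0.0)))
        effects[str(lev)] = SnpEffect(
            marker_id=marker_id,
            beta_log=beta,
            se_log=se,
            beta_psd=beta / psd,
            se_psd=se / psd,
            p_value=float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0,
            maf=maf,
        )

    df = len(estimable) - 1
    stat = max(q0 - q1, 0.0)
    p_int = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return GroupEffects(
        effects=effects,
        inestimable=inestimable,
        common=common,
        lrt_stat=float(stat),
        lrt_df=df,
        p_interaction=p_int,
    )
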