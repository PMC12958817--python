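"""BayesB whole-genome regression, window %EGV, QTL calls, and pleiotropy.

The samplers themselves live in :mod:`stressqtl._samplers` (numba kernels);
this module owns the priors, bookkeeping, and posterior summaries:

* :func:`run_bayesb` / :func:`run_bivariate_bayes` — uni/bivariate BayesB.
* :func:`window_variance` — per-window percentage of estimated genetic
  variance (%EGV), with the per-iteration total genetic variance as the
  denominator.
* :func:`call_qtl` — windows with %EGV > 1, lead SNPs with PIP >= 0.01.
* :func:`conditional_scan` — rerun with lead-SNP dosages as fixed covariates.
* :func:`adjust_for_baseline` — mixed-model regression of the infectious
  trait on its noninfectious baseline.
* :func:`pleiotropy_ad` — absolute difference in posterior probability of a
  positive vs negative within-window genetic covariance (0.25 Mb windows).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._samplers import bayesb_bivariate, bayesb_univariate
from .io import GenotypeMatrix, WindowGrid
from .varcomp import compute_grm, drop_aliased, fit_univariate

__all__ = [
    "McmcConfig",
    "GwasPosterior",
    "JointGwasPosterior",
    "WindowVariance",
    "QtlCall",
    "PleioResult",
    "BaselineAdjustment",
    "run_bayesb",
    "run_bivariate_bayes",
    "window_variance",
    "windows_to_frame",
    "call_qtl",
    "conditional_scan",
    "adjust_for_baseline",
    "pleiotropy_ad",
    "pleio_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class McmcConfig:
    """Sampler settings; desk-scale defaults (the paper ran 80,000/10,000)."""

    chain_length: int = 4000
    burn_in: int = 500
    thin: int = 2
    pi: float = 0.99
    effect_df: float = 4.0
    effect_scale: float | None = None   # solved from prior_genetic_var if None
    residual_df: float = 4.0
    pen_df: float = 4.0
    prior_genetic_var: float | None = None  # quick REML estimate if None
    seed: int = 0

    def validate(self) -> None:
        if not self.burn_in < self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must lie in (0, 1)")
        if self.thin < 1 or (self.chain_length - self.burn_in) % self.thin:
            raise ValueError("chain_length - burn_in must be divisible by thin")
        if self.effect_df <= 2 or self.residual_df <= 2 or self.pen_df <= 2:
            raise ValueError("prior degrees of freedom must exceed 2")


@dataclass
class GwasPosterior:
    marker_ids: list[str]
    effects: np.ndarray                 # posterior mean per marker
    pip: np.ndarray                     # posterior inclusion probability
    samples: np.ndarray                 # n_save x m thinned effect samples
    fixed_effects: np.ndarray           # posterior means
    fixed_names: list[str]
    sigma2e_trace: np.ndarray
    pen_var_trace: np.ndarray
    n_included_trace: np.ndarray
    genetic_var_trace: np.ndarray       # var across individuals of Z a(t)
    psrf_sigma2e: float
    psrf_genetic_var: float
    config: McmcConfig


@dataclass
class JointGwasPosterior:
    marker_ids: list[str]
    effects1: np.ndarray
    effects2: np.ndarray
    pip: np.ndarray
    samples1: np.ndarray
    samples2: np.ndarray
    fixed_effects1: np.ndarray
    fixed_effects2: np.ndarray
    fixed_names: list[str]
    residual_cov_trace: np.ndarray      # n_save x 3: R11, R12, R22
    config: McmcConfig


@dataclass
class WindowVariance:
    window: str
    chrom: str
    start: int
    end: int
    n_markers: int
    egv_pct: float                      # posterior mean %EGV
    egv_sd: float
    p_egv_gt1: float                    # posterior P(%EGV > 1)
    marker_indices: np.ndarray = field(repr=False)


@dataclass
class QtlCall:
    window: str
    egv_pct: float
    lead_snps: list[tuple[str, float]]  # (marker id, PIP), PIP >= 0.01


@dataclass
class PleioResult:
    window: str
    chrom: str
    start: int
    end: int
    p_pos: float
    p_neg: float
    ad: float
    pleiotropic: bool


@dataclass
class BaselineAdjustment:
    adjusted: np.ndarray
    coefficient: float
    se: float
    p_value: float


# ---------------------------------------------------------------------------
# shared preparation
# ---------------------------------------------------------------------------

def _psrf(trace: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one trace."""
    x = np.asarray(trace, dtype=float)
    half = x.size // 2
    if half < 2:
        return float("nan")
    chains = np.stack([x[:half], x[half : 2 * half]])
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((w * (half - 1) / half + b / half) / w))


def _pen_layout(pen: np.ndarray | None, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted index / offset arrays for per-level residual sums in the kernel."""
    if pen is None:
        return np.zeros(0, dtype=np.int64), np.zeros(1, dtype=np.int64)
    pen = np.asarray(pen)
    if pen.shape[0] != n:
        raise ValueError("pen labels must match the phenotype length")
    _, codes = np.unique(pen, return_inverse=True)
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return order, starts


def _prepare(
    y: np.ndarray,
    fixed: np.ndarray | None,
    G: GenotypeMatrix,
    cfg: McmcConfig,
    pen: np.ndarray | None,
    exclude_markers: list[str] | None,
    n_extra_fixed: int = 0,
):
    cfg.validate()
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n != G.dosages.shape[0]:
        raise ValueError("phenotype and genotype sample sizes differ")
    if np.isnan(y).any():
        raise ValueError("y must be complete for the included individuals")

    if fixed is None:
        X = np.ones((n, 1))
        names = ["intercept"]
    else:
        X = np.asarray(fixed, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    Xr, kept = drop_aliased(X, names)
    if n_extra_fixed and Xr.shape[1] < X.shape[1]:
        dropped = sorted(set(names) - set(kept))
        if any(name in names[-n_extra_fixed:] for name in dropped):
            raise ValueError(
                "covariate dosage is aliased with the fixed design: "
                + ", ".join(dropped)
            )
    X = np.ascontiguousarray(Xr)

    Z = G.dosage_float()
    Z = Z - Z.mean(axis=0)
    if exclude_markers:
        for mid in exclude_markers:
            Z[:, G.marker_index(mid)] = 0.0
    Z = np.ascontiguousarray(Z)

    pen_idx, pen_starts = _pen_layout(pen, n)
    return y, X, kept, Z, pen_idx, pen_starts


def _solve_priors(
    y: np.ndarray,
    X: np.ndarray,
    G: GenotypeMatrix,
    Z: np.ndarray,
    cfg: McmcConfig,
    pen: np.ndarray | None,
):
    """Effect/residual/pen prior scales anchored on a quick REML fit."""
    if cfg.prior_genetic_var is None:
        grm = compute_grm(G, method="standardized")
        fit = fit_univariate(y, X, grm, pen=pen)
        var_g = float(fit.variances["genetic"])
        var_e = float(fit.variances["residual"])
        var_p = float(fit.variances.get("pen", 0.1 * np.var(y)))
    else:
        var_g = float(cfg.prior_genetic_var)
        var_e = max(float(np.var(y)) - var_g, 0.05 * float(np.var(y)))
        var_p = 0.1 * float(np.var(y))

    sum_zz = float(np.sum(np.var(Z, axis=0)))
    nu = cfg.effect_df
    if cfg.effect_scale is not None:
        s2_a = float(cfg.effect_scale)
    else:
        # prior mean of a marker variance is nu*S/(nu-2); expected genetic
        # variance = (1-pi) * sum_j var(z_j) * prior mean marker variance
        s2_a = var_g * (nu - 2.0) / (nu * (1.0 - cfg.pi) * sum_zz)
    s2_e = var_e * (cfg.residual_df - 2.0) / cfg.residual_df
    s2_p = max(var_p, 1e-8) * (cfg.pen_df - 2.0) / cfg.pen_df
    return s2_a, s2_e, s2_p, var_g, var_e


# ---------------------------------------------------------------------------
# univariate
# ---------------------------------------------------------------------------

def run_bayesb(
    y: np.ndarray,
    fixed: np.ndarray | None,
    G: GenotypeMatrix,
    cfg: McmcConfig,
    pen: np.ndarray | None = None,
    exclude_markers: list[str] | None = None,
    _n_extra_fixed: int = 0,
) -> GwasPosterior:
    """Single-trait BayesB; deterministic given (data, cfg, cfg.seed)."""
    y, X, names, Z, pen_idx, pen_starts = _prepare(
        y, fixed, G, cfg, pen, exclude_markers, _n_extra_fixed
    )
    s2_a, s2_e, s2_p, _, _ = _solve_priors(y, X, G, Z, cfg, pen)

    try:
        (
            samples,
            pip,
            alpha_mean,
            beta_mean,
            s2e_trace,
            penvar_trace,
            ninc_trace,
        ) = bayesb_univariate(
            y,
            X,
            Z,
            pen_idx,
            pen_starts,
            cfg.chain_length,
            cfg.burn_in,
            cfg.thin,
            cfg.pi,
            cfg.effect_df,
            s2_a,
            cfg.residual_df,
            s2_e,
            cfg.pen_df,
            s2_p,
            int(cfg.seed) % (2**31 - 1),
        )
    except FloatingPointError as err:  # pragma: no cover - divergence guard
        raise RuntimeError(
            f"BayesB chain diverged (seed {cfg.seed}, pi {cfg.pi}): {err}"
        ) from err

    gvals = Z @ samples.T                       # n x n_save
    gvar_trace = gvals.var(axis=0, ddof=1)
    psrf_e = _psrf(s2e_trace)
    psrf_g = _psrf(gvar_trace)
    for label, val in (("sigma2e", psrf_e), ("genetic variance", psrf_g)):
        if np.isfinite(val) and val > 1.1:
            warnings.warn(
                f"split-chain PSRF for {label} is {val:.3f} (> 1.1); "
                "consider a longer chain",
                stacklevel=2,
            )

    return GwasPosterior(
        marker_ids=list(G.marker_map["id"]),
        effects=alpha_mean,
        pip=pip,
        samples=samples,
        fixed_effects=beta_mean,
        fixed_names=names,
        sigma2e_trace=s2e_trace,
        pen_var_trace=penvar_trace,
        n_included_trace=ninc_trace,
        genetic_var_trace=gvar_trace,
        psrf_sigma2e=psrf_e,
        psrf_genetic_var=psrf_g,
        config=cfg,
    )


def conditional_scan(
    y: np.ndarray,
    fixed: np.ndarray | None,
    covariate_dosages: np.ndarray,
    G: GenotypeMatrix,
    cfg: McmcConfig,
    pen: np.ndarray | None = None,
    exclude_markers: list[str] | None = None,
) -> GwasPosterior:
    """Rerun the sampler with marker dosages as extra fixed covariates.

    The covariate markers themselves must be excluded from the sampled set
    (pass their ids in ``exclude_markers``); aliasing of a covariate with
    the existing design raises.
    """
    cov = np.asarray(covariate_dosages, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    cov = cov - cov.mean(axis=0)
    if np.any(np.all(cov == 0.0, axis=0)):
        raise ValueError("covariate dosage column is constant (aliased)")
    n = cov.shape[0]
    base = np.ones((n, 1)) if fixed is None else np.asarray(fixed, dtype=float)
    X = np.column_stack([base, cov])
    return run_bayesb(
        y,
        X,
        G,
        cfg,
        pen=pen,
        exclude_markers=exclude_markers,
        _n_extra_fixed=cov.shape[1],
    )


def adjust_for_baseline(
    y_is: np.ndarray,
    y_nis: np.ndarray,
    fixed: np.ndarray | None,
    grm,
    pen: np.ndarray | None = None,
) -> BaselineAdjustment:
    """Regress the infectious-stress trait on its noninfectious baseline.

    The coefficient comes from the univariate mixed model with the baseline
    appended to the fixed design; the adjusted phenotype is
    ``y_is - b * y_nis`` (missing wherever either trait is missing).
    """
    y_is = np.asarray(y_is, dtype=float)
    y_nis = np.asarray(y_nis, dtype=float)
    ok = ~np.isnan(y_is) & ~np.isnan(y_nis)
    if not ok.any():
        raise ValueError("no individuals observed for both traits")
    n = y_is.shape[0]
    base = np.ones((n, 1)) if fixed is None else np.asarray(fixed, dtype=float)
    cov = y_nis - np.nanmean(y_nis)
    X = np.column_stack([base, cov])
    names = [f"x{j}" for j in range(base.shape[1])] + ["baseline"]
    fit = fit_univariate(
        np.where(ok, y_is, np.nan), X, grm, pen=pen, fixed_names=names
    )
    row = fit.fixed_effects.set_index("term").loc["baseline"]
    b = float(row["estimate"])
    se = float(row["se"])
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else 0.0
    adjusted = np.where(ok, y_is - b * y_nis, np.nan)
    return BaselineAdjustment(adjusted=adjusted, coefficient=b, se=se, p_value=p)


# ---------------------------------------------------------------------------
# bivariate
# ---------------------------------------------------------------------------

def run_bivariate_bayes(
    y1: np.ndarray,
    y2: np.ndarray,
    fixed: np.ndarray | None,
    G: GenotypeMatrix,
    cfg: McmcConfig,
    pen: np.ndarray | None = None,
    exclude_markers: list[str] | None = None,
) -> JointGwasPosterior:
    """Two-trait BayesB with one shared inclusion indicator.

    Restricted to individuals observed for both traits; a single fixed
    design is used for both traits.
    """
    cfg.validate()
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    ok = ~np.isnan(y1) & ~np.isnan(y2)
    if ok.sum() < 10:
        raise ValueError("too few individuals observed for both traits")
    if not ok.all():
        keep = np.flatnonzero(ok)
        G = GenotypeMatrix(
            dosages=G.dosages[keep],
            marker_map=G.marker_map,
            sample_ids=[G.sample_ids[i] for i in keep],
        )
        y1 = y1[keep]
        y2 = y2[keep]
        if fixed is not None:
            fixed = np.asarray(fixed, dtype=float)[keep]
        if pen is not None:
            pen = np.asarray(pen)[keep]

    y1p, X, names, Z, pen_idx, pen_starts = _prepare(
        y1, fixed, G, cfg, pen, exclude_markers
    )
    s2_a1, s2_e1, s2_p1, _, _ = _solve_priors(y1p, X, G, Z, cfg, pen)
    s2_a2, s2_e2, s2_p2, _, _ = _solve_priors(y2, X, G, Z, cfg, pen)

    try:
        (
            samples1,
            samples2,
            pip,
            beta1,
            beta2,
            r_trace,
        ) = bayesb_bivariate(
            y1p,
            y2,
            X,
            Z,
            pen_idx,
            pen_starts,
            cfg.chain_length,
            cfg.burn_in,
            cfg.thin,
            cfg.pi,
            cfg.effect_df,
            s2_a1,
            s2_a2,
            cfg.residual_df,
            s2_e1,
            s2_e2,
            cfg.pen_df,
            s2_p1,
            s2_p2,
            int(cfg.seed) % (2**31 - 1),
        )
    except FloatingPointError as err:  # pragma: no cover - divergence guard
        raise RuntimeError(
            f"bivariate BayesB chain diverged (seed {cfg.seed}): {err}"
        ) from err

    return JointGwasPosterior(
        marker_ids=list(G.marker_map["id"]),
        effects1=samples1.mean(axis=0),
        effects2=samples2.mean(axis=0),
        pip=pip,
        samples1=samples1,
        samples2=samples2,
        fixed_effects1=beta1,
        fixed_effects2=beta2,
        fixed_names=names,
        residual_cov_trace=r_trace,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# window summaries
# ---------------------------------------------------------------------------

def _window_blocks(grid: WindowGrid, G: GenotypeMatrix):
    """(window row, marker index array) for every grid window, grid order."""
    assign = grid.assign_markers(G.marker_map)
    by_window: dict[str, np.ndarray] = {
        w: idx.to_numpy() for w, idx in assign.groupby(assign).groups.items()
    }
    blocks = []
    for _, row in grid.windows.iterrows():
        blocks.append((row, by_window.get(row["window"], np.zeros(0, dtype=int))))
    return blocks


def window_variance(
    post: GwasPosterior,
    grid: WindowGrid,
    G: GenotypeMatrix,
    samples: np.ndarray | None = None,
) -> list[WindowVariance]:
    """Per-window %EGV from the thinned effect samples.

    For each saved iteration t the window's genetic values are
    ``Z_w a_w(t)``; the statistic is the posterior mean of
    ``100 * var(Z_w a_w(t)) / var(Z a(t))`` across individuals, where the
    denominator is that iteration's total genetic variance.  Iterations
    with zero total variance contribute 0 to every window (and are logged).
    """
    if samples is None:
        samples = post.samples
    if samples.size == 0:
        raise ValueError("posterior has no saved samples")
    Z = G.dosage_float()
    Z = Z - Z.mean(axis=0)
    total = (Z @ samples.T).var(axis=0, ddof=1)
    zero = total <= 0.0
    if zero.any():
        logger.info(
            "%d of %d iterations had zero total genetic variance; "
            "they contribute 0%% EGV to every window",
            int(zero.sum()),
            total.size,
        )
    safe_total = np.where(zero, 1.0, total)

    out: list[WindowVariance] = []
    for row, idx in _window_blocks(grid, G):
        if idx.size == 0:
            pct = np.zeros(samples.shape[0])
        else:
            gw = Z[:, idx] @ samples[:, idx].T
            vw = gw.var(axis=0, ddof=1)
            pct = np.where(zero, 0.0, 100.0 * vw / safe_total)
        out.append(
            WindowVariance(
                window=row["window"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                n_markers=int(idx.size),
                egv_pct=float(pct.mean()),
                egv_sd=float(pct.std(ddof=1)) if pct.size > 1 else 0.0,
                p_egv_gt1=float(np.mean(pct > 1.0)),
                marker_indices=idx,
            )
        )
    return out


def windows_to_frame(windows: list[WindowVariance]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [w.window for w in windows],
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_markers": [w.n_markers for w in windows],
            "egv_pct": [w.egv_pct for w in windows],
            "egv_sd": [w.egv_sd for w in windows],
            "p_egv_gt1": [w.p_egv_gt1 for w in windows],
        }
    )


def call_qtl(
    windows: list[WindowVariance],
    post: GwasPosterior,
    egv_threshold: float = 1.0,
    pip_threshold: float = 0.01,
) -> list[QtlCall]:
    """Windows whose %EGV exceeds the threshold (strict), sorted by %EGV."""
    calls: list[QtlCall] = []
    for w in windows:
        if not w.egv_pct > egv_threshold:
            continue
        leads = [
            (post.marker_ids[j], float(post.pip[j]))
            for j in w.marker_indices
            if post.pip[j] >= pip_threshold
        ]
        leads.sort(key=lambda t: -t[1])
        calls.append(QtlCall(window=w.window, egv_pct=w.egv_pct, lead_snps=leads))
    calls.sort(key=lambda c: -c.egv_pct)
    return calls


def pleiotropy_ad(
    joint: JointGwasPosterior,
    grid: WindowGrid,
    G: GenotypeMatrix,
    threshold: float = 0.02,
) -> list[PleioResult]:
    """AD statistic per window from the bivariate posterior.

    Per saved iteration and window, the genetic covariance across
    individuals between ``Z_w a_w,1(t)`` and ``Z_w a_w,2(t)``; AD is
    ``|P(cov > 0) - P(cov < 0)|`` over iterations, flagged when strictly
    above ``threshold``.  Iterations in which the window is excluded give a
    covariance of exactly zero and count toward neither sign.
    """
    if len(joint.marker_ids) != G.dosages.shape[1]:
        raise ValueError("posterior and genotype marker sets differ")
    Z = G.dosage_float()
    Z = Z - Z.mean(axis=0)
    n = Z.shape[0]
    out: list[PleioResult] = []
    for row, idx in _window_blocks(grid, G):
        if idx.size == 0:
            p_pos = p_neg = 0.0
        else:
            g1 = Z[:, idx] @ joint.samples1[:, idx].T
            g2 = Z[:, idx] @ joint.samples2[:, idx].T
            g1 = g1 - g1.mean(axis=0)
            g2 = g2 - g2.mean(axis=0)
            cov = (g1 * g2).sum(axis=0) / (n - 1)
            p_pos = float(np.mean(cov > 0.0))
            p_neg = float(np.mean(cov < 0.0))
        ad = abs(p_pos - p_neg)
        out.append(
            PleioResult(
                window=row["window"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                p_pos=p_pos,
                p_neg=p_neg,
                ad=ad,
                pleiotropic=ad > threshold,
            )
        )
    return out


def pleio_to_frame(results: list[PleioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window": [r.window for r in results],
            "chrom": [r.chrom for r in results],
            "start": [r.start for r in results],
            "end": [r.end for r in results],
            "p_pos": [r.p_pos for r in results],
            "p_neg": [r.p_neg for r in results],
            "ad": [r.ad for r in results],
            "pleiotropic": [r.pleiotropic for r in results],
        }
    )
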