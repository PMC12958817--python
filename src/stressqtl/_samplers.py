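"""Numba Gibbs-sampling kernels for the BayesB whole-genome regressions.

Single-site samplers: per-marker inclusion indicators with prior
probability 1 - pi, marker-specific effect variances with scaled
inverse-chi-square priors, flat-prior fixed effects, an optional
independent normal pen effect, and residual (co)variance sampling.  The
bivariate kernel shares one inclusion indicator across traits with
trait-specific effects and a full 2x2 residual covariance.

Everything is deterministic given the seed (numba's own np.random state is
seeded inside each kernel).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _sample_scaled_inv_chi2(df, scale_sum):
    # scale_sum = nu * S + SS; draw nu*S + SS over chi2(df)
    return scale_sum / np.random.chisquare(df)


@njit(cache=False)
def _log_sigmoid(logodds):
    # log(odds / (1 + odds)) without overflowing exp() for large log-odds
    if logodds > 0.0:
        return -np.log1p(np.exp(-logodds))
    return logodds - np.log1p(np.exp(logodds))


@njit(cache=False)
def bayesb_univariate(
    y,
    X,
    Z,
    pen_sorted_idx,
    pen_starts,
    chain,
    burn,
    thin,
    pi,
    nu_a,
    s2_a,
    nu_e,
    s2_e,
    nu_p,
    s2_p,
    seed,
):
    """Single-trait BayesB Gibbs sampler.

    Returns (alpha_samples, pip, alpha_mean, beta_mean, sigma2e_trace,
    pen_var_trace, include_count_trace).
    """
    np.random.seed(seed)
    n, m = Z.shape
    p = X.shape[1]
    npen = pen_starts.shape[0] - 1

    xx = np.empty(p)
    for c in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, c] * X[i, c]
        xx[c] = s
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    beta = np.zeros(p)
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    s2j = np.full(m, s2_a * nu_a / max(nu_a - 2.0, 1.0))
    u_pen = np.zeros(max(npen, 1))
    sigma2e = s2_e * nu_e / max(nu_e - 2.0, 1.0)
    sigma2p = s2_p * nu_p / max(nu_p - 2.0, 1.0) if npen > 0 else 0.0

    e = y.copy()
    # initialize residual with intercept-only mean
    mu0 = 0.0
    for i in range(n):
        mu0 += y[i]
    mu0 /= n
    beta[0] = mu0
    for i in range(n):
        e[i] -= X[i, 0] * mu0

    n_save = (chain - burn) // thin
    samples = np.zeros((n_save, m))
    pip_counts = np.zeros(m)
    alpha_sum = np.zeros(m)
    beta_sum = np.zeros(p)
    s2e_trace = np.zeros(n_save)
    penvar_trace = np.zeros(n_save)
    ninc_trace = np.zeros(n_save)
    n_post = 0

    log_prior_odds = np.log(1.0 - pi) - np.log(pi)

    for it in range(chain):
        # fixed effects, flat prior
        for c in range(p):
            if xx[c] <= 0.0:
                continue
            old = beta[c]
            rhs = 0.0
            for i in range(n):
                rhs += X[i, c] * (e[i] + X[i, c] * old)
            mean = rhs / xx[c]
            newb = mean + np.random.normal() * np.sqrt(sigma2e / xx[c])
            diff = newb - old
            for i in range(n):
                e[i] -= X[i, c] * diff
            beta[c] = newb

        # pen effects, independent normal prior
        if npen > 0:
            ss_u = 0.0
            for l in range(npen):
                old = u_pen[l]
                rhs = 0.0
                cnt = 0.0
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    i = pen_sorted_idx[t]
                    rhs += e[i] + old
                    cnt += 1.0
                prec = cnt / sigma2e + 1.0 / sigma2p
                mean = (rhs / sigma2e) / prec
                newu = mean + np.random.normal() / np.sqrt(prec)
                diff = newu - old
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    e[pen_sorted_idx[t]] -= diff
                u_pen[l] = newu
                ss_u += newu * newu
            sigma2p = _sample_scaled_inv_chi2(nu_p + npen, nu_p * s2_p + ss_u)

        # markers
        n_inc = 0
        for j in range(m):
            if zz[j] <= 0.0:
                continue
            old = alpha[j]
            rhs = 0.0
            if old != 0.0:
                for i in range(n):
                    e[i] += Z[i, j] * old
            for i in range(n):
                rhs += Z[i, j] * e[i]

            # marker-specific variance: posterior if included, prior draw if not
            if delta[j] == 1:
                s2j[j] = _sample_scaled_inv_chi2(nu_a + 1.0, nu_a * s2_a + old * old)
            else:
                s2j[j] = _sample_scaled_inv_chi2(nu_a, nu_a * s2_a)

            v = zz[j] * s2j[j] + sigma2e
            logodds = (
                0.5 * np.log(sigma2e / v)
                + 0.5 * rhs * rhs * s2j[j] / (sigma2e * v)
                + log_prior_odds
            )
            if np.log(np.random.random()) < _log_sigmoid(logodds):
                prec = zz[j] + sigma2e / s2j[j]
                mean = rhs / prec
                a = mean + np.random.normal() * np.sqrt(sigma2e / prec)
                for i in range(n):
                    e[i] -= Z[i, j] * a
                alpha[j] = a
                delta[j] = 1
                n_inc += 1
            else:
                alpha[j] = 0.0
                delta[j] = 0

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2e = _sample_scaled_inv_chi2(nu_e + n, nu_e * s2_e + sse)
        if not np.isfinite(sigma2e):
            raise FloatingPointError("residual variance diverged")

        if it >= burn:
            n_post += 1
            for j in range(m):
                if delta[j] == 1:
                    pip_counts[j] += 1.0
                    alpha_sum[j] += alpha[j]
            for c in range(p):
                beta_sum[c] += beta[c]
            k = it - burn
            if k % thin == 0 and k // thin < n_save:
                t = k // thin
                for j in range(m):
                    samples[t, j] = alpha[j]
                s2e_trace[t] = sigma2e
                penvar_trace[t] = sigma2p
                ninc_trace[t] = n_inc

    pip = pip_counts / max(n_post, 1)
    alpha_mean = alpha_sum / max(n_post, 1)
    beta_mean = beta_sum / max(n_post, 1)
    return samples, pip, alpha_mean, beta_mean, s2e_trace, penvar_trace, ninc_trace


@njit(cache=False)
def _inv2(a11, a12, a22):
    det = a11 * a22 - a12 * a12
    return a22 / det, -a12 / det, a11 / det, det


@njit(cache=False)
def _sample_invwishart2(df, S11, S12, S22):
    """Draw a 2x2 inverse-Wishart(df, S) via Bartlett on S^{-1}."""
    p11, p12, p22, _ = _inv2(S11, S12, S22)
    # cholesky of P = S^{-1}
    l11 = np.sqrt(p11)
    l21 = p12 / l11
    l22 = np.sqrt(p22 - l21 * l21)
    a11 = np.sqrt(np.random.chisquare(df))
    a22 = np.sqrt(np.random.chisquare(df - 1.0))
    a21 = np.random.normal()
    # W = L A (L A)^T with A lower
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    w11 = b11 * b11
    w12 = b11 * b21
    w22 = b21 * b21 + b22 * b22
    r11, r12, r22, _ = _inv2(w11, w12, w22)
    return r11, r12, r22


@njit(cache=False)
def bayesb_bivariate(
    y1,
    y2,
    X,
    Z,
    pen_sorted_idx,
    pen_starts,
    chain,
    burn,
    thin,
    pi,
    nu_a,
    s2_a1,
    s2_a2,
    nu_r,
    S_r11,
    S_r22,
    nu_p,
    s2_p1,
    s2_p2,
    seed,
):
    """Two-trait BayesB with a shared inclusion indicator.

    Given inclusion, effects are trait-specific with independent scaled
    inverse-chi-square variance priors; the residual 2x2 covariance gets an
    inverse-Wishart prior.  Returns (samples1, samples2, pip, beta1, beta2,
    R_trace (n_save x 3)).
    """
    np.random.seed(seed)
    n, m = Z.shape
    p = X.shape[1]
    npen = pen_starts.shape[0] - 1

    xx = np.empty(p)
    for c in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, c] * X[i, c]
        xx[c] = s
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    beta1 = np.zeros(p)
    beta2 = np.zeros(p)
    a1 = np.zeros(m)
    a2 = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    s2j1 = np.full(m, s2_a1 * nu_a / max(nu_a - 2.0, 1.0))
    s2j2 = np.full(m, s2_a2 * nu_a / max(nu_a - 2.0, 1.0))
    u1 = np.zeros(max(npen, 1))
    u2 = np.zeros(max(npen, 1))
    sp1 = s2_p1 * nu_p / max(nu_p - 2.0, 1.0) if npen > 0 else 0.0
    sp2 = s2_p2 * nu_p / max(nu_p - 2.0, 1.0) if npen > 0 else 0.0
    R11 = S_r11
    R12 = 0.0
    R22 = S_r22

    e1 = y1.copy()
    e2 = y2.copy()
    mu1 = 0.0
    mu2 = 0.0
    for i in range(n):
        mu1 += y1[i]
        mu2 += y2[i]
    mu1 /= n
    mu2 /= n
    beta1[0] = mu1
    beta2[0] = mu2
    for i in range(n):
        e1[i] -= X[i, 0] * mu1
        e2[i] -= X[i, 0] * mu2

    n_save = (chain - burn) // thin
    samples1 = np.zeros((n_save, m))
    samples2 = np.zeros((n_save, m))
    pip_counts = np.zeros(m)
    R_trace = np.zeros((n_save, 3))
    n_post = 0
    log_prior_odds = np.log(1.0 - pi) - np.log(pi)

    for it in range(chain):
        w11, w12, w22, _ = _inv2(R11, R12, R22)

        # fixed effects for each trait with cross-trait residual coupling
        for c in range(p):
            if xx[c] <= 0.0:
                continue
            old = beta1[c]
            r_own = 0.0
            r_oth = 0.0
            for i in range(n):
                r_own += X[i, c] * (e1[i] + X[i, c] * old)
                r_oth += X[i, c] * e2[i]
            prec = w11 * xx[c]
            mean = (w11 * r_own + w12 * r_oth) / prec
            newb = mean + np.random.normal() / np.sqrt(prec)
            diff = newb - old
            for i in range(n):
                e1[i] -= X[i, c] * diff
            beta1[c] = newb

            old = beta2[c]
            r_own = 0.0
            r_oth = 0.0
            for i in range(n):
                r_own += X[i, c] * (e2[i] + X[i, c] * old)
                r_oth += X[i, c] * e1[i]
            prec = w22 * xx[c]
            mean = (w22 * r_own + w12 * r_oth) / prec
            newb = mean + np.random.normal() / np.sqrt(prec)
            diff = newb - old
            for i in range(n):
                e2[i] -= X[i, c] * diff
            beta2[c] = newb

        # pen effects per trait
        if npen > 0:
            ss1 = 0.0
            ss2 = 0.0
            for l in range(npen):
                old = u1[l]
                r_own = 0.0
                r_oth = 0.0
                cnt = 0.0
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    i = pen_sorted_idx[t]
                    r_own += e1[i] + old
                    r_oth += e2[i]
                    cnt += 1.0
                prec = cnt * w11 + 1.0 / sp1
                mean = (w11 * r_own + w12 * r_oth) / prec
                newu = mean + np.random.normal() / np.sqrt(prec)
                diff = newu - old
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    e1[pen_sorted_idx[t]] -= diff
                u1[l] = newu
                ss1 += newu * newu

                old = u2[l]
                r_own = 0.0
                r_oth = 0.0
                cnt = 0.0
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    i = pen_sorted_idx[t]
                    r_own += e2[i] + old
                    r_oth += e1[i]
                    cnt += 1.0
                prec = cnt * w22 + 1.0 / sp2
                mean = (w22 * r_own + w12 * r_oth) / prec
                newu = mean + np.random.normal() / np.sqrt(prec)
                diff = newu - old
                for t in range(pen_starts[l], pen_starts[l + 1]):
                    e2[pen_sorted_idx[t]] -= diff
                u2[l] = newu
                ss2 += newu * newu
            sp1 = _sample_scaled_inv_chi2(nu_p + npen, nu_p * s2_p1 + ss1)
            sp2 = _sample_scaled_inv_chi2(nu_p + npen, nu_p * s2_p2 + ss2)

        # markers with a shared inclusion indicator
        for j in range(m):
            if zz[j] <= 0.0:
                continue
            o1 = a1[j]
            o2 = a2[j]
            if delta[j] == 1:
                for i in range(n):
                    e1[i] += Z[i, j] * o1
                    e2[i] += Z[i, j] * o2
                s2j1[j] = _sample_scaled_inv_chi2(nu_a + 1.0, nu_a * s2_a1 + o1 * o1)
                s2j2[j] = _sample_scaled_inv_chi2(nu_a + 1.0, nu_a * s2_a2 + o2 * o2)
            else:
                s2j1[j] = _sample_scaled_inv_chi2(nu_a, nu_a * s2_a1)
                s2j2[j] = _sample_scaled_inv_chi2(nu_a, nu_a * s2_a2)

            z1 = 0.0
            z2 = 0.0
            for i in range(n):
                z1 += Z[i, j] * e1[i]
                z2 += Z[i, j] * e2[i]
            rhs1 = w11 * z1 + w12 * z2
            rhs2 = w12 * z1 + w22 * z2
            A11 = zz[j] * w11 + 1.0 / s2j1[j]
            A12 = zz[j] * w12
            A22 = zz[j] * w22 + 1.0 / s2j2[j]
            Ai11, Ai12, Ai22, detA = _inv2(A11, A12, A22)
            quad = (
                rhs1 * rhs1 * Ai11
                + 2.0 * rhs1 * rhs2 * Ai12
                + rhs2 * rhs2 * Ai22
            )
            logodds = (
                0.5 * quad
                - 0.5 * np.log(detA)
                - 0.5 * np.log(s2j1[j] * s2j2[j])
                + log_prior_odds
            )
            if np.log(np.random.random()) < _log_sigmoid(logodds):
                m1 = Ai11 * rhs1 + Ai12 * rhs2
                m2 = Ai12 * rhs1 + Ai22 * rhs2
                # sample from N(mean, A^{-1})
                l11 = np.sqrt(Ai11)
                l21 = Ai12 / l11
                l22 = np.sqrt(max(Ai22 - l21 * l21, 1e-300))
                g1 = np.random.normal()
                g2 = np.random.normal()
                na1 = m1 + l11 * g1
                na2 = m2 + l21 * g1 + l22 * g2
                for i in range(n):
                    e1[i] -= Z[i, j] * na1
                    e2[i] -= Z[i, j] * na2
                a1[j] = na1
                a2[j] = na2
                delta[j] = 1
            else:
                a1[j] = 0.0
                a2[j] = 0.0
                delta[j] = 0

        # residual covariance
        s11 = 0.0
        s12 = 0.0
        s22 = 0.0
        for i in range(n):
            s11 += e1[i] * e1[i]
            s12 += e1[i] * e2[i]
            s22 += e2[i] * e2[i]
        R11, R12, R22 = _sample_invwishart2(
            nu_r + n, S_r11 * nu_r + s11, s12, S_r22 * nu_r + s22
        )
        if not (np.isfinite(R11) and np.isfinite(R22)):
            raise FloatingPointError("residual covariance diverged")

        if it >= burn:
            n_post += 1
            for j in range(m):
                if delta[j] == 1:
                    pip_counts[j] += 1.0
            k = it - burn
            if k % thin == 0 and k // thin < n_save:
                t = k // thin
                for j in range(m):
                    samples1[t, j] = a1[j]
                    samples2[t, j] = a2[j]
                R_trace[t, 0] = R11
                R_trace[t, 1] = R12
                R_trace[t, 2] = R22

    pip = pip_counts / max(n_post, 1)
    return samples1, samples2, pip, beta1, beta2, R_trace
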