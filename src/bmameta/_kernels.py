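"""Numba-compiled log-posterior and random-walk Metropolis kernels.

The kernels operate on an unconstrained parameter vector laid out as
``[mu, log tau, stick-breaking coords of eta (J-1), log b]`` with absent
components skipped.  They are cross-checked against the reference
implementation in :mod:`bmameta.likelihoods` by the test suite.

Model encoding passed to every kernel:

- ``y, se``: study estimates and standard errors (direction-aligned).
- ``mu_fam/tau_fam/b_fam`` with two parameters each: analysis-scale
  prior family codes from :mod:`bmameta.model_space`.
- ``bias``: 0 none, 1 selection, 2 PET, 3 PEESE.
- ``thr``: (n_cutoffs, K) y-space interval boundaries (selection only).
- ``j_obs``: observed 0-based p-interval per study (selection only).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

BIAS_NONE = 0
BIAS_SELECTION = 1
BIAS_PET = 2
BIAS_PEESE = 3

_LOG_2PI = math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + math.log(var) + (x - mean) ** 2 / var)


@njit(cache=True)
def _norm_sf(x):
    return 0.5 * math.erfc(x / _SQRT2)


@njit(cache=True)
def _prior_logpdf(fam, p1, p2, x):
    # family codes: 1 normal, 2 normal-on-d via d=2 sinh(z), 3 inv-gamma,
    # 4 half-cauchy; point (0) contributes nothing here.
    if fam == 1:
        return _norm_logpdf(x, p1, p2 * p2)
    if fam == 2:
        d = 2.0 * math.sinh(x)
        return _norm_logpdf(d, p1, p2 * p2) + math.log(2.0 * math.cosh(x))
    if fam == 3:
        if x <= 0.0:
            return -np.inf
        return p1 * math.log(p2) - math.lgamma(p1) - (p1 + 1.0) * math.log(x) - p2 / x
    if fam == 4:
        if x < 0.0:
            return -np.inf
        return math.log(2.0) - math.log(math.pi * p1 * (1.0 + (x / p1) ** 2))
    return 0.0


@njit(cache=True)
def _logpost(x, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1, tau_p2,
             bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs):
    """Unnormalized log posterior on the unconstrained scale."""
    K = y.shape[0]
    idx = 0
    lp = 0.0

    if mu_fam == 0:
        mu = mu_p1
    else:
        mu = x[idx]
        lp += _prior_logpdf(mu_fam, mu_p1, mu_p2, mu)
        idx += 1

    if tau_fam == 0:
        tau = tau_p1
    else:
        ltau = x[idx]
        tau = math.exp(ltau)
        lp += _prior_logpdf(tau_fam, tau_p1, tau_p2, tau) + ltau
        idx += 1

    J = thr.shape[0] + 1
    omega = np.empty(J)
    if bias == BIAS_SELECTION:
        # stick-breaking: eta_i = v_i * remaining, Dirichlet(1,...,1) prior
        eta = np.empty(J)
        rem = 1.0
        for i in range(J - 1):
            v = 1.0 / (1.0 + math.exp(-x[idx]))
            eta[i] = v * rem
            lp += math.log(rem) + math.log(v) + math.log(1.0 - v)
            rem *= 1.0 - v
            idx += 1
        eta[J - 1] = rem
        lp += math.lgamma(J)
        acc = 0.0
        for j in range(J - 1, -1, -1):
            acc += eta[j]
            omega[j] = acc
        omega[0] = 1.0

    b = 0.0
    if bias == BIAS_PET or bias == BIAS_PEESE:
        if b_fam == 0:
            b = b_p1
        else:
            lb = x[idx]
            b = math.exp(lb)
            lp += _prior_logpdf(b_fam, b_p1, b_p2, b) + lb
            idx += 1

    if not np.isfinite(lp):
        return -np.inf

    # likelihood
    for k in range(K):
        var = se[k] * se[k] + tau * tau
        mean = mu
        if bias == BIAS_PET:
            mean = mu + b * se[k]
        elif bias == BIAS_PEESE:
            mean = mu + b * se[k] * se[k]
        lp += _norm_logpdf(y[k], mean, var)
        if bias == BIAS_SELECTION:
            sd = math.sqrt(var)
            denom = 0.0
            prev = 0.0
            for c in range(J - 1):
                if two_sided:
                    tail = _norm_sf((thr[c, k] - mu) / sd) \
                        + 1.0 - _norm_sf((-thr[c, k] - mu) / sd)
                else:
                    tail = _norm_sf((thr[c, k] - mu) / sd)
                pj = tail - prev
                if pj < 0.0:
                    pj = 0.0
                denom += omega[c] * pj
                prev = tail
            last = 1.0 - prev
            if last < 0.0:
                last = 0.0
            denom += omega[J - 1] * last
            w = omega[j_obs[k]]
            if w <= 0.0 or denom <= 0.0:
                return -np.inf
            lp += math.log(w) - math.log(denom)
    return lp


@njit(cache=True)
def logpost_many(X, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1, tau_p2,
                 bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs):
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _logpost(X[i], y, se, mu_fam, mu_p1, mu_p2,
                          tau_fam, tau_p1, tau_p2, bias, b_fam, b_p1, b_p2,
                          two_sided, thr, j_obs)
    return out


@njit(cache=True)
def rwm_chain(x0, n_adapt, n_keep, thin, seed,
              y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1, tau_p2,
              bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs):
    """Adaptive random-walk Metropolis; adaptation is frozen before the
    kept phase so the retained draws target the exact posterior.

    Returns (draws, logposts, acceptance rate of the kept phase).
    """
    np.random.seed(seed)
    D = x0.shape[0]
    x = x0.copy()
    lp = _logpost(x, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1, tau_p2,
                  bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs)
    # fall back to the origin if the initial point is degenerate
    if not np.isfinite(lp):
        x = np.zeros(D)
        lp = _logpost(x, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1, tau_p2,
                      bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs)

    log_scale = math.log(2.38 / math.sqrt(D))
    L = np.eye(D)
    mean = x.copy()
    cov = np.eye(D) * 0.01
    n_seen = 1.0

    for t in range(n_adapt):
        z = np.random.standard_normal(D)
        step = math.exp(log_scale) * (L @ z)
        xp = x + step
        lpp = _logpost(xp, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1,
                       tau_p2, bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs)
        alpha = 0.0
        if np.isfinite(lpp):
            alpha = math.exp(min(0.0, lpp - lp))
        if np.random.random() < alpha:
            x = xp
            lp = lpp
        # Robbins-Monro scale adaptation toward 0.234 acceptance
        log_scale += (alpha - 0.234) * 1.0 / (t + 10.0) ** 0.6
        # running moments for the proposal covariance
        n_seen += 1.0
        delta = x - mean
        mean = mean + delta / n_seen
        cov = cov * (n_seen - 2.0) / (n_seen - 1.0) \
            + np.outer(delta, x - mean) / (n_seen - 1.0)
        if t >= 50 and (t + 1) % 100 == 0:
            c = 0.5 * (cov + cov.T) + np.eye(D) * 1e-6
            ok = True
            for dd in range(D):
                if not np.isfinite(c[dd, dd]):
                    ok = False
            if ok:
                L = np.linalg.cholesky(c)

    draws = np.empty((n_keep, D))
    logposts = np.empty(n_keep)
    n_acc = 0
    scale = math.exp(log_scale)
    for t in range(n_keep * thin):
        z = np.random.standard_normal(D)
        xp = x + scale * (L @ z)
        lpp = _logpost(xp, y, se, mu_fam, mu_p1, mu_p2, tau_fam, tau_p1,
                       tau_p2, bias, b_fam, b_p1, b_p2, two_sided, thr, j_obs)
        if np.isfinite(lpp) and math.log(np.random.random() + 1e-300) < lpp - lp:
            x = xp
            lp = lpp
            n_acc += 1
        if (t + 1) % thin == 0:
            i = (t + 1) // thin - 1
            draws[i] = x
            logposts[i] = lp
    return draws, logposts, n_acc / max(1, n_keep * thin)
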