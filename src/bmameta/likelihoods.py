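"""Log-likelihoods and log prior densities for the four model families.

This is the reference (numpy/scipy) implementation used by the
quadrature oracle and the test suite; the MCMC sampler uses compiled
kernels in :mod:`bmameta._kernels` that are cross-checked against these
functions.

The selection-model likelihood is the per-study-normalized weighted
density: each study contributes

    omega_{j(k)} N(y_k; mu, se_k^2 + tau^2) / sum_j omega_j A_jk,

where j(k) is the p-value interval containing the observed study and
A_jk is the probability that a study with standard error se_k lands in
interval j under the model's marginal distribution N(mu, se_k^2 + tau^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .effect_transforms import Direction, InvalidInputError, StudyData
from .model_space import (AFAM_HALF_CAUCHY, AFAM_INV_GAMMA, AFAM_NORMAL,
                          AFAM_NORMAL_SINH, AFAM_POINT, BiasType, ModelSpec,
                          WeightFunctionSpec, cum_dirichlet_weights)

__all__ = [
    "ParameterVector",
    "loglik_plain",
    "interval_probs",
    "interval_index",
    "loglik_selection",
    "loglik_regression",
    "loglik_model",
    "log_prior",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class ParameterVector:
    """Free parameters of one ensemble member (analysis scale)."""

    mu: float = 0.0
    tau: float = 0.0
    eta: Optional[np.ndarray] = None
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise InvalidInputError("tau must be non-negative")
        if self.eta is not None:
            self.eta = np.asarray(self.eta, dtype=float)

    @property
    def omega(self) -> Optional[np.ndarray]:
        return None if self.eta is None else cum_dirichlet_weights(self.eta)


def _norm_logpdf(y, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (y - mean) ** 2 / var)


def loglik_plain(data: StudyData, mu: float, tau: float = 0.0) -> float:
    """sum_k log N(y_k; mu, se_k^2 + tau^2); tau = 0 is the fixed-effect case."""
    var = data.se ** 2 + tau ** 2
    return float(np.sum(_norm_logpdf(data.y, mu, var)))


def _y_thresholds(wf: WeightFunctionSpec, se, direction: Direction):
    """Interval boundaries in y-space, one row per cutoff (ascending p)."""
    se = np.asarray(se, dtype=float)
    q = norm.isf(np.asarray(wf.cutoffs))            # one-sided quantiles
    if wf.sidedness == "two":
        q = norm.isf(np.asarray(wf.cutoffs) / 2.0)
    return np.multiply.outer(q, se)                  # (n_cutoffs, K)


def interval_probs(mu: float, tau: float, se, wf: WeightFunctionSpec,
                   direction: Direction = Direction.POSITIVE) -> np.ndarray:
    """P(study with this se falls in each p-interval | y ~ N(mu, se^2+tau^2)).

    Returns an array of shape (J,) for scalar se, else (J, K); each
    column sums to 1.
    """
    se = np.asarray(se, dtype=float)
    scalar = se.ndim == 0
    se = np.atleast_1d(se)
    if np.any(se <= 0):
        raise InvalidInputError("se must be positive")
    sd = np.sqrt(se ** 2 + tau ** 2)
    m = -mu if direction == Direction.NEGATIVE else mu
    thr = _y_thresholds(wf, se, direction)           # (C, K)
    J = wf.J
    out = np.empty((J, se.size))
    if wf.sidedness == "one":
        # interval j (1-based): p in (c_{j-1}, c_j]  <=>  y in [thr_j, thr_{j-1})
        upper_tail = norm.sf((thr - m) / sd)         # P(y > thr_c), ascending cutoffs
        prev = np.zeros(se.size)
        for j in range(J - 1):
            out[j] = upper_tail[j] - prev
            prev = upper_tail[j]
        out[J - 1] = 1.0 - prev
    else:
        # two-sided: interval j is |y| between consecutive thresholds
        tail = (norm.sf((thr - m) / sd) + norm.cdf((-thr - m) / sd))  # P(|y| > thr_c)
        prev = np.zeros(se.size)
        for j in range(J - 1):
            out[j] = tail[j] - prev
            prev = tail[j]
        out[J - 1] = 1.0 - prev
    out = np.clip(out, 0.0, 1.0)
    return out[:, 0] if scalar else out


def interval_index(y, se, wf: WeightFunctionSpec,
                   direction: Direction = Direction.POSITIVE) -> np.ndarray:
    """0-based p-interval of each observed study; ties at a cutoff go to
    the more significant interval."""
    from .effect_transforms import p_value
    p = np.atleast_1d(p_value(y, se, wf.sidedness, direction))
    # p <= cutoff -> at or below the boundary counts as more significant
    return np.sum(p[None, :] > np.asarray(wf.cutoffs)[:, None], axis=0)


def loglik_selection(data: StudyData, mu: float, tau: float,
                     omega: np.ndarray, wf: WeightFunctionSpec,
                     direction: Direction = Direction.POSITIVE) -> float:
    omega = np.asarray(omega, dtype=float)
    if omega.size != wf.J:
        raise InvalidInputError("omega length must equal the number of intervals")
    probs = interval_probs(mu, tau, data.se, wf, direction)   # (J, K)
    denom = omega @ probs                                      # (K,)
    j_obs = interval_index(data.y, data.se, wf, direction)
    w_obs = omega[j_obs]
    if np.any(w_obs <= 0.0):
        return -np.inf
    var = data.se ** 2 + tau ** 2
    return float(np.sum(np.log(w_obs) + _norm_logpdf(data.y, mu, var)
                        - np.log(denom)))


def loglik_regression(data: StudyData, mu: float, tau: float, b: float,
                      kind: str) -> float:
    """PET: mean mu + b*se_k; PEESE: mean mu + b*se_k^2."""
    if kind not in ("pet", "peese"):
        raise InvalidInputError(f"kind must be 'pet' or 'peese', got {kind!r}")
    pred = data.se if kind == "pet" else data.se ** 2
    var = data.se ** 2 + tau ** 2
    return float(np.sum(_norm_logpdf(data.y, mu + b * pred, var)))


def loglik_model(spec: ModelSpec, data: StudyData, theta: ParameterVector,
                 direction: Direction = Direction.POSITIVE) -> float:
    """Dispatch to the model family's log-likelihood."""
    if spec.bias_type is BiasType.SELECTION:
        return loglik_selection(data, theta.mu, theta.tau, theta.omega,
                                spec.weight_fn, direction)
    if spec.bias_type in (BiasType.PET, BiasType.PEESE):
        return loglik_regression(data, theta.mu, theta.tau, theta.b,
                                 spec.bias_type.value)
    return loglik_plain(data, theta.mu, theta.tau)


def _component_logpdf(afam: int, p1: float, p2: float, x: float) -> float:
    if afam == AFAM_POINT:
        return 0.0
    if afam == AFAM_NORMAL:
        return float(_norm_logpdf(x, p1, p2 * p2))
    if afam == AFAM_NORMAL_SINH:
        # prior declared on d, evaluated on z: d = 2 sinh(z), dd/dz = 2 cosh(z)
        d = 2.0 * math.sinh(x)
        return float(_norm_logpdf(d, p1, p2 * p2)) + math.log(2.0 * math.cosh(x))
    if afam == AFAM_INV_GAMMA:
        if x <= 0:
            return -np.inf
        a, b = p1, p2
        return a * math.log(b) - math.lgamma(a) - (a + 1.0) * math.log(x) - b / x
    if afam == AFAM_HALF_CAUCHY:
        if x < 0:
            return -np.inf
        s = p1
        return math.log(2.0) - math.log(math.pi * s * (1.0 + (x / s) ** 2))
    raise InvalidInputError(f"unknown analysis family code {afam}")


def log_prior(theta: ParameterVector, spec: ModelSpec) -> float:
    """Joint log prior density of the free parameters on the analysis scale.

    Point-mass components contribute 0 when theta matches the point and
    -inf otherwise.  The Dirichlet(1, ..., 1) prior on eta contributes
    log Gamma(J) on the simplex.
    """
    total = 0.0
    for role, prior, value in (("mu", spec.effect, theta.mu),
                               ("tau", spec.heterogeneity, theta.tau)):
        afam, p1, p2 = prior.analysis_form(role)
        if afam == AFAM_POINT:
            if abs(value - p1) > 1e-12:
                return -np.inf
            continue
        total += _component_logpdf(afam, p1, p2, value)
    if spec.bias_type is BiasType.SELECTION:
        eta = theta.eta
        if eta is None or eta.size != spec.weight_fn.J:
            raise InvalidInputError("eta must match the weight function's J")
        if np.any(eta < 0) or abs(eta.sum() - 1.0) > 1e-8:
            return -np.inf
        total += math.lgamma(spec.weight_fn.J)      # Dirichlet(1,...,1) density
    elif spec.bias_type in (BiasType.PET, BiasType.PEESE):
        afam, p1, p2 = spec.slope_prior.analysis_form(spec.bias_type.value)
        if afam == AFAM_POINT:
            if abs(theta.b - p1) > 1e-12:
                return -np.inf
        else:
            lp = _component_logpdf(afam, p1, p2, theta.b)
            if not np.isfinite(lp):
                return -np.inf
            total += lp
    return float(total)
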