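"""Frequentist baselines: conditional PET-PEESE and DerSimonian-Laird."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effect_transforms import InvalidInputError, StudyData

__all__ = [
    "RegressionFit",
    "PetPeeseResult",
    "pet_peese_conditional",
    "dersimonian_laird",
    "InsufficientStudiesError",
    "CollinearityError",
]


class InsufficientStudiesError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionFit:
    """Weighted least-squares fit of effect size on a precision regressor."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    df: int
    p_intercept: float

    def summary(self) -> dict:
        return {
            "intercept": self.intercept, "slope": self.slope,
            "se_intercept": self.se_intercept, "se_slope": self.se_slope,
            "t_intercept": self.t_intercept, "df": self.df,
            "p_intercept": self.p_intercept,
        }


@dataclass(frozen=True)
class PetPeeseResult:
    pet: RegressionFit
    peese: RegressionFit
    chosen: str                 # "pet" or "peese"
    estimate: float
    alpha: float


def _wls(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> RegressionFit:
    K = y.size
    X = np.column_stack([np.ones(K), x])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    if abs(np.linalg.det(XtWX)) < 1e-12 * np.trace(XtWX) ** 2:
        raise CollinearityError("regressor is collinear with the intercept "
                                "(all standard errors equal?)")
    beta = np.linalg.solve(XtWX, WX.T @ y)
    resid = y - X @ beta
    df = K - 2
    sigma2 = float(resid @ (w * resid)) / df
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    t0 = beta[0] / se[0]
    p0 = 2.0 * stats.t.sf(abs(t0), df)
    return RegressionFit(intercept=float(beta[0]), slope=float(beta[1]),
                         se_intercept=float(se[0]), se_slope=float(se[1]),
                         t_intercept=float(t0), df=df, p_intercept=float(p0))


def pet_peese_conditional(data: StudyData, alpha: float = 0.10,
                          one_sided_test: bool = False) -> PetPeeseResult:
    """Conditional PET-PEESE estimator.

    Fits WLS (weights 1/se^2) of effect on standard error (PET) and on
    variance (PEESE).  If the PET intercept test rejects at ``alpha``
    (two-sided by default), the PEESE intercept is reported, otherwise
    the PET intercept.
    """
    if data.K < 3:
        raise InsufficientStudiesError("conditional PET-PEESE needs K >= 3")
    w = 1.0 / data.se ** 2
    pet = _wls(data.y, data.se, w)
    peese = _wls(data.y, data.se ** 2, w)
    p = stats.t.sf(pet.t_intercept, pet.df) if one_sided_test else pet.p_intercept
    chosen = "peese" if p < alpha else "pet"
    estimate = peese.intercept if chosen == "peese" else pet.intercept
    return PetPeeseResult(pet=pet, peese=peese, chosen=chosen,
                          estimate=estimate, alpha=alpha)


def dersimonian_laird(data: StudyData):
    """DerSimonian-Laird random-effects estimate.

    Returns (mu_hat, tau2_hat, se_mu_hat) with the method-of-moments
    tau^2 truncated at zero.
    """
    if data.K < 2:
        raise InsufficientStudiesError("DerSimonian-Laird needs K >= 2")
    w = 1.0 / data.se ** 2
    mu_fe = float(np.sum(w * data.y) / np.sum(w))
    Q = float(np.sum(w * (data.y - mu_fe) ** 2))
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (Q - (data.K - 1)) / c) if c > 0 else 0.0
    w_re = 1.0 / (data.se ** 2 + tau2)
    mu_hat = float(np.sum(w_re * data.y) / np.sum(w_re))
    se_mu = math.sqrt(1.0 / float(np.sum(w_re)))
    return mu_hat, tau2, se_mu
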