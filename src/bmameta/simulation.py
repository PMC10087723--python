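"""Synthetic meta-analysis generation with p-value selection, plus the
evaluation metrics used to compare adjustment methods."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .effect_transforms import Direction, InvalidInputError, StudyData, p_value
from .model_space import WeightFunctionSpec

__all__ = [
    "SimulationConfig",
    "MethodEvaluation",
    "simulate_meta_analysis",
    "evaluate_method",
    "SelectionStallError",
]


class SelectionStallError(RuntimeError):
    """Raised when the selection process cannot accept any study."""


@dataclass
class SimulationConfig:
    """Data-generating process for one synthetic meta-analysis.

    Study estimates are drawn as y_k ~ N(theta_k + slope * se_k, se_k^2)
    with theta_k ~ N(true_mu, true_tau^2) on the Cohen's d scale; the
    per-study standard error follows the equal-group-size formula
    se^2 = (8 + d^2) / (2 n) at d = true_mu.  Each candidate study is
    accepted with the publication probability of its p-value interval.
    """

    true_mu: float = 0.0
    true_tau: float = 0.0
    K: int = 20
    n_range: Tuple[int, int] = (30, 300)
    n_list: Optional[Sequence[int]] = None
    selection: Optional[WeightFunctionSpec] = None
    omega: Optional[Sequence[float]] = None
    small_study_slope: float = 0.0
    direction: Direction = Direction.POSITIVE
    seed: int = 0
    max_attempts_per_study: int = 100_000

    def __post_init__(self) -> None:
        if self.K < 1:
            raise InvalidInputError("K must be at least 1")
        if (self.selection is None) != (self.omega is None):
            raise InvalidInputError("selection and omega must be given together")
        if self.omega is not None:
            om = np.asarray(self.omega, dtype=float)
            if om.size != self.selection.J:
                raise InvalidInputError("omega length must equal J")
            if np.any((om < 0) | (om > 1)):
                raise InvalidInputError("omega entries must lie in [0, 1]")
            if not np.any(om > 0):
                raise SelectionStallError("all publication probabilities are 0")


def _draw_n(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.n_list is not None:
        return int(rng.choice(np.asarray(config.n_list)))
    lo, hi = config.n_range
    return int(rng.integers(lo, hi + 1))


def simulate_meta_analysis(config: SimulationConfig) -> StudyData:
    """Generate K accepted studies under the configured selection process."""
    rng = np.random.Generator(np.random.PCG64(config.seed))
    y_out = np.empty(config.K)
    se_out = np.empty(config.K)
    n_out = np.empty(config.K)
    om = None if config.omega is None else np.asarray(config.omega, dtype=float)
    for k in range(config.K):
        for _ in range(config.max_attempts_per_study):
            n = _draw_n(config, rng)
            theta = config.true_mu + config.true_tau * rng.standard_normal()
            se = math.sqrt((8.0 + config.true_mu ** 2) / (2.0 * n))
            y = theta + config.small_study_slope * se + se * rng.standard_normal()
            if om is None:
                break
            p = float(p_value(y, se, config.selection.sidedness, config.direction))
            j = int(np.sum(p > np.asarray(config.selection.cutoffs)))
            if rng.random() < om[j]:
                break
        else:
            raise SelectionStallError(
                f"no study accepted after {config.max_attempts_per_study} attempts")
        y_out[k], se_out[k], n_out[k] = y, se, n
    return StudyData(y=y_out, se=se_out, n=n_out)


@dataclass
class MethodEvaluation:
    fpr: float
    fnr: float
    undecided_under_null: float
    undecided_under_effect: float
    of: float
    bias: float
    rmse: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("fpr", "fnr", "undecided_under_null", "undecided_under_effect",
                 "of", "bias", "rmse")}


def evaluate_method(estimates: Sequence[float], decisions: Sequence[str],
                    reference_estimates: Sequence[float],
                    reference_significant: Sequence[bool]) -> MethodEvaluation:
    """Method-vs-reference comparison metrics.

    ``decisions`` are evidence labels per case ("evidence_presence",
    "evidence_absence", "undecided" for Bayes-factor methods, or
    "significant"/"not_significant" for frequentist ones).  FPR is the
    share of reference-non-significant cases where the method claims an
    effect; FNR the share of reference-significant cases where it claims
    absence or fails to support the effect; OF is the ratio of mean
    estimates; bias and RMSE are over the estimate differences.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference_estimates, dtype=float)
    dec = list(decisions)
    sig = np.asarray(reference_significant, dtype=bool)
    if not (est.size == ref.size == len(dec) == sig.size):
        raise InvalidInputError("evaluation vectors must have equal length")

    claims_effect = np.array([d in ("evidence_presence", "significant")
                              for d in dec])
    claims_absence = np.array([d in ("evidence_absence", "not_significant")
                               for d in dec])
    undecided = np.array([d == "undecided" for d in dec])

    n_null = int((~sig).sum())
    n_eff = int(sig.sum())
    fpr = float(claims_effect[~sig].sum() / n_null) if n_null else math.nan
    fnr = float(claims_absence[sig].sum() / n_eff) if n_eff else math.nan
    und_null = float(undecided[~sig].sum() / n_null) if n_null else math.nan
    und_eff = float(undecided[sig].sum() / n_eff) if n_eff else math.nan
    of = float(est.mean() / ref.mean()) if abs(ref.mean()) > 1e-300 else math.nan
    bias = float(np.mean(est - ref))
    rmse = float(math.sqrt(np.mean((est - ref) ** 2)))
    return MethodEvaluation(fpr=fpr, fnr=fnr, undecided_under_null=und_null,
                            undecided_under_effect=und_eff, of=of, bias=bias,
                            rmse=rmse)
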