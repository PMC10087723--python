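"""Posterior model probabilities, inclusion Bayes factors, and
model-averaged (spike-and-slab) posterior summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .effect_transforms import InvalidInputError, z_point_to_d
from .inference import FittedModel
from .model_space import BiasType, Ensemble

__all__ = [
    "posterior_model_probs",
    "inclusion_bf",
    "MixturePosterior",
    "model_averaged_posterior",
    "summarize",
    "evidence_category",
    "EnsembleResult",
    "aggregate",
    "DegenerateEnsembleError",
]


class DegenerateEnsembleError(ValueError):
    pass


def posterior_model_probs(log_margliks: Sequence[float],
                          prior_probs: Sequence[float]) -> np.ndarray:
    """p_i proportional to prior_i * exp(log_marglik_i), via log-sum-exp."""
    lm = np.asarray(log_margliks, dtype=float)
    pp = np.asarray(prior_probs, dtype=float)
    if lm.shape != pp.shape:
        raise InvalidInputError("log_margliks and prior_probs must align")
    if abs(pp.sum() - 1.0) > 1e-8:
        raise InvalidInputError("prior probabilities must sum to 1")
    with np.errstate(divide="ignore"):
        logw = np.where(pp > 0, np.log(np.maximum(pp, 1e-300)) + lm, -np.inf)
    if not np.any(np.isfinite(logw)):
        raise DegenerateEnsembleError("all posterior model weights are zero")
    logw = logw - np.max(logw[np.isfinite(logw)])
    w = np.exp(logw)
    return w / w.sum()


def inclusion_bf(prior_probs: Sequence[float], posterior_probs: Sequence[float],
                 subset: Sequence[int]) -> float:
    """Change from prior to posterior odds for a set of models vs the rest."""
    pp = np.asarray(prior_probs, dtype=float)
    qq = np.asarray(posterior_probs, dtype=float)
    subset = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
    if subset.size == 0 or subset.size >= pp.size:
        raise InvalidInputError("subset must be a non-empty proper subset")
    mask = np.zeros(pp.size, dtype=bool)
    mask[subset] = True
    prior_odds = pp[mask].sum() / pp[~mask].sum()
    post_odds = qq[mask].sum() / max(qq[~mask].sum(), 1e-300)
    return float(post_odds / prior_odds)


@dataclass
class MixturePosterior:
    """Spike-and-slab mixture over pooled per-model draws.

    ``components`` holds (weight, draws) pairs; a point mass is a
    length-1 array flagged in ``spike_weight`` instead.  Supports mean
    and quantile queries over the full mixture including the spike.
    """

    spike_weight: float
    spike_value: float
    components: List[Tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def slab_weight(self) -> float:
        return sum(w for w, _ in self.components)

    def mean(self) -> float:
        m = self.spike_weight * self.spike_value
        for w, draws in self.components:
            m += w * float(np.mean(draws))
        return m

    def quantile(self, q) -> np.ndarray:
        """Weighted quantiles of the pooled mixture (spike included)."""
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        values = [np.array([self.spike_value])]
        weights = [np.array([self.spike_weight])]
        for w, draws in self.components:
            values.append(draws)
            weights.append(np.full(draws.size, w / draws.size))
        v = np.concatenate(values)
        w = np.concatenate(weights)
        order = np.argsort(v, kind="stable")
        v, w = v[order], w[order]
        cw = np.cumsum(w)
        cw /= cw[-1]
        idx = np.searchsorted(cw, qs, side="left")
        idx = np.clip(idx, 0, v.size - 1)
        return v[idx] if qs.ndim else float(v[idx])

    def ci(self, level: float = 0.95) -> Tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = self.quantile([a, 1.0 - a])
        return float(lo), float(hi)

    def transformed(self, fn) -> "MixturePosterior":
        return MixturePosterior(
            spike_weight=self.spike_weight,
            spike_value=float(fn(np.array([self.spike_value]))[0]),
            components=[(w, np.asarray(fn(d))) for w, d in self.components])


def model_averaged_posterior(fitted: Sequence[FittedModel],
                             posterior_probs: Sequence[float],
                             parameter: str = "mu") -> MixturePosterior:
    """Mixture of per-model posteriors weighted by posterior model probability.

    Models whose prior fixes the parameter at zero contribute to the
    spike; the rest contribute their pooled draws.
    """
    probs = np.asarray(posterior_probs, dtype=float)
    if len(fitted) != probs.size:
        raise InvalidInputError("posterior_probs must align with fitted models")
    spike = 0.0
    components: List[Tuple[float, np.ndarray]] = []
    for fm, p in zip(fitted, probs):
        if parameter == "mu":
            free = fm.spec.has_effect
            draws = fm.mu_draws() if free else None
        elif parameter == "tau":
            free = fm.spec.has_heterogeneity
            draws = fm.tau_draws() if free else None
        else:
            raise InvalidInputError(f"unknown parameter {parameter!r}")
        if not free:
            spike += p
        elif p > 0:
            components.append((float(p), draws))
    return MixturePosterior(spike_weight=float(spike), spike_value=0.0,
                            components=components)


def summarize(mixture: MixturePosterior, level: float = 0.95) -> Dict[str, float]:
    lo, hi = mixture.ci(level)
    return {"mean": mixture.mean(), "ci_lower": lo, "ci_upper": hi}


def evidence_category(bf: float, lower: float = 1.0 / 10.0,
                      upper: float = 10.0) -> str:
    """Trichotomous evidence label with inclusive boundaries."""
    if not bf > 0:
        raise InvalidInputError("Bayes factor must be positive")
    if bf <= lower:
        return "evidence_absence"
    if bf >= upper:
        return "evidence_presence"
    return "undecided"


@dataclass
class EnsembleResult:
    posterior_probs: np.ndarray
    prior_probs: np.ndarray
    bf_effect: float
    bf_heterogeneity: float
    bf_bias: float
    bf_selection_vs_petpeese: Optional[float]
    per_model_bf: np.ndarray
    mu_analysis: Dict[str, float]
    mu_d: Dict[str, float]
    tau_analysis: Dict[str, float]
    tau_d: Dict[str, float]
    mu_mixture: MixturePosterior
    tau_mixture: MixturePosterior
    excluded_models: List[int] = field(default_factory=list)

    @property
    def bf_effect_category(self) -> str:
        return evidence_category(self.bf_effect)


def _renormalized_priors(ensemble: Ensemble, usable: np.ndarray) -> np.ndarray:
    pp = ensemble.prior_probs.copy()
    pp[~usable] = 0.0
    total = pp.sum()
    if total <= 0:
        raise DegenerateEnsembleError("no converged models in the ensemble")
    return pp / total


def aggregate(ensemble: Ensemble, fitted: Sequence[FittedModel],
              back_transform: bool = True,
              direction_flip: bool = False) -> EnsembleResult:
    """Combine fitted models into the full ensemble-level result.

    Unconverged models are excluded with prior mass renormalized over
    the remainder.  ``back_transform`` applies the z -> d map to the
    effect summaries (the analysis-scale summaries are always kept);
    ``direction_flip`` undoes a negative-direction sign flip applied at
    fit time.
    """
    usable = np.array([fm.converged and np.isfinite(fm.log_marglik)
                       for fm in fitted])
    excluded = [fm.spec.id for fm, u in zip(fitted, usable) if not u]
    pp = _renormalized_priors(ensemble, usable)
    lm = np.array([fm.log_marglik if u else -np.inf
                   for fm, u in zip(fitted, usable)])
    post = posterior_model_probs(np.where(np.isfinite(lm), lm, -1e308), pp)

    def _bf(subset):
        subset = [i for i in subset if usable[i]]
        if not subset or len(subset) >= int(usable.sum()):
            return math.nan
        return inclusion_bf(pp, post, subset)

    bf_effect = _bf(ensemble.indices(effect=True))
    bf_heterogeneity = _bf(ensemble.indices(heterogeneity=True))
    bias_idx = ensemble.indices(bias_types=[BiasType.SELECTION, BiasType.PET,
                                            BiasType.PEESE])
    bf_bias = _bf(bias_idx)

    sel_idx = [i for i in ensemble.indices(bias_types=[BiasType.SELECTION])
               if usable[i]]
    reg_idx = [i for i in ensemble.indices(bias_types=[BiasType.PET, BiasType.PEESE])
               if usable[i]]
    bf_sel_vs_reg = None
    if sel_idx and reg_idx:
        # restricted comparison within the bias-adjusted classes
        pp_r = np.zeros_like(pp)
        pp_r[sel_idx] = pp[sel_idx]
        pp_r[reg_idx] = pp[reg_idx]
        pp_r /= pp_r.sum()
        post_r = np.zeros_like(post)
        post_r[sel_idx] = post[sel_idx]
        post_r[reg_idx] = post[reg_idx]
        post_r /= post_r.sum()
        bf_sel_vs_reg = inclusion_bf(pp_r, post_r, sel_idx)

    per_model_bf = np.full(len(ensemble), math.nan)
    for i in range(len(ensemble)):
        if usable[i]:
            per_model_bf[i] = inclusion_bf(pp, post, [i])

    mu_mix = model_averaged_posterior(fitted, post, "mu")
    tau_mix = model_averaged_posterior(fitted, post, "tau")
    if direction_flip:
        mu_mix = mu_mix.transformed(lambda x: -x)
    mu_summary = summarize(mu_mix)
    tau_summary = summarize(tau_mix)
    if back_transform:
        mu_d = summarize(mu_mix.transformed(z_point_to_d))
        tau_d = summarize(tau_mix.transformed(lambda x: 2.0 * x))
    else:
        mu_d, tau_d = dict(mu_summary), dict(tau_summary)

    return EnsembleResult(
        posterior_probs=post, prior_probs=pp,
        bf_effect=bf_effect, bf_heterogeneity=bf_heterogeneity,
        bf_bias=bf_bias, bf_selection_vs_petpeese=bf_sel_vs_reg,
        per_model_bf=per_model_bf,
        mu_analysis=mu_summary, mu_d=mu_d,
        tau_analysis=tau_summary, tau_d=tau_d,
        mu_mixture=mu_mix, tau_mixture=tau_mix,
        excluded_models=excluded)


def averaged_weight_function(ensemble: Ensemble, fitted: Sequence[FittedModel],
                             posterior_probs: Sequence[float],
                             p_grid: Optional[np.ndarray] = None) -> Dict[str, np.ndarray]:
    """Model-averaged publication weight omega evaluated on a p-value grid.

    Models without a selection component (no-bias, PET, PEESE) count as
    omega identically 1.
    """
    if p_grid is None:
        p_grid = np.linspace(1e-4, 1.0 - 1e-4, 200)
    probs = np.asarray(posterior_probs, dtype=float)
    mean = np.zeros_like(p_grid)
    lo = np.zeros_like(p_grid)
    hi = np.zeros_like(p_grid)
    # build pooled omega(p) draws per grid point
    for gi, p in enumerate(p_grid):
        vals, wts = [np.array([1.0])], []
        w_flat = 0.0
        for fm, pr in zip(fitted, probs):
            if fm.spec.bias_type is not BiasType.SELECTION:
                w_flat += pr
                continue
            wf = fm.spec.weight_fn
            j = int(np.sum(p > np.asarray(wf.cutoffs)))
            om = fm.draws["omega"].reshape(-1, wf.J)[:, j]
            vals.append(om)
            wts.append(np.full(om.size, pr / om.size))
        wts.insert(0, np.array([w_flat]))
        v = np.concatenate(vals)
        w = np.concatenate(wts)
        order = np.argsort(v)
        v, w = v[order], w[order]
        cw = np.cumsum(w) / w.sum()
        mean[gi] = float(np.sum(v * w) / w.sum())
        lo[gi] = v[np.searchsorted(cw, 0.025, side="left").clip(0, v.size - 1)]
        hi[gi] = v[np.searchsorted(cw, 0.975, side="left").clip(0, v.size - 1)]
    return {"p": p_grid, "mean": mean, "ci_lower": lo, "ci_upper": hi}
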