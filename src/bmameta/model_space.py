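"""Priors, weight functions, and construction of the default model ensemble.

The default ensemble crosses {effect null, effect slab} x {tau = 0,
tau slab} x {no bias, 6 step weight functions, PET, PEESE} = 36 models.
Half of the prior model probability goes to the four models assuming no
publication bias; the remaining half is divided equally between the
selection-model class and the regression (PET/PEESE) class, uniformly
within each class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .effect_transforms import InvalidInputError, Scale

__all__ = [
    "PriorFamily",
    "PriorSpec",
    "WeightFunctionSpec",
    "BiasType",
    "ModelSpec",
    "Ensemble",
    "default_weight_functions",
    "default_priors",
    "build_ensemble",
    "cum_dirichlet_weights",
]


class PriorFamily(str, Enum):
    POINT = "point"
    NORMAL = "normal"
    INV_GAMMA = "inv_gamma"
    CAUCHY_POS = "cauchy_truncated_positive"
    DIRICHLET = "dirichlet"


class BiasType(str, Enum):
    NONE = "none"
    SELECTION = "selection"
    PET = "pet"
    PEESE = "peese"


# analysis-scale family codes shared with the compiled likelihood kernels
AFAM_POINT = 0
AFAM_NORMAL = 1
AFAM_NORMAL_SINH = 2   # normal declared on d, fitted on z: d = 2 sinh(z)
AFAM_INV_GAMMA = 3
AFAM_HALF_CAUCHY = 4


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior with the scale it was declared on.

    params by family: point -> (value,), normal -> (mean, sd),
    inv_gamma -> (shape, scale), cauchy_truncated_positive -> (scale,).
    """

    family: PriorFamily
    params: Tuple[float, ...]
    declared_scale: Scale = Scale.COHENS_D

    def __post_init__(self) -> None:
        p = self.params
        if self.family is PriorFamily.NORMAL and not p[1] > 0:
            raise InvalidInputError("normal prior sd must be positive")
        if self.family is PriorFamily.INV_GAMMA and not (p[0] > 0 and p[1] > 0):
            raise InvalidInputError("inverse-gamma shape and scale must be positive")
        if self.family is PriorFamily.CAUCHY_POS and not p[0] > 0:
            raise InvalidInputError("cauchy scale must be positive")
        if self.family is PriorFamily.POINT and not math.isfinite(p[0]):
            raise InvalidInputError("point mass must be finite")

    @property
    def is_point(self) -> bool:
        return self.family is PriorFamily.POINT

    def analysis_form(self, role: str) -> Tuple[int, float, float]:
        """(family code, p1, p2) of this prior expressed on the analysis scale.

        Priors declared on the Cohen's d scale are mapped to the Fisher's z
        scale: the effect prior by exact change of variables through
        d = 2 sinh(z); the heterogeneity scale by the Jacobian at zero
        (dz/dd|_0 = 1/2); the PET slope is a ratio of like-scaled
        quantities and is unchanged; the PEESE slope scale doubles.
        """
        on_d = self.declared_scale is Scale.COHENS_D
        if self.family is PriorFamily.POINT:
            v = self.params[0]
            if on_d:
                if role == "mu":
                    v = math.asinh(v / 2.0)
                elif role == "tau":
                    v = v / 2.0
                elif role == "peese":
                    v = v * 2.0
            return (AFAM_POINT, v, 0.0)
        if self.family is PriorFamily.NORMAL:
            m, s = self.params
            if on_d and role == "mu":
                return (AFAM_NORMAL_SINH, m, s)
            return (AFAM_NORMAL, m, s)
        if self.family is PriorFamily.INV_GAMMA:
            a, b = self.params
            if on_d and role == "tau":
                b = b / 2.0
            return (AFAM_INV_GAMMA, a, b)
        if self.family is PriorFamily.CAUCHY_POS:
            s = self.params[0]
            if on_d and role == "peese":
                s = s * 2.0
            return (AFAM_HALF_CAUCHY, s, 0.0)
        raise InvalidInputError(f"no analysis form for family {self.family}")

    def describe(self) -> str:
        p = self.params
        if self.family is PriorFamily.POINT:
            return f"point({p[0]:g})"
        if self.family is PriorFamily.NORMAL:
            return f"Normal({p[0]:g}, {p[1]:g})"
        if self.family is PriorFamily.INV_GAMMA:
            return f"InvGamma({p[0]:g}, {p[1]:g})"
        if self.family is PriorFamily.CAUCHY_POS:
            return f"Cauchy({p[0]:g})[0, inf)"
        return self.family.value


@dataclass(frozen=True)
class WeightFunctionSpec:
    """Step weight function over p-value intervals.

    ``cutoffs`` are strictly increasing p-value cutoffs in (0, 1); the
    function has J = len(cutoffs) + 1 intervals ordered from the most
    significant (smallest p-values) to the least.
    """

    sidedness: str
    cutoffs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.sidedness not in ("one", "two"):
            raise InvalidInputError(f"sidedness must be 'one' or 'two', got {self.sidedness!r}")
        c = tuple(float(x) for x in self.cutoffs)
        if len(c) < 1 or any(not (0.0 < x < 1.0) for x in c):
            raise InvalidInputError("cutoffs must lie in (0, 1)")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise InvalidInputError("cutoffs must be strictly increasing")
        object.__setattr__(self, "cutoffs", c)

    @property
    def J(self) -> int:
        return len(self.cutoffs) + 1

    def describe(self) -> str:
        cuts = ", ".join(f"{c:g}" for c in self.cutoffs)
        return f"{self.sidedness}-sided({cuts})"


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model ensemble."""

    id: int
    effect: PriorSpec
    heterogeneity: PriorSpec
    bias_type: BiasType
    weight_fn: Optional[WeightFunctionSpec] = None
    slope_prior: Optional[PriorSpec] = None
    prior_prob: float = 0.0
    prior_prob_exact: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        if self.bias_type is BiasType.SELECTION and self.weight_fn is None:
            raise InvalidInputError("selection model requires a weight function")
        if self.bias_type in (BiasType.PET, BiasType.PEESE) and self.slope_prior is None:
            raise InvalidInputError("regression model requires a slope prior")
        if self.prior_prob < 0:
            raise InvalidInputError("prior probability must be non-negative")

    @property
    def has_effect(self) -> bool:
        return not self.effect.is_point

    @property
    def has_heterogeneity(self) -> bool:
        return not self.heterogeneity.is_point

    @property
    def n_free(self) -> int:
        n = int(self.has_effect) + int(self.has_heterogeneity)
        if self.bias_type is BiasType.SELECTION:
            n += self.weight_fn.J - 1
        elif self.bias_type in (BiasType.PET, BiasType.PEESE):
            n += int(not self.slope_prior.is_point)
        return n

    def bias_label(self) -> str:
        if self.bias_type is BiasType.NONE:
            return "none"
        if self.bias_type is BiasType.SELECTION:
            return f"omega[{self.weight_fn.describe()}] ~ CumDirichlet"
        return f"{self.bias_type.value.upper()} ~ {self.slope_prior.describe()}"


@dataclass
class Ensemble:
    models: List[ModelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise InvalidInputError("ensemble must contain at least one model")
        total = sum(m.prior_prob_exact for m in self.models)
        if total != 1:
            total_f = sum(m.prior_prob for m in self.models)
            if abs(total_f - 1.0) > 1e-12:
                raise InvalidInputError(f"prior model probabilities sum to {total_f}, not 1")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    @property
    def prior_probs(self) -> np.ndarray:
        return np.array([m.prior_prob for m in self.models])

    def indices(self, *, effect: Optional[bool] = None,
                heterogeneity: Optional[bool] = None,
                bias_types: Optional[Sequence[BiasType]] = None) -> List[int]:
        """Indices (0-based) of models matching all given component filters."""
        out = []
        for i, m in enumerate(self.models):
            if effect is not None and m.has_effect != effect:
                continue
            if heterogeneity is not None and m.has_heterogeneity != heterogeneity:
                continue
            if bias_types is not None and m.bias_type not in bias_types:
                continue
            out.append(i)
        return out


def default_weight_functions() -> List[WeightFunctionSpec]:
    """The six step weight functions of the default ensemble.

    Two two-sided functions (cutoffs {0.05} and {0.05, 0.10}) and four
    one-sided functions ({0.05}, {0.025, 0.05}, {0.05, 0.50} and
    {0.025, 0.05, 0.50}).
    """
    return [
        WeightFunctionSpec("two", (0.05,)),
        WeightFunctionSpec("two", (0.05, 0.10)),
        WeightFunctionSpec("one", (0.05,)),
        WeightFunctionSpec("one", (0.025, 0.05)),
        WeightFunctionSpec("one", (0.05, 0.50)),
        WeightFunctionSpec("one", (0.025, 0.05, 0.50)),
    ]


def default_priors() -> dict:
    """Default parameter priors, declared on the Cohen's d scale."""
    return {
        "effect": PriorSpec(PriorFamily.NORMAL, (0.0, 1.0)),
        "tau": PriorSpec(PriorFamily.INV_GAMMA, (1.0, 0.15)),
        "pet": PriorSpec(PriorFamily.CAUCHY_POS, (1.0,)),
        "peese": PriorSpec(PriorFamily.CAUCHY_POS, (5.0,)),
    }


def cum_dirichlet_weights(eta: np.ndarray) -> np.ndarray:
    """Map a Dirichlet simplex vector to monotone publication weights.

    omega_j = sum_{i=j}^{J} eta_i, so omega_1 = 1 and omega is
    non-increasing from the most significant p-interval to the least.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1 or eta.size < 2:
        raise InvalidInputError("eta must be a vector of length >= 2")
    if np.any(eta < 0) or abs(eta.sum() - 1.0) > 1e-10:
        raise InvalidInputError("eta must lie on the probability simplex")
    omega = np.cumsum(eta[::-1])[::-1]
    omega[0] = 1.0
    return np.clip(omega, 0.0, 1.0)


def build_ensemble(effect_prior: Optional[PriorSpec] = None,
                   tau_prior: Optional[PriorSpec] = None,
                   weight_fns: Optional[Sequence[WeightFunctionSpec]] = None,
                   pet_prior: Optional[PriorSpec] = None,
                   peese_prior: Optional[PriorSpec] = None,
                   include_selection: bool = True,
                   include_regression: bool = True,
                   include_bias: bool = True) -> Ensemble:
    """Construct the model ensemble with its prior model probabilities.

    With the defaults this yields 36 models: 4 without bias adjustment
    (prior probability 1/8 each), 24 selection models (1/96 each), and
    8 PET/PEESE models (1/32 each).  Prior probabilities are computed in
    exact rational arithmetic and sum to 1.
    """
    defaults = default_priors()
    effect_prior = effect_prior or defaults["effect"]
    tau_prior = tau_prior or defaults["tau"]
    pet_prior = pet_prior or defaults["pet"]
    peese_prior = peese_prior or defaults["peese"]
    if weight_fns is None:
        weight_fns = default_weight_functions()
    weight_fns = list(weight_fns) if include_selection else []
    regressions: List[Tuple[BiasType, PriorSpec]] = []
    if include_regression:
        regressions = [(BiasType.PET, pet_prior), (BiasType.PEESE, peese_prior)]
    if not include_bias:
        weight_fns, regressions = [], []

    point0_d = PriorSpec(PriorFamily.POINT, (0.0,), Scale.COHENS_D)
    effect_options = [point0_d, effect_prior]
    tau_options = [point0_d, tau_prior]

    n_combo = len(effect_options) * len(tau_options)  # 4
    n_bias_classes = int(bool(weight_fns)) + int(bool(regressions))
    if n_bias_classes:
        mass_none = Fraction(1, 2)
        mass_class = Fraction(1, 2) / n_bias_classes
    else:
        mass_none = Fraction(1)
        mass_class = Fraction(0)
    p_none = mass_none / n_combo
    p_sel = mass_class / (n_combo * len(weight_fns)) if weight_fns else Fraction(0)
    p_reg = mass_class / (n_combo * len(regressions)) if regressions else Fraction(0)

    models: List[ModelSpec] = []
    mid = 1
    for eff in effect_options:
        for tau in tau_options:
            bias_slots: List[Tuple[BiasType, Optional[WeightFunctionSpec],
                                   Optional[PriorSpec], Fraction]] = [
                (BiasType.NONE, None, None, p_none)]
            for wf in weight_fns:
                bias_slots.append((BiasType.SELECTION, wf, None, p_sel))
            for kind, prior in regressions:
                bias_slots.append((kind, None, prior, p_reg))
            for bias_type, wf, slope, prob in bias_slots:
                models.append(ModelSpec(
                    id=mid, effect=eff, heterogeneity=tau, bias_type=bias_type,
                    weight_fn=wf, slope_prior=slope,
                    prior_prob=float(prob), prior_prob_exact=prob))
                mid += 1
    return Ensemble(models=models)
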