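"""Effect-size scale conversions and p-value helpers.

The analysis pipeline fits all models on the Fisher's z scale when the
input effect sizes are Cohen's d.  The conversions here implement the
standard equal-group-size back-calculation: a two-sample standardised
mean difference with total sample size N has

    var(d) = 4/N + d^2 / (2 N),

so the sample size implied by a reported standard error is
N = (d^2 + 8) / (2 se_d^2).  The point transform is d = 2 sinh(z)
(equivalently z = atanh(d / sqrt(d^2 + 4))) and se_z = 1/sqrt(N - 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "StudyData",
    "Scale",
    "Direction",
    "ScaleConvention",
    "cohen_d_to_fisher_z",
    "fisher_z_to_cohen_d",
    "d_point_to_z",
    "z_point_to_d",
    "p_value",
    "p_cutoff_to_y_threshold",
    "InvalidInputError",
    "DegenerateStudyError",
]


class InvalidInputError(ValueError):
    """Raised for arguments outside an operation's domain."""


class DegenerateStudyError(ValueError):
    """Raised when a study's implied sample size is too small to transform."""


class Scale(str, Enum):
    COHENS_D = "cohens_d"
    FISHERS_Z = "fishers_z"
    RAW = "raw"


class Direction(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class ScaleConvention:
    """Scale of the input effect sizes and the expected effect direction."""

    scale: Scale = Scale.COHENS_D
    direction: Direction = Direction.POSITIVE


@dataclass
class StudyData:
    """Per-study effect estimates and standard errors.

    Parameters
    ----------
    y : array of effect sizes on the analysis scale.
    se : array of standard errors, all strictly positive.
    n : optional per-study total sample sizes (>= 4 where given).
    labels : optional study labels.
    """

    y: np.ndarray
    se: np.ndarray
    n: Optional[np.ndarray] = None
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        self.se = np.atleast_1d(np.asarray(self.se, dtype=float))
        if self.y.shape != self.se.shape:
            raise InvalidInputError("y and se must have the same length")
        if self.y.size < 1:
            raise InvalidInputError("at least one study is required")
        if not np.all(np.isfinite(self.y)):
            raise InvalidInputError("effect sizes must be finite")
        if not np.all(np.isfinite(self.se) & (self.se > 0)):
            raise InvalidInputError("all standard errors must be positive")
        if self.n is not None:
            self.n = np.atleast_1d(np.asarray(self.n, dtype=float))
            if self.n.shape != self.y.shape:
                raise InvalidInputError("n must match y in length")
        if not self.labels:
            self.labels = [f"study_{k + 1}" for k in range(self.y.size)]

    @property
    def K(self) -> int:
        return int(self.y.size)

    def label_of(self, k: int) -> str:
        return self.labels[k] if k < len(self.labels) else f"study_{k + 1}"


def _implied_n(d: float, se_d: float) -> float:
    return (d * d + 8.0) / (2.0 * se_d * se_d)


def d_point_to_z(d):
    """Point transform Cohen's d -> Fisher's z: z = atanh(d/sqrt(d^2+4))."""
    d = np.asarray(d, dtype=float)
    return np.arcsinh(d / 2.0)


def z_point_to_d(z):
    """Inverse point transform: d = 2 sinh(z)."""
    z = np.asarray(z, dtype=float)
    return 2.0 * np.sinh(z)


def cohen_d_to_fisher_z(d: float, se_d: float, n: Optional[float] = None,
                        label: str = "study"):
    """Convert (d, se_d) to (z, se_z).

    When ``n`` is not supplied the total sample size is back-calculated
    from the standard error; ``se_z = 1/sqrt(N - 3)`` either way.
    """
    if not se_d > 0:
        raise InvalidInputError(f"se_d must be positive, got {se_d!r}")
    N = float(n) if n is not None else _implied_n(d, se_d)
    if N <= 3:
        raise DegenerateStudyError(
            f"{label}: implied sample size N={N:.2f} <= 3; cannot map to Fisher's z"
        )
    z = float(d_point_to_z(d))
    se_z = 1.0 / math.sqrt(N - 3.0)
    return z, se_z


def fisher_z_to_cohen_d(z: float, se_z: float):
    """Exact inverse of :func:`cohen_d_to_fisher_z` (implied-N branch)."""
    if not se_z > 0:
        raise InvalidInputError(f"se_z must be positive, got {se_z!r}")
    d = float(z_point_to_d(z))
    N = 1.0 / (se_z * se_z) + 3.0
    se_d = math.sqrt((d * d + 8.0) / (2.0 * N))
    return d, se_d


def p_value(y, se, sidedness: str = "two",
            direction: Direction = Direction.POSITIVE):
    """Normal-theory p-value of a study estimate.

    two-sided: ``2 (1 - Phi(|y|/se))``; one-sided (positive direction):
    ``1 - Phi(y/se)``; the negative direction mirrors the sign.
    """
    y = np.asarray(y, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InvalidInputError("se must be positive")
    t = y / se
    if direction == Direction.NEGATIVE:
        t = -t
    if sidedness == "two":
        return 2.0 * norm.sf(np.abs(t))
    if sidedness == "one":
        return norm.sf(t)
    raise InvalidInputError(f"unknown sidedness {sidedness!r}")


def p_cutoff_to_y_threshold(cutoff: float, sidedness: str, se: float,
                            direction: Direction = Direction.POSITIVE):
    """y-space boundary of the region {p < cutoff}.

    One-sided: scalar ``se * Phi^-1(1 - cutoff)`` (sign flipped for the
    negative direction).  Two-sided: the pair ``+-se * Phi^-1(1 - cutoff/2)``.
    """
    if not (0.0 < cutoff < 1.0):
        raise InvalidInputError(f"cutoff must lie in (0, 1), got {cutoff!r}")
    if not se > 0:
        raise InvalidInputError("se must be positive")
    if sidedness == "one":
        thr = se * norm.isf(cutoff)
        return -thr if direction == Direction.NEGATIVE else thr
    if sidedness == "two":
        thr = se * norm.isf(cutoff / 2.0)
        return (-thr, thr)
    raise InvalidInputError(f"unknown sidedness {sidedness!r}")


def to_analysis_scale(data: StudyData, convention: ScaleConvention,
                      transform: bool = True) -> StudyData:
    """Map input studies to the analysis scale (Fisher's z for d input)."""
    if convention.scale is not Scale.COHENS_D or not transform:
        return data
    z = np.empty(data.K)
    se_z = np.empty(data.K)
    for k in range(data.K):
        n_k = None if data.n is None else data.n[k]
        z[k], se_z[k] = cohen_d_to_fisher_z(
            data.y[k], data.se[k], n=n_k, label=data.label_of(k))
    return StudyData(y=z, se=se_z, n=data.n, labels=list(data.labels))
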