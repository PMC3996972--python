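"""Binormal continuous-marker model, threshold policies and ROC curves.

A continuous marker ``X`` is modelled by a pair of class-conditional
densities: ``f_d(x)`` among diseased and ``f_nd(x)`` among non-diseased
subjects.  The default is the equal-variance binormal model,
``X | non-diseased ~ N(mu_nd, sigma^2)`` and ``X | diseased ~ N(mu_d,
sigma^2)``.  Under that model the disease log-odds are linear in ``x`` with
slope ``(mu_d - mu_nd) / sigma^2``, so a marker whose per-unit odds ratio is
``OR`` corresponds to the mean shift::

    mu_d - mu_nd = sigma^2 * ln(OR)

which :func:`calibrate_from_or` applies.  Positive calls are made above a
threshold ``c`` (right tail):  sensitivity ``= Phi((mu_d - c)/sigma)``,
specificity ``= Phi((c - mu_nd)/sigma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .exceptions import (
    IntegrationFailureError,
    InvalidInputError,
    SolverFailureError,
)

__all__ = [
    "GaussianMarkerPair",
    "DensityPair",
    "ThresholdPolicy",
    "RocCurve",
    "calibrate_from_or",
    "sensitivity_at",
    "specificity_at",
    "solve_threshold",
    "roc_curve",
]

_QUAD_TOL = 1e-10
_SUPPORT_SIGMAS = 10.0


@dataclass(frozen=True)
class GaussianMarkerPair:
    """Equal-variance binormal marker model.

    Defaults follow the usual standardized presentation: non-diseased mean 0,
    common standard deviation 0.5.
    """

    mu_diseased: float
    mu_nondiseased: float = 0.0
    sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise InvalidInputError(f"sigma must be > 0, got {self.sigma}")

    @property
    def odds_ratio(self) -> float:
        """Per-unit odds ratio implied by the logistic calibration."""
        return math.exp((self.mu_diseased - self.mu_nondiseased) / self.sigma**2)

    @property
    def auc(self) -> float:
        """Closed-form binormal AUC, ``Phi(delta / (sigma sqrt(2)))``."""
        delta = self.mu_diseased - self.mu_nondiseased
        return float(norm.cdf(delta / (self.sigma * math.sqrt(2.0))))

    def pdf_diseased(self, x):
        return norm.pdf(x, loc=self.mu_diseased, scale=self.sigma)

    def pdf_nondiseased(self, x):
        return norm.pdf(x, loc=self.mu_nondiseased, scale=self.sigma)

    def support(self) -> tuple:
        lo = min(self.mu_diseased, self.mu_nondiseased) - _SUPPORT_SIGMAS * self.sigma
        hi = max(self.mu_diseased, self.mu_nondiseased) + _SUPPORT_SIGMAS * self.sigma
        return lo, hi

    def to_density_pair(self) -> "DensityPair":
        """View this model through the generic density contract (quadrature path)."""
        return DensityPair(self.pdf_diseased, self.pdf_nondiseased, self.support())


@dataclass(frozen=True)
class DensityPair:
    """Generic class-conditional density contract.

    ``f_d`` and ``f_nd`` are callables (vectorized or scalar) that integrate
    to one over ``(support[0], support[1])``.  Tail areas are computed by
    adaptive quadrature; Gaussian models override this with closed forms.
    """

    f_d: Callable
    f_nd: Callable
    support: tuple = (-np.inf, np.inf)

    def _tail(self, f: Callable, c: float) -> float:
        lo, hi = self.support
        a = max(c, lo)
        if a >= hi:
            return 0.0
        val, err = integrate.quad(f, a, hi, epsabs=_QUAD_TOL, limit=200)
        if err > 1e-6:
            raise IntegrationFailureError(
                f"tail integral above {c} did not converge (estimated error {err})"
            )
        return min(max(val, 0.0), 1.0)

    def sensitivity_at(self, c: float) -> float:
        return self._tail(self.f_d, c)

    def specificity_at(self, c: float) -> float:
        return 1.0 - self._tail(self.f_nd, c)


MarkerModel = Union[GaussianMarkerPair, DensityPair]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How to choose the positivity threshold ``c``.

    mode
        ``fixed_sensitivity`` / ``fixed_specificity`` hold the named rate at
        ``level``; ``balanced`` equates sensitivity and specificity;
        ``explicit`` uses ``level`` as the threshold value itself.
    """

    mode: str
    level: Optional[float] = None

    _MODES = ("fixed_sensitivity", "fixed_specificity", "balanced", "explicit")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise InvalidInputError(f"mode must be one of {self._MODES}, got {self.mode!r}")
        if self.mode in ("fixed_sensitivity", "fixed_specificity"):
            if self.level is None or not 0 < self.level < 1:
                raise InvalidInputError(f"level must be in (0,1) for {self.mode}")
        if self.mode == "explicit" and self.level is None:
            raise InvalidInputError("explicit mode requires a threshold value in `level`")


@dataclass(frozen=True)
class RocCurve:
    """ROC curve as ordered (FPR, TPR) points with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_tsv(self) -> str:
        lines = ["fpr\ttpr"]
        lines += [f"{f!r}\t{t!r}" for f, t in zip(self.fpr, self.tpr)]
        return "\n".join(lines) + "\n"


def calibrate_from_or(
    odds_ratio: float, sigma: float = 0.5, mu_nondiseased: float = 0.0
) -> GaussianMarkerPair:
    """Binormal pair whose per-unit odds ratio equals ``odds_ratio``.

    Applies the mean shift ``sigma^2 * ln(OR)``; ``OR=1`` gives identical
    class-conditional distributions.
    """
    if not (math.isfinite(odds_ratio) and odds_ratio > 0):
        raise InvalidInputError(f"odds_ratio must be > 0, got {odds_ratio}")
    if not (math.isfinite(sigma) and sigma > 0):
        raise InvalidInputError(f"sigma must be > 0, got {sigma}")
    mu_d = mu_nondiseased + sigma**2 * math.log(odds_ratio)
    return GaussianMarkerPair(mu_d, mu_nondiseased, sigma)


def sensitivity_at(pair: MarkerModel, c: float) -> float:
    """P(X > c | diseased): Gaussian closed form, else quadrature."""
    if isinstance(pair, GaussianMarkerPair):
        return float(norm.cdf((pair.mu_diseased - c) / pair.sigma))
    return pair.sensitivity_at(c)


def specificity_at(pair: MarkerModel, c: float) -> float:
    """P(X <= c | non-diseased): Gaussian closed form, else quadrature."""
    if isinstance(pair, GaussianMarkerPair):
        return float(norm.cdf((c - pair.mu_nondiseased) / pair.sigma))
    return pair.specificity_at(c)


def solve_threshold(pair: MarkerModel, policy: ThresholdPolicy) -> float:
    """Threshold ``c`` realizing a :class:`ThresholdPolicy`.

    Gaussian pairs use quantile closed forms (``c = mu_d - sigma *
    Phi^{-1}(level)`` for fixed sensitivity, the mirror image for fixed
    specificity, the midpoint of the means for balanced).  Generic density
    pairs fall back to monotone root finding on the relevant rate, refined to
    |rate - target| < 1e-9.
    """
    if policy.mode == "explicit":
        return float(policy.level)

    if isinstance(pair, GaussianMarkerPair):
        if policy.mode == "fixed_sensitivity":
            return pair.mu_diseased - pair.sigma * float(norm.ppf(policy.level))
        if policy.mode == "fixed_specificity":
            return pair.mu_nondiseased + pair.sigma * float(norm.ppf(policy.level))
        return 0.5 * (pair.mu_diseased + pair.mu_nondiseased)

    lo, hi = pair.support
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise SolverFailureError("generic threshold solving needs a finite support")
    if policy.mode == "fixed_sensitivity":
        g = lambda c: pair.sensitivity_at(c) - policy.level
    elif policy.mode == "fixed_specificity":
        g = lambda c: pair.specificity_at(c) - policy.level
    else:
        g = lambda c: pair.sensitivity_at(c) - pair.specificity_at(c)
    if g(lo) * g(hi) > 0:
        raise SolverFailureError(
            f"threshold root not bracketed on support ({lo}, {hi}) for {policy.mode}"
        )
    return float(optimize.brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16))


def roc_curve(pair: MarkerModel, n_points: int = 512) -> RocCurve:
    """ROC curve over a threshold grid, with trapezoidal AUC.

    Endpoints (0,0) and (1,1) are always included.  For a binormal pair the
    trapezoidal AUC agrees with the closed form ``Phi(delta/(sigma sqrt(2)))``
    to well under 1e-4 at the default grid size.
    """
    if n_points < 2:
        raise InvalidInputError("n_points must be >= 2")
    if isinstance(pair, GaussianMarkerPair):
        lo, hi = pair.support()
    else:
        lo, hi = pair.support
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise InvalidInputError("ROC over a generic pair needs a finite support")
    grid = np.linspace(hi, lo, n_points)  # descending c: FPR ascends
    fpr = np.array([1.0 - specificity_at(pair, c) for c in grid])
    tpr = np.array([sensitivity_at(pair, c) for c in grid])
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    # enforce monotonicity against quadrature jitter
    fpr = np.maximum.accumulate(fpr)
    tpr = np.maximum.accumulate(tpr)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)
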