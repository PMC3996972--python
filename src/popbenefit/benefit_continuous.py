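"""RPB, PAR% and net benefit for continuous markers.

All indices are driven by the tail areas of the class-conditional densities
above the positivity threshold ``c``: sensitivity ``= int_c^inf f_d`` and
1 - specificity ``= int_c^inf f_nd``.  With disease prevalence ``w`` the
detection RPB is::

    RPB = [w f1 sens_c - (1-w) f2 (1-spec_c)] / [w f1 + (1-w) f2]

(the denominator is the threshold-independent total population stake).  The
prevention variant replaces the detection credit with efficacy and
adverse-effect integrals of marker-level-dependent profiles ``eta(x)`` and
``delta(x)``::

    numerator = w f1 int_c^inf eta(x) f_d dx
                - w int_c^inf delta(x) f_d dx
                - (1-w) int_c^inf delta(x) f_nd dx

Gaussian models evaluate every tail area in closed form; profile integrals
and non-Gaussian densities go through adaptive quadrature (absolute tolerance
1e-8, support truncated at mu +/- 10 sigma).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from numbers import Real
from typing import Callable, Optional, Union

from scipy import integrate

from .benefit_binary import BenefitWeights, CostCoefficient
from .contingency import StratumSet
from .exceptions import (
    DivisionDegeneracyError,
    IntegrationFailureError,
    InvalidInputError,
)
from .marker_density import (
    GaussianMarkerPair,
    MarkerModel,
    sensitivity_at,
    specificity_at,
)

__all__ = [
    "ContinuousPreventionProfile",
    "ContinuousBenefitReport",
    "q_unexposed",
    "par_percent_continuous",
    "rpb_detection_continuous",
    "rpb_prevention_continuous",
    "rpb_restricted_continuous",
    "rpb_adjusted_continuous",
    "total_gain_continuous",
    "nb_continuous",
]

_QUAD_ABS_TOL = 1e-8


def _as_callable(v: Union[float, Callable]) -> Callable:
    if callable(v):
        return v
    value = float(v)
    return lambda x: value


@dataclass(frozen=True)
class ContinuousPreventionProfile:
    """Marker-level-dependent prevention profile.

    ``eta`` and ``delta`` may be constants or callables of the marker value;
    ``eta(x)`` must lie in [0,1] and ``delta(x) >= 0`` over the support (spot
    checked at evaluation time).  Named presets:

    - ``constant(eta, delta)``
    - ``linear(slope, intercept, ...)``: clipped to [0,1] for eta
    - ``logistic(midpoint, scale, ...)``: ``1/(1+exp(-(x-midpoint)/scale))``
    """

    eta: Union[float, Callable] = 1.0
    delta: Union[float, Callable] = 0.0

    def eta_at(self, x):
        v = _as_callable(self.eta)(x)
        return v

    def delta_at(self, x):
        return _as_callable(self.delta)(x)

    @classmethod
    def constant(cls, eta: float, delta: float = 0.0) -> "ContinuousPreventionProfile":
        if not 0 <= eta <= 1:
            raise InvalidInputError(f"eta must be in [0,1], got {eta}")
        if delta < 0:
            raise InvalidInputError(f"delta must be >= 0, got {delta}")
        return cls(eta=eta, delta=delta)

    @classmethod
    def linear(
        cls, eta_slope: float, eta_intercept: float, delta: Union[float, Callable] = 0.0
    ) -> "ContinuousPreventionProfile":
        return cls(
            eta=lambda x: min(max(eta_slope * x + eta_intercept, 0.0), 1.0),
            delta=delta,
        )

    @classmethod
    def logistic(
        cls, midpoint: float, scale: float, delta: Union[float, Callable] = 0.0
    ) -> "ContinuousPreventionProfile":
        if scale <= 0:
            raise InvalidInputError(f"logistic scale must be > 0, got {scale}")
        return cls(
            eta=lambda x: 1.0 / (1.0 + math.exp(-(x - midpoint) / scale)),
            delta=delta,
        )


@dataclass(frozen=True)
class ContinuousBenefitReport:
    """Raw benefit summaries of one continuous-marker scenario at threshold ``c``."""

    threshold: float
    sensitivity: float
    specificity: float
    q_ue: float
    par_percent: float
    rpb: float
    nb: float
    total_gain: float
    rpb_prevention: Optional[float] = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "q_ue": self.q_ue,
            "par_percent": self.par_percent,
            "rpb": self.rpb,
            "nb": self.nb,
            "total_gain": self.total_gain,
        }
        if self.rpb_prevention is not None:
            out["rpb_prevention"] = self.rpb_prevention
        if self.params:
            out["params"] = dict(self.params)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _check_w(w: float) -> None:
    if not 0 < w < 1:
        raise InvalidInputError(f"disease prevalence w must be in (0,1), got {w}")


def q_unexposed(pair: MarkerModel, c: float, w: float) -> float:
    """Disease risk among marker-negative subjects.

    ``q_ue = w (1-sens_c) / [(1-w) spec_c + w (1-sens_c)]`` — the fraction of
    below-threshold subjects who are diseased.
    """
    _check_w(w)
    sens = sensitivity_at(pair, c)
    spec = specificity_at(pair, c)
    den = (1.0 - w) * spec + w * (1.0 - sens)
    if den <= 0:
        raise DivisionDegeneracyError(
            "no marker-negative subjects at this threshold (denominator zero)"
        )
    return w * (1.0 - sens) / den


def par_percent_continuous(pair: MarkerModel, c: float, w: float) -> float:
    """PAR% of the thresholded marker, ``(w - q_ue)/w * 100`` in percent units."""
    _check_w(w)
    return (w - q_unexposed(pair, c, w)) / w * 100.0


def _rpb_denominator(w: float, wts: BenefitWeights) -> float:
    den = w * wts.f1 + (1.0 - w) * wts.f2
    if den <= 0:
        raise DivisionDegeneracyError("RPB denominator w*f1 + (1-w)*f2 is zero")
    return den


def rpb_detection_continuous(
    pair: MarkerModel, c: float, w: float, wts: BenefitWeights
) -> float:
    """Detection RPB ``[w f1 sens - (1-w) f2 (1-spec)] / [w f1 + (1-w) f2]``."""
    _check_w(w)
    sens = sensitivity_at(pair, c)
    spec = specificity_at(pair, c)
    num = w * wts.f1 * sens - (1.0 - w) * wts.f2 * (1.0 - spec)
    return num / _rpb_denominator(w, wts)


def _profile_integral(f_density: Callable, g: Callable, lo: float, hi: float) -> float:
    """``int_lo^hi g(x) f(x) dx`` by adaptive quadrature."""
    if lo >= hi:
        return 0.0
    val, err = integrate.quad(
        lambda x: g(x) * f_density(x), lo, hi, epsabs=_QUAD_ABS_TOL, limit=200
    )
    if err > 1e-6:
        raise IntegrationFailureError(
            f"profile integral on ({lo}, {hi}) did not converge "
            f"(value {val}, estimated error {err})"
        )
    return val


def _supports(pair: MarkerModel) -> tuple:
    if isinstance(pair, GaussianMarkerPair):
        return pair.support()
    return pair.support


def _densities(pair: MarkerModel) -> tuple:
    if isinstance(pair, GaussianMarkerPair):
        return pair.pdf_diseased, pair.pdf_nondiseased
    return pair.f_d, pair.f_nd


def rpb_prevention_continuous(
    pair: MarkerModel,
    c: float,
    w: float,
    wts: BenefitWeights,
    prof: ContinuousPreventionProfile,
) -> float:
    """Prevention RPB with marker-level-dependent efficacy and adverse effects.

    Numerator: ``w f1 int_c eta f_d - w int_c delta f_d - (1-w) int_c delta
    f_nd``; the denominator is the same population stake as for detection.
    Constant ``eta`` with ``delta=0`` reduces to ``eta * w f1 sens_c /
    denominator`` (verified in tests against the closed form).
    """
    _check_w(w)
    f_d, f_nd = _densities(pair)
    lo, hi = _supports(pair)
    a = max(c, lo)
    eta_int = _profile_integral(f_d, prof.eta_at, a, hi)
    num = w * wts.f1 * eta_int
    delta = prof.delta
    if callable(delta) or float(delta) != 0.0:
        num -= w * _profile_integral(f_d, prof.delta_at, a, hi)
        num -= (1.0 - w) * _profile_integral(f_nd, prof.delta_at, a, hi)
    return num / _rpb_denominator(w, wts)


def rpb_restricted_continuous(
    pair: MarkerModel, c: float, prof: ContinuousPreventionProfile
) -> float:
    """Prevention benefit restricted to the diseased group (``delta = 0``).

    ``int_c^inf eta(x) f_d dx`` over the full diseased mass (which is one), so
    the value lies in [0, sensitivity] and is always nonnegative.
    """
    f_d, _ = _densities(pair)
    lo, hi = _supports(pair)
    return _profile_integral(f_d, prof.eta_at, max(c, lo), hi)


def rpb_adjusted_continuous(strata: StratumSet) -> float:
    """Case-weighted average of per-stratum detection RPBs.

    Payloads may be ``(pair, c, w, weights)`` tuples or precomputed RPBs.
    """
    total = 0.0
    for p_i, payload in strata:
        if isinstance(payload, tuple):
            pair_i, c_i, w_i, wts_i = payload
            total += p_i * rpb_detection_continuous(pair_i, c_i, w_i, wts_i)
        else:
            total += p_i * float(payload)
    return total


def total_gain_continuous(
    pair: MarkerModel,
    c: float,
    w: float,
    wts: BenefitWeights,
    prof: Optional[ContinuousPreventionProfile] = None,
    cost: CostCoefficient = CostCoefficient(0.0),
) -> float:
    """Total lives gained net of the per-treated-person cost ``h``.

    Detection (``prof=None``): ``[w f1 sens - (1-w) f2 (1-spec)] - h [w sens
    + (1-w)(1-spec)]``; with a prevention profile the RPB-prevention numerator
    replaces the detection numerator.  ``h=0`` recovers the RPB numerator.
    """
    _check_w(w)
    sens = sensitivity_at(pair, c)
    spec = specificity_at(pair, c)
    treated = w * sens + (1.0 - w) * (1.0 - spec)
    if prof is None:
        num = w * wts.f1 * sens - (1.0 - w) * wts.f2 * (1.0 - spec)
    else:
        num = rpb_prevention_continuous(pair, c, w, wts, prof) * _rpb_denominator(w, wts)
    return num - cost.h * treated


def nb_continuous(pair: MarkerModel, c: float, w: float, cost_ratio: float) -> float:
    """Continuous-marker net benefit ``w sens - cost_ratio (1-w)(1-spec)``.

    The continuous analog of the 2x2 quantity ``a - w_nb b`` with
    ``a = w*sens`` and ``b = (1-w)(1-spec)``.
    """
    _check_w(w)
    if not (math.isfinite(cost_ratio) and cost_ratio >= 0):
        raise InvalidInputError(f"cost_ratio must be >= 0, got {cost_ratio}")
    sens = sensitivity_at(pair, c)
    spec = specificity_at(pair, c)
    return w * sens - cost_ratio * (1.0 - w) * (1.0 - spec)
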