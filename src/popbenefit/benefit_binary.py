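"""Ratio of population benefit (RPB) and net benefit for binary markers.

The RPB weighs the lives gained by early detection of true positives against
the quality-of-life lost by intervening on false positives, relative to the
total population stake.  With population fractions ``a, b, c, d`` (see
:mod:`popbenefit.contingency`), a gain ``f1`` per early-detected case and a
loss ``f2`` per falsely treated non-case::

    RPB_detection = (a f1 - b f2) / (a f1 + b f2 + c f1 + d f2)

The denominator is the worst-case population stake and collapses to
``w f1 + (1-w) f2`` where ``w`` is disease prevalence — it does not depend on
the marker.  RPB < 0 / = 0 / > 0 classifies the program as detrimental /
neutral / beneficial at the population level.

For prevention programs a measure of efficacy ``eta`` (fraction of cases
averted among treated carriers) and adverse-effect loss ``delta`` (per
treated person, same life-value units as ``f1``) replace the detection
credit::

    RPB_prevention = (a eta f1 - a delta - b delta) / (same denominator)

Net benefit is the decision-curve quantity ``NB = a - w_nb * b`` per unit
population, with cost weight ``w_nb`` defaulting to ``f2/f1``; absolute gain
subtracts a per-treated-person cost ``h(a+b)`` from the RPB numerator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .contingency import (
    BinaryMarkerSpec,
    PopulationContext,
    StratumSet,
    TwoByTwoTable,
    metrics_from_table,
    solve_two_by_two,
)
from .exceptions import DivisionDegeneracyError, InvalidInputError

__all__ = [
    "BenefitWeights",
    "PreventionProfile",
    "CostCoefficient",
    "BenefitReport",
    "rpb_detection",
    "rpb_prevention",
    "rpb_restricted_diseased",
    "net_benefit",
    "absolute_gain",
    "rpb_adjusted_binary",
    "scenario_report",
]


@dataclass(frozen=True)
class BenefitWeights:
    """Life-value weights: ``f1`` gained per early-detected case, ``f2`` lost per false positive.

    ``f2`` is typically one minus the QALY utility weight of the intervention
    (e.g. 0.03 for esophageal adenocarcinoma surgery, 0.06 breast, 0.15
    ovarian).
    """

    f1: float = 1.0
    f2: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f1) and self.f1 > 0):
            raise InvalidInputError(f"f1 must be > 0, got {self.f1}")
        if not (math.isfinite(self.f2) and self.f2 >= 0):
            raise InvalidInputError(f"f2 must be >= 0, got {self.f2}")

    @property
    def nb_cost_ratio(self) -> float:
        """Default net-benefit cost weight, ``f2/f1``."""
        return self.f2 / self.f1


@dataclass(frozen=True)
class PreventionProfile:
    """Efficacy ``eta`` in [0,1] and per-treated-person adverse loss ``delta >= 0``."""

    eta: float
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.eta <= 1:
            raise InvalidInputError(f"eta must be in [0,1], got {self.eta}")
        if not (math.isfinite(self.delta) and self.delta >= 0):
            raise InvalidInputError(f"delta must be >= 0, got {self.delta}")


@dataclass(frozen=True)
class CostCoefficient:
    """Per-person cost ``h >= 0`` of treating each marker-positive subject."""

    h: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h) and self.h >= 0):
            raise InvalidInputError(f"h must be >= 0, got {self.h}")


@dataclass(frozen=True)
class BenefitReport:
    """All benefit summaries for one binary-marker scenario (raw, unrounded)."""

    sensitivity: float
    specificity: float
    par_percent: float
    rpb: float
    nb: float
    absolute_gain: float
    rpb_prevention: Optional[float] = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "par_percent": self.par_percent,
            "rpb": self.rpb,
            "nb": self.nb,
            "absolute_gain": self.absolute_gain,
        }
        if self.rpb_prevention is not None:
            out["rpb_prevention"] = self.rpb_prevention
        if self.params:
            out["params"] = dict(self.params)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_tsv(self) -> str:
        d = self.to_dict()
        d.pop("params", None)
        return "\t".join(d) + "\n" + "\t".join(repr(v) for v in d.values()) + "\n"


def _denominator(t: TwoByTwoTable, wts: BenefitWeights) -> float:
    den = wts.f1 * (t.a + t.c) + wts.f2 * (t.b + t.d)
    if den <= 0:
        raise DivisionDegeneracyError("RPB denominator f1*(a+c) + f2*(b+d) is zero")
    return den


def rpb_detection(t: TwoByTwoTable, wts: BenefitWeights) -> float:
    """Detection RPB ``(a f1 - b f2) / (f1 (a+c) + f2 (b+d))``."""
    return (t.a * wts.f1 - t.b * wts.f2) / _denominator(t, wts)


def rpb_prevention(
    t: TwoByTwoTable, wts: BenefitWeights, prev: PreventionProfile
) -> float:
    """Prevention RPB ``(a eta f1 - (a+b) delta) / (f1 (a+c) + f2 (b+d))``.

    With ``delta=0`` and ``eta=1`` this reduces to ``a f1 / denominator`` —
    every detected carrier's case is averted and nothing is lost on false
    positives.
    """
    num = t.a * prev.eta * wts.f1 - (t.a + t.b) * prev.delta
    return num / _denominator(t, wts)


def rpb_restricted_diseased(
    sensitivity: float, wts: BenefitWeights, prev: PreventionProfile
) -> float:
    """Prevention benefit restricted to the diseased group.

    Ignoring non-diseased subjects entirely, the benefit is the marker's
    sensitivity times the dimensionless net-efficacy factor
    ``(eta f1 - delta) / f1``.
    """
    if not 0 <= sensitivity <= 1:
        raise InvalidInputError(f"sensitivity must be in [0,1], got {sensitivity}")
    return sensitivity * (prev.eta * wts.f1 - prev.delta) / wts.f1


def net_benefit(t: TwoByTwoTable, w_nb: float) -> float:
    """Decision-curve net benefit ``a - w_nb * b`` per unit population."""
    if not (math.isfinite(w_nb) and w_nb >= 0):
        raise InvalidInputError(f"net-benefit cost weight must be >= 0, got {w_nb}")
    return t.a - w_nb * t.b


def absolute_gain(
    t: TwoByTwoTable,
    wts: BenefitWeights,
    prev: Optional[PreventionProfile] = None,
    cost: CostCoefficient = CostCoefficient(0.0),
) -> float:
    """Absolute population gain net of treatment cost ``h`` per marker-positive subject.

    Detection: ``(a f1 - b f2) - h (a+b)``; prevention (``prev`` given):
    ``(a eta f1 - (a+b) delta) - h (a+b)``.  At ``h=0`` this is the
    corresponding RPB numerator.
    """
    if prev is None:
        num = t.a * wts.f1 - t.b * wts.f2
    else:
        num = t.a * prev.eta * wts.f1 - (t.a + t.b) * prev.delta
    return num - cost.h * (t.a + t.b)


def rpb_adjusted_binary(strata: StratumSet) -> float:
    """Confounder-adjusted RPB: case-weighted average of per-stratum detection RPBs.

    Payloads may be ``(TwoByTwoTable, BenefitWeights)`` pairs or precomputed
    per-stratum RPB values.
    """
    total = 0.0
    for p_i, payload in strata:
        if isinstance(payload, tuple):
            t_i, wts_i = payload
            total += p_i * rpb_detection(t_i, wts_i)
        else:
            total += p_i * float(payload)
    return total


def scenario_report(
    spec: BinaryMarkerSpec,
    pop: PopulationContext,
    wts: BenefitWeights,
    prev: Optional[PreventionProfile] = None,
    cost: CostCoefficient = CostCoefficient(0.0),
) -> BenefitReport:
    """One-call pipeline: solve the 2x2 table, then compute every benefit summary."""
    t = solve_two_by_two(spec, pop)
    m = metrics_from_table(t)
    return BenefitReport(
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        par_percent=m.par_percent,
        rpb=rpb_detection(t, wts),
        nb=net_benefit(t, wts.nb_cost_ratio),
        absolute_gain=absolute_gain(t, wts, prev, cost),
        rpb_prevention=None if prev is None else rpb_prevention(t, wts, prev),
        params={
            "odds_ratio": spec.odds_ratio,
            "marker_prevalence": spec.marker_prevalence,
            "disease_prevalence": pop.disease_prevalence,
            "f1": wts.f1,
            "f2": wts.f2,
            "eta": None if prev is None else prev.eta,
            "delta": None if prev is None else prev.delta,
            "h": cost.h,
        },
    )
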