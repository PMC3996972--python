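"""Population 2x2 exposure-by-disease tables and classification metrics.

The central object is the joint distribution of a binary marker (or risk-factor
exposure) and a binary disease outcome, stored as the four population fractions

=========  =========  ============
              diseased  non-diseased
=========  =========  ============
marker +       a           b
marker -       c           d
=========  =========  ============

Summary association studies usually report an odds ratio and a marker
prevalence rather than the joint table, so :func:`solve_two_by_two`
reconstructs the unique table consistent with a given odds ratio, marker
prevalence and disease prevalence.  From the table, sensitivity ``a/(a+c)``,
specificity ``d/(b+d)``, the overall disease risk ``r1 = a+c``, the risk in
the marker-negative group ``r2 = c/(c+d)`` and the population attributable
risk percent ``PAR% = (r1-r2)/r1 * 100`` all follow in closed form.

Note on naming: some sources label ``r1`` "prevalence" and ``r2`` the "false
negative fraction".  The formulas here are the standard ones: ``r1`` is the
overall disease risk and ``r2`` the disease risk among the unexposed (the
false negative fraction proper is ``1 - sensitivity = c/(a+c)``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .exceptions import (
    DivisionDegeneracyError,
    InternalConsistencyError,
    InvalidInputError,
    InvalidStrataError,
)

__all__ = [
    "TwoByTwoTable",
    "BinaryMarkerSpec",
    "PopulationContext",
    "BinaryClassificationMetrics",
    "StratumSet",
    "solve_two_by_two",
    "metrics_from_table",
    "rare_disease_metrics",
    "par_percent_adjusted",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TwoByTwoTable:
    """Joint population fractions of a binary marker and a binary outcome.

    Parameters
    ----------
    a, b, c, d
        Fractions of the population that are marker-positive diseased,
        marker-positive non-diseased, marker-negative diseased and
        marker-negative non-diseased.  Must be nonnegative and sum to one.
    n
        Optional total count when the table was built from cohort counts.
    """

    a: float
    b: float
    c: float
    d: float
    n: Optional[float] = None

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(not math.isfinite(x) or x < 0 for x in cells):
            raise InvalidInputError(f"table cells must be finite and >= 0, got {cells}")
        if abs(sum(cells) - 1.0) > _SUM_TOL:
            raise InvalidInputError(
                f"table cells must sum to 1, got {sum(cells)!r}; "
                "use TwoByTwoTable.from_counts for raw counts"
            )

    @classmethod
    def from_counts(cls, a: float, b: float, c: float, d: float) -> "TwoByTwoTable":
        """Build a table from (possibly integer) cell counts, normalizing to fractions."""
        total = a + b + c + d
        if total <= 0:
            raise InvalidInputError("counts must have a positive total")
        return cls(a / total, b / total, c / total, d / total, n=total)

    @property
    def marker_prevalence(self) -> float:
        return self.a + self.b

    @property
    def disease_prevalence(self) -> float:
        return self.a + self.c

    @property
    def odds_ratio(self) -> float:
        if self.b == 0 or self.c == 0:
            raise DivisionDegeneracyError("odds ratio undefined: cell b or c is zero")
        return (self.a * self.d) / (self.b * self.c)

    def to_tsv(self) -> str:
        """One-row tab-delimited representation with an ``a b c d`` header."""
        header = "a\tb\tc\td"
        if self.n is not None:
            return f"{header}\tn\n{self.a}\t{self.b}\t{self.c}\t{self.d}\t{self.n}\n"
        return f"{header}\n{self.a}\t{self.b}\t{self.c}\t{self.d}\n"

    @classmethod
    def from_tsv(cls, text: str) -> "TwoByTwoTable":
        """Parse :meth:`to_tsv` output; values summing to more than 1 are treated as counts."""
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        if len(lines) < 2:
            raise InvalidInputError("expected a header line and a value line")
        header = [h.strip().lower() for h in lines[0].split("\t")]
        values = dict(zip(header, (float(v) for v in lines[1].split("\t"))))
        try:
            a, b, c, d = values["a"], values["b"], values["c"], values["d"]
        except KeyError as exc:
            raise InvalidInputError(f"missing column {exc} in table header") from exc
        if abs((a + b + c + d) - 1.0) > _SUM_TOL:
            return cls.from_counts(a, b, c, d)
        return cls(a, b, c, d, n=values.get("n"))


@dataclass(frozen=True)
class BinaryMarkerSpec:
    """Summary description of a binary marker: odds ratio and carrier prevalence."""

    odds_ratio: float
    marker_prevalence: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.odds_ratio) and self.odds_ratio > 0):
            raise InvalidInputError(f"odds_ratio must be > 0, got {self.odds_ratio}")
        if not 0 < self.marker_prevalence < 1:
            raise InvalidInputError(
                f"marker_prevalence must be in (0,1), got {self.marker_prevalence}"
            )


@dataclass(frozen=True)
class PopulationContext:
    """Disease prevalence ``w`` of the target population.

    With ``rare_disease_limit=True`` the ``w -> 0`` closed forms apply and
    ``disease_prevalence`` may be zero.
    """

    disease_prevalence: float
    rare_disease_limit: bool = False

    def __post_init__(self) -> None:
        if self.rare_disease_limit:
            if not 0 <= self.disease_prevalence < 1:
                raise InvalidInputError("disease_prevalence must be in [0,1)")
        elif not 0 < self.disease_prevalence < 1:
            raise InvalidInputError(
                f"disease_prevalence must be in (0,1), got {self.disease_prevalence}"
            )


@dataclass(frozen=True)
class BinaryClassificationMetrics:
    """Classification and attributable-risk summaries of a 2x2 table.

    ``par_percent`` is in percent units; every other field is a fraction.
    """

    sensitivity: float
    specificity: float
    r1: float
    r2: float
    risk_exposed: float
    par_percent: float
    odds_ratio: float

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "r1": self.r1,
            "r2": self.r2,
            "risk_exposed": self.risk_exposed,
            "par_percent": self.par_percent,
            "odds_ratio": self.odds_ratio,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class StratumSet:
    """Case-proportion weights ``p_i`` with arbitrary per-stratum payloads.

    Weights must be nonnegative and sum to one (within 1e-9); payloads are
    interpreted by the consuming adjusted-index function.
    """

    weights: Sequence[float]
    payloads: Sequence[object] = field(default=())

    def __post_init__(self) -> None:
        w = list(self.weights)
        if any(p < 0 for p in w):
            raise InvalidStrataError(f"stratum weights must be >= 0, got {w}")
        if abs(sum(w) - 1.0) > 1e-9:
            raise InvalidStrataError(f"stratum weights must sum to 1, got {sum(w)!r}")
        if self.payloads and len(self.payloads) != len(w):
            raise InvalidStrataError("payloads and weights must have equal length")

    def __iter__(self):
        return iter(zip(self.weights, self.payloads))

    def __len__(self) -> int:
        return len(self.weights)


def solve_two_by_two(spec: BinaryMarkerSpec, pop: PopulationContext) -> TwoByTwoTable:
    """Reconstruct the population 2x2 table from (OR, marker prevalence, disease prevalence).

    With margins ``p = a+b`` (marker prevalence) and ``w = a+c`` (disease
    prevalence) and total 1, the constraint ``ad = OR * bc`` gives a quadratic
    in the joint cell ``a``::

        (1 - OR) a^2 + [1 + (OR - 1)(p + w)] a - OR p w = 0

    Exactly one root yields four cells in ``[0, 1]``; it is returned.  ``OR=1``
    is handled as exact independence, ``a = p*w``.  The roots are computed in a
    cancellation-free form (the larger-magnitude branch first, the companion
    root via Vieta's product ``C/q``).
    """
    orr = spec.odds_ratio
    p = spec.marker_prevalence
    w = pop.disease_prevalence
    if not 0 < w < 1:
        raise InvalidInputError("solve_two_by_two requires disease_prevalence in (0,1)")

    if orr == 1.0:
        a = p * w
    else:
        A = 1.0 - orr
        B = 1.0 + (orr - 1.0) * (p + w)
        C = -orr * p * w
        disc = B * B - 4.0 * A * C
        if disc < 0:
            raise InternalConsistencyError(
                f"negative discriminant {disc} for OR={orr}, p={p}, w={w}"
            )
        q = -(B + math.copysign(math.sqrt(disc), B)) / 2.0
        roots = [q / A, C / q]
        lo, hi = max(0.0, p + w - 1.0), min(p, w)
        eps = 1e-12
        admissible = [r for r in roots if lo - eps <= r <= hi + eps]
        if len(admissible) != 1:
            # A double root at the boundary can appear twice; collapse duplicates.
            admissible = sorted(set(round(r, 15) for r in admissible))
            if len(admissible) != 1:
                raise InternalConsistencyError(
                    f"expected exactly one admissible root, got {roots} "
                    f"for OR={orr}, p={p}, w={w}"
                )
        a = min(max(admissible[0], lo), hi)

    b = p - a
    c = w - a
    d = 1.0 - a - b - c
    return TwoByTwoTable(a, max(b, 0.0), max(c, 0.0), max(d, 0.0))


def metrics_from_table(t: TwoByTwoTable) -> BinaryClassificationMetrics:
    """Sensitivity, specificity, risks, PAR% and the recomputed odds ratio of a table."""
    for margin, name in (
        (t.a + t.c, "diseased margin a+c"),
        (t.b + t.d, "non-diseased margin b+d"),
        (t.c + t.d, "marker-negative margin c+d"),
        (t.a + t.b, "marker-positive margin a+b"),
    ):
        if margin == 0:
            raise DivisionDegeneracyError(f"{name} is zero")
    sens = t.a / (t.a + t.c)
    spec = t.d / (t.b + t.d)
    r1 = t.a + t.c
    r2 = t.c / (t.c + t.d)
    risk_exposed = t.a / (t.a + t.b)
    par = (r1 - r2) / r1 * 100.0
    if sens in (0.0, 1.0) or spec in (0.0, 1.0):
        orr = math.inf if (sens == 1.0 or spec == 1.0) else 0.0
    else:
        orr = (sens / (1.0 - sens)) / ((1.0 - spec) / spec)
    return BinaryClassificationMetrics(sens, spec, r1, r2, risk_exposed, par, orr)


def rare_disease_metrics(spec: BinaryMarkerSpec) -> BinaryClassificationMetrics:
    """Classification metrics in the rare-disease (``w -> 0``) limit.

    In the limit, sensitivity ``= p*OR / (p*OR + 1 - p)``, specificity
    ``= 1 - p`` and ``PAR% = 100 * p(OR-1) / (p(OR-1) + 1)`` with ``p`` the
    marker prevalence.  The absolute risks ``r1``, ``r2`` and the risk in the
    exposed all tend to zero and are reported as 0.
    """
    p = spec.marker_prevalence
    orr = spec.odds_ratio
    sens = p * orr / (p * orr + 1.0 - p)
    spec_ = 1.0 - p
    par = 100.0 * p * (orr - 1.0) / (p * (orr - 1.0) + 1.0)
    return BinaryClassificationMetrics(sens, spec_, 0.0, 0.0, 0.0, par, orr)


def _par_of(payload: Union[float, TwoByTwoTable, BinaryClassificationMetrics]) -> float:
    if isinstance(payload, TwoByTwoTable):
        return metrics_from_table(payload).par_percent
    if isinstance(payload, BinaryClassificationMetrics):
        return payload.par_percent
    return float(payload)


def par_percent_adjusted(strata: StratumSet) -> float:
    """Confounder-adjusted PAR% as the case-weighted average of stratum PAR% values.

    Each payload may be a :class:`TwoByTwoTable`, a
    :class:`BinaryClassificationMetrics`, or a bare PAR% value in percent.
    """
    return sum(p_i * _par_of(payload) for p_i, payload in strata)
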