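"""Synthetic individual-level cohorts and plug-in (empirical) estimators.

The simulators are the stochastic oracle for the analytic formulas: a binary
cohort is a multinomial draw over the four solved table cells (so the
empirical odds ratio is unbiased for the generating odds ratio by
construction), and a continuous cohort draws Bernoulli(w) disease labels and
class-conditional Gaussian marker values.  The plug-in estimators count the
empirical 2x2 at a threshold and reuse the binary benefit formulas, so the
empirical RPB/PAR%/NB converge to the analytic values of the generating
scenario as n grows.

Cohort files are two-column tab-delimited text with a ``marker\tdisease``
header; binary markers are encoded 0/1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .benefit_binary import (
    BenefitReport,
    BenefitWeights,
    CostCoefficient,
    PreventionProfile,
    absolute_gain,
    net_benefit,
    rpb_detection,
    rpb_prevention,
)
from .contingency import (
    BinaryMarkerSpec,
    PopulationContext,
    TwoByTwoTable,
    metrics_from_table,
    solve_two_by_two,
)
from .exceptions import EstimationDegeneracyError, InvalidInputError
from .marker_density import GaussianMarkerPair

__all__ = [
    "SimulatedCohort",
    "simulate_binary_cohort",
    "simulate_continuous_cohort",
    "empirical_table",
    "empirical_benefit",
    "write_cohort",
    "read_cohort",
]

_COLUMNS = ["marker", "disease"]


@dataclass(frozen=True)
class SimulatedCohort:
    """Per-subject records plus the parameters that generated them."""

    data: pd.DataFrame  # columns: marker (float or 0/1), disease (0/1)
    params: dict

    def __post_init__(self) -> None:
        if list(self.data.columns) != _COLUMNS:
            raise InvalidInputError(f"cohort columns must be {_COLUMNS}")

    @property
    def n(self) -> int:
        return len(self.data)


def _check_n(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise InvalidInputError(f"n must be a positive integer, got {n!r}")


def simulate_binary_cohort(
    spec: BinaryMarkerSpec, pop: PopulationContext, n: int, seed: int
) -> SimulatedCohort:
    """Multinomial cohort over the four cells of the solved 2x2 table."""
    _check_n(n)
    t = solve_two_by_two(spec, pop)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, [t.a, t.b, t.c, t.d])
    marker = np.repeat([1, 1, 0, 0], counts)
    disease = np.repeat([1, 0, 1, 0], counts)
    data = pd.DataFrame({"marker": marker, "disease": disease})
    params = {
        "kind": "binary",
        "odds_ratio": spec.odds_ratio,
        "marker_prevalence": spec.marker_prevalence,
        "disease_prevalence": pop.disease_prevalence,
        "n": int(n),
        "seed": int(seed),
    }
    return SimulatedCohort(data, params)


def simulate_continuous_cohort(
    pair: GaussianMarkerPair, w: float, n: int, seed: int
) -> SimulatedCohort:
    """Bernoulli(w) disease labels with class-conditional Gaussian marker values."""
    _check_n(n)
    if not 0 < w < 1:
        raise InvalidInputError(f"disease prevalence w must be in (0,1), got {w}")
    rng = np.random.default_rng(seed)
    disease = (rng.random(n) < w).astype(np.int64)
    means = np.where(disease == 1, pair.mu_diseased, pair.mu_nondiseased)
    marker = rng.normal(means, pair.sigma)
    data = pd.DataFrame({"marker": marker, "disease": disease})
    params = {
        "kind": "continuous",
        "mu_diseased": pair.mu_diseased,
        "mu_nondiseased": pair.mu_nondiseased,
        "sigma": pair.sigma,
        "disease_prevalence": w,
        "n": int(n),
        "seed": int(seed),
    }
    return SimulatedCohort(data, params)


def empirical_table(
    cohort: Union[SimulatedCohort, pd.DataFrame], threshold: Optional[float] = None
) -> TwoByTwoTable:
    """Empirical 2x2 population-fraction table, dichotomizing at ``threshold`` if given.

    Binary cohorts (0/1 markers) need no threshold; continuous cohorts are
    called positive above ``threshold``.
    """
    data = cohort.data if isinstance(cohort, SimulatedCohort) else cohort
    disease = data["disease"].to_numpy()
    if disease.min() == disease.max():
        raise EstimationDegeneracyError(
            "cohort contains a single outcome class; empirical metrics undefined"
        )
    marker = data["marker"].to_numpy()
    if threshold is None:
        values = set(np.unique(marker))
        if not values <= {0, 1}:
            raise InvalidInputError(
                "continuous markers require a threshold for dichotomization"
            )
        positive = marker == 1
    else:
        positive = marker > threshold
    a = int(np.sum(positive & (disease == 1)))
    b = int(np.sum(positive & (disease == 0)))
    c = int(np.sum(~positive & (disease == 1)))
    d = int(np.sum(~positive & (disease == 0)))
    return TwoByTwoTable.from_counts(a, b, c, d)


def empirical_benefit(
    cohort: Union[SimulatedCohort, pd.DataFrame],
    wts: BenefitWeights,
    threshold: Optional[float] = None,
    prev: Optional[PreventionProfile] = None,
    cost: CostCoefficient = CostCoefficient(0.0),
) -> BenefitReport:
    """Plug-in benefit report from the empirical 2x2 at ``threshold``."""
    t = empirical_table(cohort, threshold)
    m = metrics_from_table(t)
    return BenefitReport(
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        par_percent=m.par_percent,
        rpb=rpb_detection(t, wts),
        nb=net_benefit(t, wts.nb_cost_ratio),
        absolute_gain=absolute_gain(t, wts, prev, cost),
        rpb_prevention=None if prev is None else rpb_prevention(t, wts, prev),
        params={"n": t.n, "threshold": threshold, "f1": wts.f1, "f2": wts.f2},
    )


def write_cohort(cohort: SimulatedCohort, path: Union[str, Path]) -> None:
    """Write the cohort TSV plus a ``<path>.json`` sidecar of generating parameters."""
    path = Path(path)
    cohort.data.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(cohort.params, indent=2) + "\n"
    )


def read_cohort(path: Union[str, Path]) -> SimulatedCohort:
    """Read a cohort TSV (and its parameter sidecar when present)."""
    path = Path(path)
    data = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    params = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return SimulatedCohort(data[_COLUMNS], params)
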