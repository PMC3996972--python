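"""Reference benefit grids for hypothetical binary and continuous markers.

Two standard grids cross marker strength with marker prevalence (binary) or
threshold policy (continuous) under three disease-specific false-positive
loss weights (``f2`` = 0.03 esophageal adenocarcinoma, 0.06 breast cancer,
0.15 ovarian cancer, all with ``f1 = 1``):

- binary grid: OR in {1.5, 2, 4, 10, 20, 50} x prevalence in
  {0.1, 1, 10, 30, 70}% -> PAR%, sensitivity, specificity, RPB and NB per
  disease, at 1% disease prevalence by default;
- continuous grid: the same ORs under three threshold policies (sensitivity
  fixed at 95%, specificity fixed at 95%, balanced).

``generate_*`` return full-precision DataFrames; ``render_*`` format them the
way such grids are conventionally printed (rates and RPB/NB to 3 decimals,
PAR% to 2, half-up, keeping the sign of values that round to zero — a raw
-0.0001 prints as "-0.000").
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .benefit_binary import BenefitWeights, net_benefit, rpb_detection
from .benefit_continuous import (
    nb_continuous,
    par_percent_continuous,
    rpb_detection_continuous,
)
from .contingency import (
    BinaryMarkerSpec,
    PopulationContext,
    metrics_from_table,
    solve_two_by_two,
)
from .marker_density import ThresholdPolicy, calibrate_from_or, sensitivity_at, specificity_at, solve_threshold

__all__ = [
    "ODDS_RATIOS",
    "PREVALENCES_PCT",
    "DISEASE_F2",
    "THRESHOLD_POLICIES",
    "generate_table1",
    "generate_table2",
    "render_table1",
    "render_table2",
    "format_fixed",
]

ODDS_RATIOS = (1.5, 2.0, 4.0, 10.0, 20.0, 50.0)
PREVALENCES_PCT = (0.1, 1.0, 10.0, 30.0, 70.0)
#: false-positive loss weights (1 - QALY utility of intervention) per disease
DISEASE_F2 = {"ea": 0.03, "breast": 0.06, "ovarian": 0.15}
THRESHOLD_POLICIES = (
    ("fixed_sensitivity", ThresholdPolicy("fixed_sensitivity", 0.95)),
    ("fixed_specificity", ThresholdPolicy("fixed_specificity", 0.95)),
    ("balanced", ThresholdPolicy("balanced")),
)


def format_fixed(x: float, decimals: int) -> str:
    """Half-up fixed-point formatting that preserves the sign of a rounded zero."""
    quantum = Decimal(1).scaleb(-decimals)
    s = str(Decimal(repr(float(abs(x)))).quantize(quantum, ROUND_HALF_UP))
    return ("-" if x < 0 else "") + s


def generate_table1(disease_prev: float = 0.01) -> pd.DataFrame:
    """Binary-marker benefit grid (full precision), one row per (OR, prevalence)."""
    pop = PopulationContext(disease_prev)
    rows = []
    for prev_pct in PREVALENCES_PCT:
        for orr in ODDS_RATIOS:
            spec = BinaryMarkerSpec(orr, prev_pct / 100.0)
            t = solve_two_by_two(spec, pop)
            m = metrics_from_table(t)
            row = {
                "or": orr,
                "prevalence_pct": prev_pct,
                "par_percent": m.par_percent,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            }
            for name, f2 in DISEASE_F2.items():
                wts = BenefitWeights(1.0, f2)
                row[f"rpb_{name}"] = rpb_detection(t, wts)
            for name, f2 in DISEASE_F2.items():
                row[f"nb_{name}"] = net_benefit(t, f2)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_table2(disease_prev: float = 0.01) -> pd.DataFrame:
    """Continuous-marker benefit grid (full precision), one row per (policy, OR)."""
    rows = []
    for policy_name, policy in THRESHOLD_POLICIES:
        for orr in ODDS_RATIOS:
            pair = calibrate_from_or(orr)
            c = solve_threshold(pair, policy)
            row = {
                "policy": policy_name,
                "or": orr,
                "threshold": c,
                "par_percent": par_percent_continuous(pair, c, disease_prev),
                "sensitivity": sensitivity_at(pair, c),
                "specificity": specificity_at(pair, c),
            }
            for name, f2 in DISEASE_F2.items():
                wts = BenefitWeights(1.0, f2)
                row[f"rpb_{name}"] = rpb_detection_continuous(pair, c, disease_prev, wts)
            for name, f2 in DISEASE_F2.items():
                row[f"nb_{name}"] = nb_continuous(pair, c, disease_prev, f2)
            rows.append(row)
    return pd.DataFrame(rows)


_VALUE_DECIMALS = {"par_percent": 2, "sensitivity": 3, "specificity": 3}


def _render(df: pd.DataFrame, id_cols: list, rate_decimals: dict, raw: bool) -> str:
    if raw:
        return df.to_csv(sep="\t", index=False, lineterminator="\n")
    out = df.copy()
    for col in out.columns:
        if col in id_cols:
            continue
        nd = rate_decimals.get(col, 3)
        out[col] = [format_fixed(v, nd) for v in out[col]]
    return out.to_csv(sep="\t", index=False, lineterminator="\n")


def render_table1(df: pd.DataFrame, raw: bool = False) -> str:
    """TSV rendering of the binary grid (rounded unless ``raw``)."""
    return _render(df, ["or", "prevalence_pct"], _VALUE_DECIMALS, raw)


def render_table2(df: pd.DataFrame, raw: bool = False) -> str:
    """TSV rendering of the continuous grid.

    Sensitivity/specificity print to 2 decimals here (threshold policies make
    finer digits uninformative); the threshold itself prints to 4.
    """
    decimals = {"par_percent": 2, "sensitivity": 2, "specificity": 2, "threshold": 4}
    return _render(df, ["policy", "or"], decimals, raw)
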