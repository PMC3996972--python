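"""Exception hierarchy.

All package errors derive from :class:`PopulationBenefitError` so callers can
catch one type; validation failures additionally derive from ``ValueError``.
"""


class PopulationBenefitError(Exception):
    """Base class for all errors raised by popbenefit."""


class InvalidInputError(PopulationBenefitError, ValueError):
    """A scalar parameter is outside its valid range (e.g. prevalence of 0 or 1)."""


class InternalConsistencyError(PopulationBenefitError, RuntimeError):
    """An internal invariant failed (e.g. no admissible root of the table quadratic)."""


class DivisionDegeneracyError(PopulationBenefitError, ZeroDivisionError):
    """A required margin or denominator is zero; the message names it."""


class InvalidStrataError(PopulationBenefitError, ValueError):
    """Stratum weights are negative or do not sum to one."""


class SolverFailureError(PopulationBenefitError, RuntimeError):
    """A threshold root could not be bracketed or refined."""


class IntegrationFailureError(PopulationBenefitError, RuntimeError):
    """Adaptive quadrature did not converge; the message carries diagnostics."""


class EstimationDegeneracyError(PopulationBenefitError, ValueError):
    """An empirical estimate is undefined for the given cohort (e.g. one class only)."""
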