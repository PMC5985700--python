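"""Apparent incidence and risk ratio under the three analysis variants.

Each variant pairs a baseline-status source (defining who enters the
at-risk set) with an outcome source (defining who counts as an incident
case):

==========================  ================  ==============
variant                     baseline source   outcome source
==========================  ================  ==============
``total``                   test (T1)         test (T2)
``selection_only``          test (T1)         truth (D2)
``misclassification_only``  truth (D1)        test (T2)
==========================  ================  ==============

``total`` is what a real study observes; the other two isolate the bias
contributed by imperfect enrolment screening and by imperfect incident-case
detection, respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .simulate import Cohort

VARIANTS: tuple[str, ...] = ("total", "selection_only", "misclassification_only")

# variant -> (attribute giving baseline status, attribute giving outcome)
_SOURCES = {
    "total": ("test_baseline", "test_followup"),
    "selection_only": ("test_baseline", "disease_followup"),
    "misclassification_only": ("disease_baseline", "test_followup"),
}


class EstimationError(RuntimeError):
    """A replicate-level estimate could not be computed (e.g. empty risk set)."""


def _check_variant(variant: str) -> None:
    if variant not in _SOURCES:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts among the at-risk set.

    a: exposed cases, b: exposed non-cases, c: unexposed cases,
    d: unexposed non-cases.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class VariantEstimate:
    """Apparent estimates for one analysis variant of one replicate.

    ``apparent_rr`` is NaN when inestimable (no unexposed cases, or an
    empty exposure arm).
    """

    apparent_incidence: float
    apparent_rr: float
    at_risk_n: int


#: replicate-level estimates keyed by variant tag
BiasEstimates = dict[str, VariantEstimate]


def build_risk_set(cohort: Cohort, variant: str) -> np.ndarray:
    """Boolean mask of subjects entering the at-risk cohort under ``variant``.

    Subjects whose baseline-status source is negative are at risk: T1 = 0
    for ``total`` and ``selection_only``, D1 = 0 for
    ``misclassification_only``.
    """
    _check_variant(variant)
    baseline_attr, _ = _SOURCES[variant]
    return ~getattr(cohort, baseline_attr)


def contingency(cohort: Cohort, variant: str) -> TwoByTwo:
    """Cross-tabulate exposure against outcome over the variant's risk set."""
    _check_variant(variant)
    at_risk = build_risk_set(cohort, variant)
    if not at_risk.any():
        raise EstimationError(f"empty risk set for variant {variant!r}")
    _, outcome_attr = _SOURCES[variant]
    case = getattr(cohort, outcome_attr) & at_risk
    exposed = cohort.exposure
    a = int(np.count_nonzero(case & exposed))
    c = int(np.count_nonzero(case & ~exposed))
    b = int(np.count_nonzero(at_risk & exposed)) - a
    d = int(np.count_nonzero(at_risk & ~exposed)) - c
    return TwoByTwo(a, b, c, d)


def incidence(table: TwoByTwo) -> float:
    """One-interval risk: new cases divided by the number at risk at baseline."""
    if table.total == 0:
        raise EstimationError("cannot compute incidence from an all-zero table")
    return (table.a + table.c) / table.total


def risk_ratio(table: TwoByTwo) -> float:
    """Risk among exposed divided by risk among unexposed.

    Returns NaN when the ratio is undefined (no unexposed cases).  A zero
    numerator with a positive denominator is a defined estimate of 0.
    """
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise EstimationError("empty exposure arm: risk ratio inestimable")
    if table.c == 0:
        return math.nan
    risk_exposed = table.a / (table.a + table.b)
    risk_unexposed = table.c / (table.c + table.d)
    return risk_exposed / risk_unexposed


def analyze_cohort(cohort: Cohort) -> BiasEstimates:
    """Estimate apparent incidence and RR under all three variants.

    Replicate-level failures (empty risk set or exposure arm) are recorded
    as NaN rather than raised, so a single degenerate replicate does not
    abort a grid run.
    """
    estimates: BiasEstimates = {}
    for variant in VARIANTS:
        try:
            table = contingency(cohort, variant)
            inc = incidence(table)
        except EstimationError:
            estimates[variant] = VariantEstimate(math.nan, math.nan, 0)
            continue
        try:
            rr = risk_ratio(table)
        except EstimationError:
            rr = math.nan
        estimates[variant] = VariantEstimate(inc, rr, table.total)
    return estimates
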