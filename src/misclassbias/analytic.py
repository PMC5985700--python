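"""Closed-form expected apparent incidence and risk ratio.

These expressions follow from the generative assumptions of the simulator
(disease persistence, non-differential test errors, conditional
independence of the two test applications given true status) by
conditioning on baseline truth within the observed at-risk set.

Let p be true baseline prevalence, I the true one-interval incidence among
the truly at-risk, Se/Sp the test operating characteristics.  A subject
enters the observed at-risk set when its baseline source is negative:

* truly non-diseased and test-negative, with probability (1-p)*Sp; such a
  subject is an apparent incident case at follow-up with probability
  q0 = I*Se + (1-I)*(1-Sp);
* truly diseased but a baseline false negative, with probability p*(1-Se);
  disease persists, so the subject tests positive at follow-up with
  probability Se.

The ``total`` expectation is the mixture of those two case probabilities
over the at-risk set; ``selection_only`` replaces the follow-up test with
truth (case probabilities I and 1); ``misclassification_only`` starts from
the true at-risk set (D1 = 0), leaving q0 alone.

Because baseline disease is independent of exposure in the default
generator, the expected apparent risk ratio is the ratio of the expected
apparent incidence evaluated at the exposed and unexposed true incidences.
These closed forms are validated against the Monte-Carlo simulator in the
test suite before being used as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .simulate import Scenario, _check_probability

__all__ = [
    "ExpectedEstimates",
    "expected_apparent_incidence",
    "expected_apparent_rr",
    "expected_estimates",
    "contour_surface",
]

_VARIANTS = ("total", "selection_only", "misclassification_only")


@dataclass(frozen=True)
class ExpectedEstimates:
    """Deterministic limits of the apparent estimates for one variant."""

    variant: str
    expected_apparent_incidence: float
    expected_apparent_rr: float


def expected_apparent_incidence(
    variant: str, p: float, incidence: float, se: float, sp: float
) -> float:
    """Expected apparent one-interval incidence for an analysis variant.

    Parameters are the true baseline prevalence ``p``, the true marginal
    at-risk incidence ``incidence``, and the test's ``se`` and ``sp``.
    """
    for name, value in (("p", p), ("incidence", incidence), ("se", se), ("sp", sp)):
        _check_probability(name, value)
    q0 = incidence * se + (1.0 - incidence) * (1.0 - sp)
    if variant == "misclassification_only":
        return q0
    denom = (1.0 - p) * sp + p * (1.0 - se)
    if denom == 0.0:
        raise ParameterError(
            "degenerate at-risk set: no subject can test negative at baseline "
            f"(p={p}, se={se}, sp={sp})"
        )
    if variant == "total":
        return ((1.0 - p) * sp * q0 + p * (1.0 - se) * se) / denom
    if variant == "selection_only":
        return ((1.0 - p) * sp * incidence + p * (1.0 - se)) / denom
    raise ParameterError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")


def expected_apparent_rr(
    variant: str,
    p: float,
    incidence_unexposed: float,
    incidence_exposed: float,
    se: float,
    sp: float,
    exposure_prevalence: float = 0.5,
) -> float:
    """Expected apparent risk ratio for an analysis variant.

    Valid because baseline disease is independent of exposure in the
    default generator, so both exposure arms share the prevalence ``p``.
    ``exposure_prevalence`` is accepted for forward compatibility with a
    baseline exposure-disease association and is unused in the default
    model.
    """
    inc_exposed = expected_apparent_incidence(variant, p, incidence_exposed, se, sp)
    inc_unexposed = expected_apparent_incidence(variant, p, incidence_unexposed, se, sp)
    if inc_unexposed == 0.0:
        raise ParameterError("expected unexposed apparent incidence is 0: RR undefined")
    return inc_exposed / inc_unexposed


def expected_estimates(scenario: Scenario, variant: str) -> ExpectedEstimates:
    """Expected apparent estimates for one scenario and variant."""
    return ExpectedEstimates(
        variant=variant,
        expected_apparent_incidence=expected_apparent_incidence(
            variant, scenario.prevalence, scenario.incidence, scenario.se, scenario.sp
        ),
        expected_apparent_rr=expected_apparent_rr(
            variant,
            scenario.prevalence,
            scenario.incidence_unexposed,
            scenario.incidence_exposed,
            scenario.se,
            scenario.sp,
            scenario.exposure_prevalence,
        ),
    )


def contour_surface(
    variant: str,
    p: float,
    incidence: float,
    se_grid: np.ndarray,
    sp_grid: np.ndarray,
    estimand: str = "incidence",
    true_rr: float = 3.0,
    exposure_prevalence: float = 0.5,
) -> np.ndarray:
    """Dense matrix of expected values over a Se x Sp grid.

    Entry ``[i, j]`` is the expectation at ``se_grid[i]``, ``sp_grid[j]``.
    With ``estimand="risk_ratio"`` the unexposed and exposed incidences are
    back-solved from the marginal ``incidence``, ``true_rr`` and
    ``exposure_prevalence``, as in the simulator.  The cell where
    se = sp = 1 equals the true estimand.
    """
    se_grid = np.asarray(se_grid, dtype=float)
    sp_grid = np.asarray(sp_grid, dtype=float)
    for grid, name in ((se_grid, "se_grid"), (sp_grid, "sp_grid")):
        if grid.size == 0 or np.any((grid < 0) | (grid > 1)):
            raise ParameterError(f"{name} values must lie in [0, 1] and be non-empty")
    if estimand not in ("incidence", "risk_ratio"):
        raise ParameterError(f"unknown estimand {estimand!r}")

    surface = np.empty((se_grid.size, sp_grid.size))
    if estimand == "incidence":
        for i, se in enumerate(se_grid):
            for j, sp in enumerate(sp_grid):
                surface[i, j] = expected_apparent_incidence(variant, p, incidence, se, sp)
        return surface
    pi = exposure_prevalence
    inc_unexposed = incidence / (1.0 - pi + pi * true_rr)
    inc_exposed = inc_unexposed * true_rr
    for i, se in enumerate(se_grid):
        for j, sp in enumerate(sp_grid):
            surface[i, j] = expected_apparent_rr(
                variant, p, inc_unexposed, inc_exposed, se, sp, pi
            )
    return surface
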