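"""Cohort replicate generation.

A replicate is a closed cohort of ``n_subjects`` observed at two sampling
points one time unit apart.  Each subject carries a binary exposure E, a
true disease status at baseline (D1) and at follow-up (D2), and the results
of an imperfect diagnostic test applied at both points (T1, T2).

Generative model
----------------
* E ~ Bernoulli(pi_E), i.i.d.
* D1 ~ Bernoulli(p), independent of E (baseline disease is not associated
  with exposure by default).
* Disease persists: D1 = 1 implies D2 = 1 ("no elimination of disease"
  over the single inter-sample interval).
* Among subjects truly at risk (D1 = 0), incident disease over the interval
  follows Bernoulli(I_u * RR**E), where I_u is the unexposed incidence
  back-solved so that the exposure-marginal incidence equals the scenario's
  ``incidence``:  I = pi_E * I_e + (1 - pi_E) * I_u  with  I_e = I_u * RR.
* Test errors are non-differential and conditionally independent given true
  status, across subjects and across the two sampling points:
  P(T = 1 | D = 1) = Se,  P(T = 1 | D = 0) = 1 - Sp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["Scenario", "Cohort", "apply_test", "simulate_cohort", "simulate_true_statuses"]


def _check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class Scenario:
    """Full parameter set for one simulated disease / test / exposure context.

    Parameters
    ----------
    prevalence
        True baseline disease prevalence p.
    incidence
        True one-interval incidence I among truly at-risk subjects,
        marginal over exposure (cases per animal-time unit, one unit of
        follow-up).
    true_rr
        True risk ratio of incident disease, exposed vs unexposed.
    exposure_prevalence
        P(E = 1).  The hypothetical-exposure default of 0.5 splits the
        cohort evenly.
    se, sp
        Sensitivity and specificity of the diagnostic test, identical at
        baseline and follow-up.
    n_subjects, n_replicates
        Cohort size and number of Monte-Carlo replicates.
    seed
        Seed for the default random stream when none is supplied.
    """

    prevalence: float
    incidence: float
    true_rr: float = 3.0
    exposure_prevalence: float = 0.5
    se: float = 1.0
    sp: float = 1.0
    n_subjects: int = 1000
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "incidence", "exposure_prevalence", "se", "sp"):
            _check_probability(name, getattr(self, name))
        if self.true_rr <= 0:
            raise ParameterError(f"true_rr must be positive, got {self.true_rr!r}")
        if self.n_subjects < 1:
            raise ParameterError(f"n_subjects must be >= 1, got {self.n_subjects!r}")
        if self.n_replicates < 1:
            raise ParameterError(f"n_replicates must be >= 1, got {self.n_replicates!r}")
        if self.incidence_exposed > 1.0:
            raise ParameterError(
                "infeasible scenario: exposed incidence "
                f"I_u * true_rr = {self.incidence_exposed:.4g} exceeds 1 "
                f"(incidence={self.incidence}, true_rr={self.true_rr}, "
                f"exposure_prevalence={self.exposure_prevalence})"
            )

    @property
    def incidence_unexposed(self) -> float:
        """Unexposed incidence I_u such that the exposure-marginal incidence is I."""
        pi = self.exposure_prevalence
        return self.incidence / (1.0 - pi + pi * self.true_rr)

    @property
    def incidence_exposed(self) -> float:
        """Exposed incidence I_e = I_u * RR."""
        return self.incidence_unexposed * self.true_rr


@dataclass
class Cohort:
    """Per-subject vectors for one simulated replicate.

    All vectors are boolean arrays of the same length.  ``disease_baseline``
    and ``disease_followup`` are the true statuses at the two sampling
    points; ``test_baseline`` and ``test_followup`` the corresponding
    imperfect test results.
    """

    exposure: np.ndarray
    disease_baseline: np.ndarray
    disease_followup: np.ndarray
    test_baseline: np.ndarray
    test_followup: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        arrays = {
            "exposure": self.exposure,
            "disease_baseline": self.disease_baseline,
            "disease_followup": self.disease_followup,
            "test_baseline": self.test_baseline,
            "test_followup": self.test_followup,
        }
        for name, arr in arrays.items():
            setattr(self, name, np.asarray(arr, dtype=bool))
        if not self.validate:
            return
        n = self.exposure.shape[0]
        for name, arr in arrays.items():
            arr = getattr(self, name)
            if arr.ndim != 1 or arr.shape[0] != n:
                raise ParameterError(f"{name} must be a 1-d vector of length {n}")
        if np.any(self.disease_baseline & ~self.disease_followup):
            raise ParameterError(
                "disease persistence violated: a baseline case is disease-free at follow-up"
            )

    @property
    def n_subjects(self) -> int:
        return self.exposure.shape[0]


def apply_test(
    true_status: np.ndarray, se: float, sp: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply an imperfect diagnostic test to a vector of true statuses.

    Each subject's result is drawn independently: positive with probability
    ``se`` if truly diseased, with probability ``1 - sp`` otherwise.
    """
    _check_probability("se", se)
    _check_probability("sp", sp)
    status = np.asarray(true_status)
    if status.dtype != bool and not np.isin(status, (0, 1)).all():
        raise ParameterError("true_status must be a binary vector")
    status = status.astype(bool)
    p_positive = np.where(status, se, 1.0 - sp)
    return rng.random(status.shape) < p_positive


def simulate_true_statuses(
    scenario: Scenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (exposure, disease_baseline, disease_followup) for one replicate.

    Draw order is fixed (E, D1, incident disease) so that a given generator
    state always yields the same true cohort regardless of which test
    parameters are applied afterwards.
    """
    n = scenario.n_subjects
    exposure = rng.random(n) < scenario.exposure_prevalence
    disease_baseline = rng.random(n) < scenario.prevalence
    p_incident = np.where(
        exposure, scenario.incidence_exposed, scenario.incidence_unexposed
    )
    incident = rng.random(n) < p_incident
    disease_followup = disease_baseline | incident
    return exposure, disease_baseline, disease_followup


def simulate_cohort(scenario: Scenario, rng: np.random.Generator | None = None) -> Cohort:
    """Simulate one full cohort replicate, including both test applications."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    exposure, d1, d2 = simulate_true_statuses(scenario, rng)
    t1 = apply_test(d1, scenario.se, scenario.sp, rng)
    t2 = apply_test(d2, scenario.se, scenario.sp, rng)
    return Cohort(exposure, d1, d2, t1, t2, validate=False)
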