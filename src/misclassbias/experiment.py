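"""Factorial study orchestration and replicate summaries.

The default grid reproduces the study design: two baseline prevalences
(5%, 20%) x three incidences (0.01, 0.05, 0.1) define six disease
contexts, each crossed with 9 sensitivity and 7 specificity values
(378 cells); 1,000 cohorts of 1,000 subjects per context.

Within a context the true cohorts (exposure and true statuses) are shared
across all (se, sp) cells and only the test errors are re-drawn per cell,
via a pair of per-subject uniforms thresholded at the cell's operating
characteristics.  Each cell's test results therefore have exactly the
required Bernoulli margins while cells are positively correlated across
the grid — a common-random-numbers scheme that sharpens between-cell
comparisons at no extra cost.  Set ``share_true_cohorts=False`` to draw
fully independent replicates per cell instead.

Randomness is organised as one master seed per run with per-(context,
replicate) substreams spawned deterministically, so any single replicate
is reproducible in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .analytic import expected_apparent_incidence, expected_apparent_rr
from .errors import ParameterError
from .estimation import VARIANTS, BiasEstimates, analyze_cohort
from .simulate import Cohort, Scenario, simulate_cohort, simulate_true_statuses

__all__ = ["GridSpec", "run_grid", "run_scenario", "summarize_replicates"]

logger = logging.getLogger(__name__)

_DEFAULT_SE = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1.0)
_DEFAULT_SP = (0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Full factorial design: disease contexts x test operating points."""

    prevalences: tuple[float, ...] = (0.05, 0.20)
    incidences: tuple[float, ...] = (0.01, 0.05, 0.1)
    se_values: tuple[float, ...] = _DEFAULT_SE
    sp_values: tuple[float, ...] = _DEFAULT_SP
    true_rr: float = 3.0
    exposure_prevalence: float = 0.5
    n_subjects: int = 1000
    n_replicates: int = 1000
    master_seed: int = 0
    share_true_cohorts: bool = True

    def __post_init__(self) -> None:
        for name in ("prevalences", "incidences", "se_values", "sp_values"):
            values = getattr(self, name)
            object.__setattr__(self, name, tuple(float(v) for v in values))
            if not values:
                raise ParameterError(f"{name} must be non-empty")
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ParameterError(f"all {name} must lie in [0, 1]")
        if self.true_rr <= 0:
            raise ParameterError(f"true_rr must be positive, got {self.true_rr!r}")
        if not 0.0 <= self.exposure_prevalence <= 1.0:
            raise ParameterError("exposure_prevalence must be a probability in [0, 1]")
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ParameterError("n_subjects and n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        """Number of (context x se x sp) grid cells."""
        return (
            len(self.prevalences)
            * len(self.incidences)
            * len(self.se_values)
            * len(self.sp_values)
        )


def _replicate_rng(master_seed: int, context_index: int, replicate: int) -> np.random.Generator:
    """Deterministic substream for one replicate of one disease context."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(context_index, replicate))
    )


def summarize_replicates(estimates: Sequence[BiasEstimates]) -> dict[str, dict[str, float]]:
    """Median and quartiles of apparent incidence and RR, per variant.

    Inestimable risk ratios (NaN) are excluded from the RR quantiles and
    counted in ``n_missing_rr``; if every replicate's RR is missing the RR
    quantiles are NaN and ``rr_available`` is False.  Quantiles use linear
    interpolation between order statistics.
    """
    if not estimates:
        raise ParameterError("summarize_replicates requires at least one replicate")
    summary: dict[str, dict[str, float]] = {}
    for variant in VARIANTS:
        inc = np.array([e[variant].apparent_incidence for e in estimates])
        rr = np.array([e[variant].apparent_rr for e in estimates])
        rr_ok = rr[~np.isnan(rr)]
        row: dict[str, float] = {}
        inc_ok = inc[~np.isnan(inc)]
        if inc_ok.size:
            row["inc_q1"], row["inc_median"], row["inc_q3"] = np.percentile(
                inc_ok, [25, 50, 75]
            )
            row["inc_mean"] = float(inc_ok.mean())
            row["inc_sem"] = (
                float(inc_ok.std(ddof=1) / math.sqrt(inc_ok.size)) if inc_ok.size > 1 else math.nan
            )
        else:
            row["inc_q1"] = row["inc_median"] = row["inc_q3"] = math.nan
            row["inc_mean"] = row["inc_sem"] = math.nan
        if rr_ok.size:
            row["rr_q1"], row["rr_median"], row["rr_q3"] = np.percentile(rr_ok, [25, 50, 75])
        else:
            row["rr_q1"] = row["rr_median"] = row["rr_q3"] = math.nan
        row["n_missing_rr"] = int(np.isnan(rr).sum())
        row["rr_available"] = bool(rr_ok.size)
        summary[variant] = row
    return summary


def _analyze_cell(
    exposure: np.ndarray,
    d1: np.ndarray,
    d2: np.ndarray,
    u1: np.ndarray,
    u2: np.ndarray,
    se: float,
    sp: float,
) -> BiasEstimates:
    """Apply a (se, sp) operating point via shared uniforms and estimate."""
    t1 = u1 < np.where(d1, se, 1.0 - sp)
    t2 = u2 < np.where(d2, se, 1.0 - sp)
    cohort = Cohort(exposure, d1, d2, t1, t2, validate=False)
    return analyze_cohort(cohort)


def run_grid(grid: GridSpec) -> pd.DataFrame:
    """Run the full factorial study and summarize replicate distributions.

    Returns one row per (prevalence, incidence, se, sp, variant) holding
    Monte-Carlo medians/quartiles of apparent incidence and RR, the count
    of inestimable RRs, and the closed-form expectations.  Deterministic
    given ``master_seed``.
    """
    rows: list[dict] = []
    context_index = -1
    for p in grid.prevalences:
        for inc in grid.incidences:
            context_index += 1
            try:
                scenario = Scenario(
                    prevalence=p,
                    incidence=inc,
                    true_rr=grid.true_rr,
                    exposure_prevalence=grid.exposure_prevalence,
                    n_subjects=grid.n_subjects,
                    n_replicates=grid.n_replicates,
                )
            except ParameterError as exc:
                logger.warning("skipping infeasible context p=%s, I=%s: %s", p, inc, exc)
                continue
            rows.extend(_run_context(grid, scenario, context_index))
    if not rows:
        raise ParameterError("no feasible disease context in the grid")
    return pd.DataFrame(rows)


def _run_context(grid: GridSpec, scenario: Scenario, context_index: int) -> list[dict]:
    cells = [(se, sp) for se in grid.se_values for sp in grid.sp_values]
    per_cell: list[list[BiasEstimates]] = [[] for _ in cells]
    for rep in range(grid.n_replicates):
        rng = _replicate_rng(grid.master_seed, context_index, rep)
        if grid.share_true_cohorts:
            exposure, d1, d2 = simulate_true_statuses(scenario, rng)
            u1 = rng.random(scenario.n_subjects)
            u2 = rng.random(scenario.n_subjects)
            for k, (se, sp) in enumerate(cells):
                per_cell[k].append(_analyze_cell(exposure, d1, d2, u1, u2, se, sp))
        else:
            for k, (se, sp) in enumerate(cells):
                cell_scenario = Scenario(
                    prevalence=scenario.prevalence,
                    incidence=scenario.incidence,
                    true_rr=scenario.true_rr,
                    exposure_prevalence=scenario.exposure_prevalence,
                    se=se,
                    sp=sp,
                    n_subjects=scenario.n_subjects,
                    n_replicates=scenario.n_replicates,
                )
                cell_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        grid.master_seed, spawn_key=(context_index, rep, k)
                    )
                )
                per_cell[k].append(analyze_cohort(simulate_cohort(cell_scenario, cell_rng)))

    rows = []
    for k, (se, sp) in enumerate(cells):
        summary = summarize_replicates(per_cell[k])
        for variant in VARIANTS:
            row = {
                "prevalence": scenario.prevalence,
                "incidence": scenario.incidence,
                "true_rr": scenario.true_rr,
                "exposure_prevalence": scenario.exposure_prevalence,
                "n_subjects": scenario.n_subjects,
                "n_replicates": grid.n_replicates,
                "se": se,
                "sp": sp,
                "variant": variant,
            }
            row.update(
                {key: val for key, val in summary[variant].items() if key != "rr_available"}
            )
            row["expected_incidence"] = expected_apparent_incidence(
                variant, scenario.prevalence, scenario.incidence, se, sp
            )
            row["expected_rr"] = expected_apparent_rr(
                variant,
                scenario.prevalence,
                scenario.incidence_unexposed,
                scenario.incidence_exposed,
                se,
                sp,
                scenario.exposure_prevalence,
            )
            rows.append(row)
    return rows


def run_scenario(scenario: Scenario, master_seed: int | None = None) -> pd.DataFrame:
    """Per-replicate apparent estimates for a single scenario.

    Returns one row per (replicate, variant).  ``master_seed`` defaults to
    the scenario's own seed.
    """
    seed = scenario.seed if master_seed is None else master_seed
    rows = []
    for rep in range(scenario.n_replicates):
        rng = _replicate_rng(seed, 0, rep)
        estimates = analyze_cohort(simulate_cohort(scenario, rng))
        for variant in VARIANTS:
            est = estimates[variant]
            rows.append(
                {
                    "replicate": rep,
                    "variant": variant,
                    "apparent_incidence": est.apparent_incidence,
                    "apparent_rr": est.apparent_rr,
                    "at_risk_n": est.at_risk_n,
                }
            )
    return pd.DataFrame(rows)
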