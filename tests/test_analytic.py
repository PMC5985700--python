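"""Closed-form expectations: worked values, limits, monotonicity, MC agreement."""

import itertools

import numpy as np
import pytest

from misclassbias import (
    ParameterError,
    Scenario,
    analyze_cohort,
    contour_surface,
    expected_apparent_incidence,
    expected_apparent_rr,
    expected_estimates,
    simulate_cohort,
)
from misclassbias.experiment import _replicate_rng

from conftest import MASTER_SEED

SE_GRID = (0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1.0)
SP_GRID = (0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1.0)
CONTEXTS = tuple(itertools.product((0.05, 0.20), (0.01, 0.05, 0.1)))


@pytest.mark.parametrize(
    "p, incidence, se, sp, expected, contour_label",
    [
        (0.05, 0.1, 0.7, 0.845, 0.21850, 0.22),
        (0.05, 0.1, 1.0, 0.87, 0.21700, 0.22),
        (0.20, 0.01, 0.955, 1.0, 0.02007, 0.02),
    ],
)
def test_total_bias_worked_contour_points(p, incidence, se, sp, expected, contour_label):
    """Published contour-line crossings of the total-bias incidence surface."""
    value = expected_apparent_incidence("total", p, incidence, se, sp)
    assert value == pytest.approx(expected, abs=5e-5)
    assert round(value, 2) == contour_label


@pytest.mark.parametrize("variant", ["total", "selection_only", "misclassification_only"])
def test_perfect_test_recovers_true_incidence(variant):
    assert expected_apparent_incidence(variant, 0.2, 0.07, 1.0, 1.0) == pytest.approx(0.07)


def test_perfect_test_recovers_true_rr():
    assert expected_apparent_rr("total", 0.05, 0.05, 0.15, 1.0, 1.0) == pytest.approx(3.0)


def test_misclassification_only_unbiased_rr_at_perfect_specificity():
    """With Sp = 1 the false-positive channel is closed and RR bias is absent."""
    for se in SE_GRID:
        rr = expected_apparent_rr("misclassification_only", 0.05, 0.05, 0.15, se, 1.0)
        assert rr == pytest.approx(3.0, abs=1e-12)


def test_total_bias_rr_plugin_value():
    rr = expected_apparent_rr("total", 0.05, 0.05, 0.15, 0.9, 0.95)
    assert rr == pytest.approx(1.872, abs=1e-3)


def test_misclassification_only_matches_total_at_zero_prevalence():
    """With no prevalent disease, selection plays no role and the formulas agree."""
    for se, sp in itertools.product(SE_GRID, SP_GRID):
        total = expected_apparent_incidence("total", 0.0, 0.05, se, sp)
        mis = expected_apparent_incidence("misclassification_only", 0.0, 0.05, se, sp)
        assert total == pytest.approx(mis, abs=1e-12)


def test_misclassification_only_incidence_decreasing_in_sp():
    for se in SE_GRID:
        values = [
            expected_apparent_incidence("misclassification_only", 0.05, 0.1, se, sp)
            for sp in SP_GRID
        ]
        assert all(x > y for x, y in zip(values, values[1:]))


def test_misclassification_only_incidence_affine_in_incidence():
    """Three-point collinearity in I at fixed test characteristics."""
    points = [
        expected_apparent_incidence("misclassification_only", 0.05, i, 0.8, 0.9)
        for i in (0.0, 0.1, 0.2)
    ]
    assert points[1] - points[0] == pytest.approx(points[2] - points[1], abs=1e-12)


def test_total_rr_attenuated_toward_null_across_full_grid():
    """Non-differential errors with D1 independent of E keep RR in [1, RR_true]."""
    for (p, inc), se, sp in itertools.product(CONTEXTS, SE_GRID, SP_GRID):
        scenario = Scenario(prevalence=p, incidence=inc, true_rr=3.0)
        rr = expected_apparent_rr(
            "total", p, scenario.incidence_unexposed, scenario.incidence_exposed, se, sp
        )
        assert 1.0 - 1e-9 <= rr <= 3.0 + 1e-9


def test_selection_only_expected_incidence_never_below_truth():
    """Baseline false negatives are persistent cases, inflating apparent incidence."""
    for (p, inc), se, sp in itertools.product(CONTEXTS, SE_GRID, SP_GRID):
        value = expected_apparent_incidence("selection_only", p, inc, se, sp)
        assert value >= inc - 1e-12


def test_degenerate_at_risk_set_raises():
    with pytest.raises(ParameterError, match="degenerate"):
        expected_apparent_incidence("total", 1.0, 0.1, 1.0, 0.9)


def test_unknown_variant_rejected():
    with pytest.raises(ParameterError, match="variant"):
        expected_apparent_incidence("bogus", 0.1, 0.1, 0.9, 0.9)


class TestContourSurface:
    def test_corner_equals_true_estimand(self):
        surface = contour_surface("total", 0.05, 0.1, np.array(SE_GRID), np.array(SP_GRID))
        assert surface[-1, -1] == pytest.approx(0.1)
        rr_surface = contour_surface(
            "total", 0.05, 0.1, np.array(SE_GRID), np.array(SP_GRID), "risk_ratio"
        )
        assert rr_surface[-1, -1] == pytest.approx(3.0)

    def test_published_level_set_crossings(self):
        """The 0.22 contour of the (p=0.05, I=0.1) surface passes through both
        published (se, sp) combinations."""
        se_grid = np.array([0.7, 1.0])
        sp_grid = np.array([0.845, 0.87])
        surface = contour_surface("total", 0.05, 0.1, se_grid, sp_grid)
        assert round(surface[0, 0], 2) == 0.22  # se=0.7, sp=0.845
        assert round(surface[1, 1], 2) == 0.22  # se=1.0, sp=0.87

    def test_invalid_grid_rejected(self):
        with pytest.raises(ParameterError, match="se_grid"):
            contour_surface("total", 0.05, 0.1, np.array([1.2]), np.array([0.9]))


class TestMonteCarloAgreement:
    """The closed forms are oracles only if the simulator converges on them."""

    @pytest.mark.parametrize(
        "p, incidence, se, sp",
        [
            (0.05, 0.1, 0.7, 0.845),
            (0.20, 0.05, 0.9, 0.9),
            (0.05, 0.01, 0.95, 0.98),
        ],
    )
    def test_mean_apparent_incidence_within_four_se(self, p, incidence, se, sp):
        n_replicates = 300
        scenario = Scenario(
            prevalence=p, incidence=incidence, se=se, sp=sp, n_subjects=1000
        )
        sums = {v: [] for v in ("total", "selection_only", "misclassification_only")}
        for rep in range(n_replicates):
            cohort = simulate_cohort(scenario, _replicate_rng(MASTER_SEED, 0, rep))
            for variant, est in analyze_cohort(cohort).items():
                sums[variant].append(est.apparent_incidence)
        for variant, values in sums.items():
            values = np.array(values)
            expected = expected_apparent_incidence(variant, p, incidence, se, sp)
            sem = values.std(ddof=1) / np.sqrt(n_replicates)
            assert abs(values.mean() - expected) < 4 * sem

    def test_median_rr_tracks_expected_rr(self):
        scenario = Scenario(prevalence=0.05, incidence=0.1, se=0.9, sp=0.95, n_subjects=1000)
        rrs = []
        for rep in range(300):
            cohort = simulate_cohort(scenario, _replicate_rng(MASTER_SEED, 1, rep))
            rrs.append(analyze_cohort(cohort)["total"].apparent_rr)
        rrs = np.array(rrs)
        expected = expected_estimates(scenario, "total").expected_apparent_rr
        # log-scale comparison; median of ~300 log-RRs has SE ~ 1.25*sd/sqrt(n)
        log_rr = np.log(rrs[~np.isnan(rrs)])
        sem_median = 1.2533 * log_rr.std(ddof=1) / np.sqrt(log_rr.size)
        assert abs(np.median(log_rr) - np.log(expected)) < 4 * sem_median
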