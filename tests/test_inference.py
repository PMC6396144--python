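"""Hypothesis fitting, feasibility verdicts and bootstrap intervals."""

import numpy as np
import pytest

from tafsim.inference import (
    ObservedTrajectory,
    bootstrap_ci,
    compare_models,
    fit_proliferation,
    fit_stress,
    observed_from_cohort,
)
from tafsim.models import ModelSpec, delta_from_lifetime_fraction
from tafsim.synthetic import CohortDesign, generate_cohort


def _obs_from_lines(ages, means_by_age, fracs_by_age, n_mice=5):
    return ObservedTrajectory(
        ages=np.asarray(ages, dtype=float),
        mouse_mean_taf={
            float(a): np.full(n_mice, m) for a, m in zip(ages, means_by_age)
        },
        mouse_frac_positive={
            float(a): np.full(n_mice, f) for a, f in zip(ages, fracs_by_age)
        },
        cells_per_mouse=100.0,
        horizon_months=27.0,
    )


class TestFitStress:
    def test_noiseless_line_recovered_exactly(self):
        ages = [3.0, 15.0, 22.0, 30.0]
        means = [0.1 + 0.05 * a for a in ages]
        fracs = [1 - np.exp(-m) for m in means]
        fit = fit_stress(_obs_from_lines(ages, means, fracs))
        assert fit.estimates["lambda_T"] == pytest.approx(0.05, rel=1e-9)
        assert fit.estimates["initial_mean_taf"] == pytest.approx(0.1, rel=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_flat_observations_zero_slope(self):
        fit = fit_stress(_obs_from_lines([3.0, 30.0], [0.4, 0.4], [0.3, 0.3]))
        assert fit.estimates["lambda_T"] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_age_rejected(self):
        with pytest.raises(ValueError):
            ObservedTrajectory(
                ages=np.array([3.0]),
                mouse_mean_taf={3.0: np.array([0.1])},
                mouse_frac_positive={3.0: np.array([0.1])},
                cells_per_mouse=100.0,
            )

    def test_slope_matches_statsmodels_ols(self, stress_cohort):
        sm = pytest.importorskip("statsmodels.api")
        obs = observed_from_cohort(stress_cohort)
        ages, means, _ = obs.flat()
        ref = sm.OLS(means, sm.add_constant(ages)).fit()
        fit = fit_stress(obs)
        assert fit.estimates["lambda_T"] == pytest.approx(ref.params[1], rel=1e-9)
        assert fit.estimates["initial_mean_taf"] == pytest.approx(
            max(ref.params[0], 0.0), rel=1e-9
        )

    def test_parameter_recovery_on_synthetic_cohorts(self, stress_model):
        errs = []
        for seed in range(60):
            cohort = generate_cohort(CohortDesign(seed=seed), stress_model)
            fit = fit_stress(observed_from_cohort(cohort))
            errs.append(abs(fit.estimates["lambda_T"] - 0.05) / 0.05)
        assert np.median(errs) <= 0.10


class TestFitProliferation:
    def test_high_positive_fraction_is_infeasible(self):
        # 60% positive at 30 months cannot come from <=15% lifetime division
        ages = [3.0, 15.0, 22.0, 30.0]
        obs = _obs_from_lines(ages, [0.1, 0.5, 0.75, 1.0],
                              [0.09, 0.35, 0.5, 0.60])
        fit = fit_proliferation(obs)
        assert not fit.feasible
        assert "exceeds" in fit.constraint_note

    def test_self_consistency_within_bounds(self):
        delta = delta_from_lifetime_fraction(0.10, 27.0)
        model = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=3.0,
                          horizon_months=30.0)
        cohort = generate_cohort(
            CohortDesign(cells_per_mouse=400, seed=11), model
        )
        fit = fit_proliferation(observed_from_cohort(cohort))
        assert fit.feasible
        assert 0.04 <= fit.estimates["lifetime_division_fraction"] <= 0.15

    def test_all_zero_observations(self):
        obs = _obs_from_lines([3.0, 30.0], [0.0, 0.0], [0.0, 0.0])
        fit = fit_proliferation(obs)
        assert fit.estimates["mu_d"] == pytest.approx(0.0, abs=1e-6)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_invalid_bounds_rejected(self):
        obs = _obs_from_lines([3.0, 30.0], [0.1, 0.5], [0.1, 0.3])
        with pytest.raises(ValueError):
            fit_proliferation(obs, (0.2, 0.1))


class TestCompareModels:
    def test_stress_cohort_yields_stress_verdict(self):
        # lambda_T tuned so ~60% of cells are TAF-positive at 30 months
        model = ModelSpec(mechanism="stress", lambda_T=0.0305,
                          horizon_months=30.0)
        cohort = generate_cohort(CohortDesign(seed=21), model)
        cmp_ = compare_models(observed_from_cohort(cohort))
        assert cmp_.verdict == "stress"
        assert cmp_.fits["stress"].pearson_r >= 0.95
        assert not cmp_.fits["proliferation"].feasible

    def test_proliferation_cohort_yields_proliferation_verdict(self):
        delta = delta_from_lifetime_fraction(0.10, 27.0)
        model = ModelSpec(mechanism="proliferation", delta_c=delta, mu_d=3.0,
                          horizon_months=30.0)
        cohort = generate_cohort(
            CohortDesign(cells_per_mouse=400, seed=31), model
        )
        cmp_ = compare_models(observed_from_cohort(cohort))
        assert cmp_.verdict == "proliferation"

    def test_empty_cohort_rejected(self):
        from tafsim.synthetic import CohortDataset

        with pytest.raises(ValueError):
            CohortDataset([], "external", 0)


class TestBootstrap:
    def test_noiseless_data_degenerate_interval(self):
        ages = [3.0, 15.0, 22.0, 30.0]
        means = [0.1 + 0.05 * a for a in ages]
        fracs = [float(1 - np.exp(-m)) for m in means]
        ci = bootstrap_ci(_obs_from_lines(ages, means, fracs), "stress",
                          n_boot=100, seed=0)
        lo, hi = ci["lambda_T"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_intervals(self, stress_cohort):
        obs = observed_from_cohort(stress_cohort)
        a = bootstrap_ci(obs, "stress", n_boot=150, seed=5)
        b = bootstrap_ci(obs, "stress", n_boot=150, seed=5)
        assert a == b

    def test_interval_contains_point_estimate(self, stress_cohort):
        obs = observed_from_cohort(stress_cohort)
        fit = fit_stress(obs)
        ci = bootstrap_ci(obs, "stress", n_boot=150, seed=9)
        for k, (lo, hi) in ci.items():
            assert lo <= fit.estimates[k] <= hi

    def test_too_few_replicates_rejected(self, stress_cohort):
        with pytest.raises(ValueError):
            bootstrap_ci(observed_from_cohort(stress_cohort), "stress",
                         n_boot=10, seed=0)
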