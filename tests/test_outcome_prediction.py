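import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sbpcourse as sc


def _frame(values, name="x"):
    return pd.DataFrame({name: values}, index=pd.Index([f"p{i}" for i in range(len(values))], name="patient_id"))


def _labels(values):
    return pd.Series(
        np.asarray(values, dtype=float),
        index=pd.Index([f"p{i}" for i in range(len(values))], name="patient_id"),
    )


class TestComputeAuc:
    def test_perfect_separation(self):
        assert sc.compute_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert sc.compute_auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_enumeration_example(self):
        """Frozen value from exhaustive pair enumeration with 1/2 per tie."""
        scores = [3, 1, 2, 4, 2]
        labels = [1, 0, 0, 1, 1]
        # positives (3, 4, 2) vs negatives (1, 2): pairs -> 1+1 + 1+1 + 1+0.5 = 5.5 of 6
        assert sc.compute_auc(scores, labels) == pytest.approx(5.5 / 6)
        assert sc.compute_auc(scores, labels) == pytest.approx(
            sc.pairwise_auc_oracle(scores, labels)
        )

    def test_agrees_with_pairwise_oracle_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert sc.compute_auc(scores, labels) == pytest.approx(
                sc.pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="both classes"):
            sc.compute_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=4, max_size=30),
        st.floats(-5, 5),
    )
    def test_invariant_under_increasing_transform(self, scores, shift):
        labels = np.tile([0, 1], len(scores))[: len(scores)]
        scores = np.asarray(scores, dtype=float)
        base = sc.compute_auc(scores, labels)
        transformed = sc.compute_auc(np.exp(scores / 300.0) + shift, labels)
        assert transformed == pytest.approx(base, abs=1e-12)


class TestFitOutcomeModel:
    def test_null_predictor_or_near_one(self):
        """Oracle: independence implies OR -> 1."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = rng.integers(0, 2, 2000)
        fit = sc.fit_outcome_model(None, _frame(x), _labels(y))
        i = fit.coefficient_names.index("x")
        assert 0.9 <= fit.odds_ratios[i] <= 1.1

    def test_two_by_two_odds_ratio(self):
        """Oracle: logistic ML on a 2x2 table equals ad/bc.

        Counts a=10, b=20, c=5, d=40 give (10*40)/(20*5) = 4.0.
        """
        x = [1] * 30 + [0] * 45
        y = [1] * 10 + [0] * 20 + [1] * 5 + [0] * 40
        fit = sc.fit_outcome_model(None, _frame(x), _labels(y))
        i = fit.coefficient_names.index("x")
        assert fit.odds_ratios[i] == pytest.approx(4.0, rel=1e-4)

    def test_or_equals_exp_coefficient(self):
        rng = np.random.default_rng(3)
        fit = sc.fit_outcome_model(
            None, _frame(rng.standard_normal(100)), _labels(rng.integers(0, 2, 100))
        )
        assert np.allclose(fit.odds_ratios, np.exp(fit.coefficients))

    def test_duplicated_column_identity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(120)
        y = (x + rng.standard_normal(120) > 0).astype(int)
        base = sc.fit_outcome_model(None, _frame(x), _labels(y))
        df = _frame(x)
        df["x_copy"] = df["x"]
        df = df.drop(columns="x_copy")
        again = sc.fit_outcome_model(None, df, _labels(y))
        assert np.array_equal(base.coefficients, again.coefficients)

    def test_separation_names_column(self):
        x = np.concatenate([np.ones(15), -np.ones(15)])
        other = np.tile([0.0, 1.0], 15)
        y = (x > 0).astype(int)
        df = _frame(x)
        df["other"] = other
        with pytest.raises(sc.SeparationError, match="'x'") as exc_info:
            sc.fit_outcome_model(None, df, _labels(y))
        assert exc_info.value.column == "x"

    def test_rejects_too_few_events(self):
        y = [1] * 5 + [0] * 50
        with pytest.raises(ValueError, match="10 events"):
            sc.fit_outcome_model(None, _frame(np.random.default_rng(0).standard_normal(55)), _labels(y))

    def test_listwise_deletion(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(100)
        y = rng.integers(0, 2, 100).astype(float)
        y[:7] = np.nan
        fit = sc.fit_outcome_model(None, _frame(x), _labels(y))
        assert fit.n_used == 93


class TestCohortProportions:
    def _cohort(self, n_favourable, n_total, outcome="functional_independence"):
        cohort = []
        for i in range(n_total):
            cohort.append(
                sc.PatientRecord(
                    patient_id=f"p{i}", times=[0.0], sbp=[130.0], age=70.0, sex=1,
                    nihss_baseline=10.0, hypertension=0, mtici_success=1,
                    outcomes={outcome: 1 if i < n_favourable else 0},
                )
            )
        return cohort

    def test_functional_independence_headline(self):
        assert sc.cohort_proportions(self._cohort(169, 374), "functional_independence") == 45.2

    def test_no_sich_headline(self):
        assert sc.cohort_proportions(self._cohort(354, 374), "functional_independence") == 94.7

    def test_zero_favourable(self):
        assert sc.cohort_proportions(self._cohort(0, 50), "functional_independence") == 0.0

    def test_missing_labels_count_in_denominator(self):
        cohort = self._cohort(10, 20)
        cohort[-1].outcomes["functional_independence"] = None
        assert sc.cohort_proportions(cohort, "functional_independence") == 50.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sc.cohort_proportions([], "alive")


@pytest.fixture(scope="module")
def signal_cohort():
    """Outcome driven by the trend random effect (correlated with level)."""
    config = sc.SyntheticConfig(
        n_patients=200,
        true_alpha=np.array([130.0, -0.28]),
        true_G=np.array([[100.0, 4.5], [4.5, 0.25]]),
        true_sigma2=64.0,
        outcome_coefficients={
            "functional_independence": sc.OutcomeCoefficients(
                0.0, (0.0, -3.5), {"age": -0.08, "nihss_baseline": -0.06}
            )
        },
        optional_measurement_prob=0.3,
        dropout_prob=0.05,
        seed=2024,
    )
    return sc.generate_cohort(config)


@pytest.fixture(scope="module")
def power_cohort():
    """Trend-driven outcome with *uncorrelated* effects, so the trend
    coefficient is individually identifiable (|beta| * SD(effect) = 1.5)."""
    config = sc.SyntheticConfig(
        n_patients=200,
        true_alpha=np.array([130.0, -0.28]),
        true_G=np.diag([100.0, 0.25]),
        true_sigma2=64.0,
        outcome_coefficients={
            "functional_independence": sc.OutcomeCoefficients(0.0, (0.0, -3.0))
        },
        optional_measurement_prob=0.3,
        dropout_prob=0.05,
        seed=404,
    )
    return sc.generate_cohort(config)


class TestBootstrapPipeline:
    def test_fixed_seed_determinism(self, signal_cohort):
        spec = sc.CourseSpec(1, "functional_independence")
        kwargs = dict(n_iterations=50, seed=17, covariate_names=("age",))
        a = sc.bootstrap_pipeline(signal_cohort, spec, **kwargs)
        b = sc.bootstrap_pipeline(signal_cohort, spec, **kwargs)
        assert np.array_equal(a.samples, b.samples, equal_nan=True)
        assert np.array_equal(a.ci_lower, b.ci_lower)
        assert np.array_equal(a.ci_upper, b.ci_upper)

    def test_identity_resample_reproduces_point_estimates(self, signal_cohort):
        spec = sc.CourseSpec(1, "functional_independence")
        result = sc.bootstrap_pipeline(
            signal_cohort, spec, n_iterations=1, seed=0,
            covariate_names=("age",), _identity_resample=True,
        )
        assert result.n_failed_iterations == 0
        assert np.allclose(result.samples[0], result.point_estimates, atol=1e-8)

    def test_nonzero_effect_ci_excludes_zero(self, power_cohort):
        """Power check: |beta| * SD(effect) = 3.0 * 0.5 > 1 generating signal."""
        spec = sc.CourseSpec(1, "functional_independence")
        result = sc.bootstrap_pipeline(
            power_cohort, spec, n_iterations=200, seed=3, covariate_names=(),
        )
        i = result.coefficient_names.index("effect_1")
        assert result.ci_upper[i] < 0.0  # generating coefficient is negative
        assert not result.flagged

    def test_failed_iteration_accounting(self, signal_cohort):
        result = sc.bootstrap_pipeline(
            signal_cohort, sc.CourseSpec(1, "functional_independence"),
            n_iterations=20, seed=5, covariate_names=(),
        )
        assert 0 <= result.n_failed_iterations <= 20
        assert result.samples.shape == (20, len(result.coefficient_names))


class TestRunScenarios:
    def test_grid_shape(self, signal_cohort):
        results = sc.run_scenarios(
            signal_cohort, degrees=(1, 2, 3), windows=(24, 18, 12, 6),
            outcome_names=("functional_independence",), covariate_names=("age",),
        )
        assert len(results) == 12
        assert {(r.degree, r.window_hours) for r in results} == {
            (d, w) for d in (1, 2, 3) for w in (24, 18, 12, 6)
        }

    def test_windows_subset(self, signal_cohort):
        results = sc.run_scenarios(
            signal_cohort, degrees=(1,), windows=(24,),
            outcome_names=("functional_independence",), covariate_names=(),
        )
        assert len(results) == 1

    def test_24h_cell_matches_direct_run(self, signal_cohort):
        """Consistency: the 24h cell equals an end-to-end run without the grid."""
        results = sc.run_scenarios(
            signal_cohort, degrees=(1,), windows=(24,),
            outcome_names=("functional_independence",), covariate_names=("age",),
        )
        included, _ = sc.apply_inclusion_filter(signal_cohort, sc.WindowFilter.for_window(24))
        course = sc.fit_reference_course(
            sc.select_favourable(included, "functional_independence"),
            sc.CourseSpec(1, "functional_independence"),
        )
        effects = sc.compute_effects_table(included, course)
        eff = effects[["effect_0", "effect_1"]]
        covs = sc.covariates_frame(included, ("age",))
        labels = sc.labels_series(included, "functional_independence")
        fit = sc.fit_outcome_model(eff, covs, labels)
        X = pd.concat([eff, covs], axis=1)
        direct = sc.compute_auc(fit.linear_predictor(X), labels.to_numpy())
        assert results[0].auc == pytest.approx(direct, abs=1e-10)

    def test_zeroed_effects_degrade_to_covariate_auc(self, signal_cohort):
        included, _ = sc.apply_inclusion_filter(signal_cohort, sc.WindowFilter.for_window(24))
        course = sc.fit_reference_course(
            sc.select_favourable(included, "functional_independence"),
            sc.CourseSpec(1, "functional_independence"),
        )
        effects = sc.compute_effects_table(included, course)[["effect_0", "effect_1"]]
        covs = sc.covariates_frame(included, ("age", "nihss_baseline"))
        labels = sc.labels_series(included, "functional_independence")
        y = labels.to_numpy()
        full = sc.fit_outcome_model(effects, covs, labels)
        X_full = pd.concat([effects, covs], axis=1)
        auc_full = sc.compute_auc(full.linear_predictor(X_full), y)
        X_zeroed = X_full.copy()
        X_zeroed[["effect_0", "effect_1"]] = 0.0
        auc_zeroed = sc.compute_auc(full.linear_predictor(X_zeroed), y)
        cov_only = sc.fit_outcome_model(None, covs, labels)
        auc_cov = sc.compute_auc(cov_only.linear_predictor(covs), y)
        assert auc_full > auc_cov + 0.05  # deviations carry the increment
        assert auc_zeroed == pytest.approx(auc_cov, abs=0.03)

    def test_single_class_cell_flagged_missing(self, signal_cohort):
        import dataclasses as dc

        # force one outcome to be constant
        broken = [
            dc.replace(p, outcomes={**p.outcomes, "alive": 1}) for p in signal_cohort
        ]
        results = sc.run_scenarios(
            broken, degrees=(1,), windows=(24,), outcome_names=("alive",),
            covariate_names=(),
        )
        assert results[0].missing
        assert np.isnan(results[0].auc)

    def test_scenario_frame_layout(self, signal_cohort):
        results = sc.run_scenarios(
            signal_cohort, degrees=(1,), windows=(24, 6),
            outcome_names=("functional_independence",), covariate_names=(),
        )
        frame = sc.scenario_frame(results)
        assert list(frame.columns) == [6, 24] or list(frame.columns) == [24, 6]
        assert frame.shape == (1, 2)
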