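"""Surrogate baseline score and logistic fitting, checked against independent
oracles: a hand-rolled IRLS fit, hand dot-products, and recovery of the
generator's true coefficients."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from fraxval import (
    GeneratorConfig,
    ModelSpec,
    MissingInputError,
    SeparationError,
    fit_logistic,
    generate_cohort,
    predict,
    prepare_analysis_columns,
    surrogate_frax_score,
)
from fraxval.scoring import (
    SURROGATE_BMD_WEIGHT,
    SURROGATE_INTERCEPT,
    SURROGATE_WEIGHTS,
    FittedModel,
    build_design_matrix,
)


def reference_record(**overrides) -> pd.Series:
    rec = pd.Series(
        {
            "age": 63.0,
            "bmi": 25.0,
            "prior_fracture_ge55": False,
            "parental_hip_fracture": False,
            "smoking_current": False,
            "glucocorticoid_use": False,
            "rheumatoid_arthritis": False,
            "alcohol_heavy": False,
            "lumbar_spine_bmd": 1.0,
        }
    )
    for k, v in overrides.items():
        rec[k] = v
    return rec


class TestSurrogateScore:
    def test_reference_record_equals_inverse_logit_of_intercept(self):
        assert surrogate_frax_score(reference_record()) == pytest.approx(
            expit(SURROGATE_INTERCEPT), abs=1e-12)

    def test_monotone_increasing_in_age_and_prior_fracture(self):
        s55 = surrogate_frax_score(reference_record(age=55.0))
        s75 = surrogate_frax_score(reference_record(age=75.0))
        assert s75 > s55
        s_frac = surrogate_frax_score(reference_record(prior_fracture_ge55=True))
        assert s_frac > surrogate_frax_score(reference_record())

    def test_decreasing_in_bmd_when_with_bmd(self):
        low = surrogate_frax_score(reference_record(lumbar_spine_bmd=0.7), with_bmd=True)
        high = surrogate_frax_score(reference_record(lumbar_spine_bmd=1.3), with_bmd=True)
        assert low > high

    def test_missing_input_error_names_field(self):
        rec = reference_record()
        rec["bmi"] = pd.NA
        with pytest.raises(MissingInputError, match="bmi"):
            surrogate_frax_score(rec)
        with pytest.raises(MissingInputError, match="lumbar_spine_bmd"):
            surrogate_frax_score(reference_record().drop("lumbar_spine_bmd"),
                                 with_bmd=True)

    def test_matches_direct_tabulation_on_cohort(self, uncensored_cohort):
        """Vectorized score equals a row-by-row recomputation of the published
        surrogate formula, including the high-risk (>=20%) fraction."""
        frame = uncensored_cohort.head(5_000)
        scored = surrogate_frax_score(frame)
        ref = {"age": 63.0, "bmi": 25.0}
        lp = np.full(len(frame), SURROGATE_INTERCEPT)
        for name, w in SURROGATE_WEIGHTS.items():
            lp = lp + w * (frame[name].to_numpy(dtype=float) - ref.get(name, 0.0))
        oracle = expit(lp)
        np.testing.assert_allclose(scored, oracle, atol=1e-12)
        assert (scored >= 0.20).mean() == (oracle >= 0.20).mean()

    def test_with_bmd_shifts_by_bmd_weight(self):
        rec = reference_record(lumbar_spine_bmd=0.8)
        with_bmd = surrogate_frax_score(rec, with_bmd=True)
        expected = expit(SURROGATE_INTERCEPT + SURROGATE_BMD_WEIGHT * (0.8 - 1.0))
        assert with_bmd == pytest.approx(expected, abs=1e-12)


def irls_logistic(X: np.ndarray, y: np.ndarray, tol=1e-12, maxiter=200) -> np.ndarray:
    """Independent iteratively-reweighted-least-squares logistic fit."""
    Xc = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xc.shape[1])
    for _ in range(maxiter):
        eta = Xc @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        WX = Xc * w[:, None]
        beta_new = np.linalg.solve(Xc.T @ WX, WX.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestFitLogistic:
    def test_matches_irls_oracle_to_1e8(self, tiny_config):
        frame = prepare_analysis_columns(generate_cohort(tiny_config))
        spec = ModelSpec("m", ("age", "bmi", "frax_logit"), "mof",
                         adjustment_covariates=())
        model = fit_logistic(frame, spec)
        X = frame[["age", "bmi", "frax_logit"]].to_numpy(dtype=float)
        y = frame["mof_event"].to_numpy(dtype=float)
        beta = irls_logistic(X, y)
        p_pkg = predict(model, frame)["predicted_probability"].to_numpy()
        p_oracle = expit(np.column_stack([np.ones(len(y)), X]) @ beta)
        assert np.max(np.abs(p_pkg - p_oracle)) < 1e-8

    def test_null_predictor_intercept_near_logit_prevalence(self):
        """Outcome independent of the predictor: intercept -> logit(0.124)."""
        rng = np.random.default_rng(0)
        n = 50_000
        frame = pd.DataFrame(
            {
                "id": np.arange(n).astype(str),
                "x": rng.standard_normal(n),
                "mof_event": rng.random(n) < 0.124,
            }
        )
        model = fit_logistic(frame, ModelSpec("null", ("x",), "mof",
                                              adjustment_covariates=()))
        se_intercept = 1 / np.sqrt(n * 0.124 * 0.876)
        assert model.intercept == pytest.approx(logit(0.124), abs=3 * se_intercept)
        assert abs(model.coefficients["x"]) < 3 * model.standard_errors["x"]

    def test_recovers_generator_coefficients_within_3_se(
        self, uncensored_cohort, uncensored_config
    ):
        frame = prepare_analysis_columns(uncensored_cohort)
        predictors = tuple(uncensored_config.risk_coefficients)
        spec = ModelSpec("truth", predictors, "mof", adjustment_covariates=())
        model = fit_logistic(frame, spec)
        for name, truth in uncensored_config.risk_coefficients.items():
            est = model.coefficients[name]
            se = model.standard_errors[name]
            assert abs(est - truth) < 3 * se, (name, est, truth, se)

    def test_mean_prediction_equals_event_rate(self, cohort):
        """Score-equation identity of the logistic MLE (calibration-in-the-large)."""
        frame = prepare_analysis_columns(cohort)
        model = fit_logistic(frame, ModelSpec("frax", ("frax_logit",), "mof"))
        p = predict(model, frame)["predicted_probability"]
        assert p.mean() == pytest.approx(frame["mof_event"].mean(), abs=1e-8)

    def test_nested_models_never_lose_likelihood(self, cohort):
        frame = prepare_analysis_columns(cohort)
        base = fit_logistic(frame, ModelSpec("frax", ("frax_logit",), "mof"))
        bigger = fit_logistic(
            frame,
            ModelSpec("frax_all",
                      ("frax_logit", "diabetes_treated", "falls_ge2",
                       "vasomotor_symptoms", "physical_function"), "mof"))
        assert bigger.log_likelihood >= base.log_likelihood - 1e-6

    def test_adjustment_covariates_keep_mean_prediction_identity(self, cohort):
        frame = prepare_analysis_columns(cohort)
        unadj = fit_logistic(frame, ModelSpec("u", ("frax_logit",), "mof",
                                              adjustment_covariates=()))
        adj = fit_logistic(frame, ModelSpec("a", ("frax_logit",), "mof"))
        assert adj.coefficients["frax_logit"] != unadj.coefficients["frax_logit"]
        p = predict(adj, frame)["predicted_probability"]
        assert p.mean() == pytest.approx(frame["mof_event"].mean(), abs=1e-8)

    def test_separation_raises_with_diagnostics(self):
        n = 200
        x = np.linspace(-2, 2, n)
        frame = pd.DataFrame({"id": np.arange(n).astype(str), "x": x,
                              "mof_event": x > 0})
        with pytest.raises(SeparationError):
            fit_logistic(frame, ModelSpec("sep", ("x",), "mof",
                                          adjustment_covariates=()))

    def test_missing_predictor_raises(self, cohort):
        frame = prepare_analysis_columns(cohort).copy()
        frame.loc[frame.index[0], "bmi"] = np.nan
        with pytest.raises(MissingInputError, match="bmi"):
            fit_logistic(frame, ModelSpec("m", ("bmi",), "mof"))


class TestPredict:
    def _manual_model(self, coefficients, intercept):
        spec = ModelSpec("manual", tuple(coefficients), "mof",
                         adjustment_covariates=())
        return FittedModel(
            spec=spec, intercept=intercept, coefficients=dict(coefficients),
            standard_errors={k: 0.0 for k in coefficients}, n_fit=10,
            log_likelihood=0.0, design_columns=tuple(coefficients))

    def test_zero_model_predicts_half(self):
        frame = pd.DataFrame({"id": ["a", "b"], "x": [1.0, -3.0]})
        model = self._manual_model({"x": 0.0}, 0.0)
        p = predict(model, frame)["predicted_probability"]
        assert (p == 0.5).all()

    def test_hand_computed_dot_product(self):
        frame = pd.DataFrame(
            {"id": list("abcde"),
             "x1": [0.0, 1.0, -1.0, 2.0, 0.5],
             "x2": [1.0, 0.0, 2.0, -1.0, 0.25]})
        model = self._manual_model({"x1": 0.8, "x2": -0.4}, 0.3)
        p = predict(model, frame)["predicted_probability"].to_numpy()
        expected = expit(0.3 + 0.8 * frame["x1"].to_numpy()
                         - 0.4 * frame["x2"].to_numpy())
        np.testing.assert_allclose(p, expected, atol=1e-15)

    def test_extreme_linear_predictor_stays_in_open_interval(self):
        frame = pd.DataFrame({"id": ["a", "b"], "x": [1e9, -1e9]})
        model = self._manual_model({"x": 10.0}, 0.0)
        p = predict(model, frame)["predicted_probability"].to_numpy()
        assert 0.0 < p.min() and p.max() < 1.0

    def test_trial_arm_dummies_reference_level(self, cohort):
        frame = prepare_analysis_columns(cohort)
        X = build_design_matrix(frame, ModelSpec("m", ("age",), "mof"))
        assert "hormone_trial_arm_not_randomized" not in X.columns
        assert {"hormone_trial_arm_active", "hormone_trial_arm_placebo"} <= set(X.columns)
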