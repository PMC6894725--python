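"""Risk scoring: a surrogate FRAX-like baseline score and nested logistic models.

The true FRAX coefficient set is proprietary, so the baseline 10-year risk
score here is an explicit, documented logistic score over the classical FRAX
inputs (age, BMI, prior fracture after 55, parental hip fracture, current
smoking, glucocorticoid use, rheumatoid arthritis, heavy alcohol use, and
optionally lumbar-spine BMD).  Every downstream evaluation treats it as an
arbitrary monotone predictor of fracture risk: no result depends on the exact
weights, only on the score ordering and on the logistic recalibration that the
evaluation pipeline performs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .config import ModelSpec

__all__ = [
    "MissingInputError",
    "SeparationError",
    "FittedModel",
    "surrogate_frax_score",
    "prepare_analysis_columns",
    "build_design_matrix",
    "fit_logistic",
    "predict",
]

# Bound on the linear predictor so predicted probabilities stay inside the
# open interval (0, 1) in double precision.
_LP_CLIP = 35.0


class MissingInputError(ValueError):
    """A required model/score input is missing; carries the field name(s)."""

    def __init__(self, fields):
        self.fields = tuple(fields)
        super().__init__(f"missing required input(s): {', '.join(self.fields)}")


class SeparationError(RuntimeError):
    """Logistic fit failed to converge (e.g. quasi-complete separation)."""

    def __init__(self, message, iterations=None):
        self.iterations = iterations
        super().__init__(message)


# Surrogate score: log-odds weights on deviations from a reference woman
# (age 63, BMI 25, lumbar-spine BMD 1.0 g/cm^2, no categorical risk factors).
SURROGATE_INTERCEPT = -2.10
SURROGATE_WEIGHTS = {
    "age": 0.065,                 # per year above 63
    "bmi": -0.015,                # per kg/m^2 above 25
    "prior_fracture_ge55": 0.70,
    "parental_hip_fracture": 0.35,
    "smoking_current": 0.25,
    "glucocorticoid_use": 0.60,
    "rheumatoid_arthritis": 0.35,
    "alcohol_heavy": 0.25,
}
SURROGATE_BMD_WEIGHT = -1.80      # per g/cm^2 above 1.0, only when with_bmd
_SURROGATE_REFERENCE = {"age": 63.0, "bmi": 25.0, "lumbar_spine_bmd": 1.0}


def surrogate_frax_score(
    records: pd.DataFrame | pd.Series,
    with_bmd: bool = False,
) -> np.ndarray | float:
    """10-year MOF probability from the surrogate baseline score.

    Accepts a cohort DataFrame (returns an array) or a single record as a
    Series (returns a float).  Deterministic; increasing in age and prior
    fracture, decreasing in BMD when ``with_bmd``.
    """
    single = isinstance(records, pd.Series)
    frame = records.to_frame().T if single else records

    required = list(SURROGATE_WEIGHTS) + (["lumbar_spine_bmd"] if with_bmd else [])
    absent = [c for c in required if c not in frame.columns]
    if absent:
        raise MissingInputError(absent)
    na_fields = [c for c in required if frame[c].isna().any()]
    if na_fields:
        raise MissingInputError(na_fields)

    lp = np.full(len(frame), SURROGATE_INTERCEPT, dtype=float)
    for name, weight in SURROGATE_WEIGHTS.items():
        x = frame[name].to_numpy(dtype=float)
        lp += weight * (x - _SURROGATE_REFERENCE.get(name, 0.0))
    if with_bmd:
        bmd = frame["lumbar_spine_bmd"].to_numpy(dtype=float)
        lp += SURROGATE_BMD_WEIGHT * (bmd - _SURROGATE_REFERENCE["lumbar_spine_bmd"])
    p = expit(np.clip(lp, -_LP_CLIP, _LP_CLIP))
    return float(p[0]) if single else p


def prepare_analysis_columns(cohort: pd.DataFrame, with_bmd: bool = False) -> pd.DataFrame:
    """Add derived analysis columns: the baseline score (probability and
    log-odds scale) and the frequent-falls indicator (>= 2 falls last year)."""
    out = cohort.copy()
    score = surrogate_frax_score(out, with_bmd=with_bmd)
    out["frax_score"] = score
    out["frax_logit"] = logit(score)
    out["falls_ge2"] = (out["falls_past_year"].astype("Int64") >= 2).astype("boolean")
    return out


@dataclass
class FittedModel:
    """A fitted logistic model: spec, MLE coefficients and standard errors."""

    spec: ModelSpec
    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    n_fit: int
    log_likelihood: float
    converged: bool = True
    design_columns: tuple[str, ...] = field(default_factory=tuple)

    def to_json(self) -> str:
        payload = {
            "name": self.spec.name,
            "outcome": self.spec.outcome,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "n_fit": self.n_fit,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }
        return json.dumps(payload, indent=2)


def _dummy_columns(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    """not_randomized is the reference level for trial-arm adjustment."""
    dummies = pd.get_dummies(frame[name], prefix=name, dtype=float)
    ref = f"{name}_not_randomized"
    return dummies.drop(columns=[ref], errors="ignore")


def build_design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Numeric design matrix (without intercept) for ``spec`` on ``cohort``."""
    absent = [c for c in (*spec.predictors, *spec.adjustment_covariates)
              if c not in cohort.columns]
    if absent:
        raise MissingInputError(absent)
    parts = []
    for name in spec.predictors:
        col = cohort[name]
        if col.isna().any():
            raise MissingInputError([name])
        parts.append(col.astype(float).rename(name))
    for name in spec.adjustment_covariates:
        if cohort[name].dtype == object or str(cohort[name].dtype) in ("string", "category"):
            parts.append(_dummy_columns(cohort, name))
        else:
            parts.append(cohort[name].astype(float).rename(name))
    return pd.concat(parts, axis=1)


def _outcome_vector(cohort: pd.DataFrame, outcome: str) -> np.ndarray:
    col = {"mof": "mof_event", "hip": "hip_event"}[outcome]
    y = cohort[col]
    if y.isna().any():
        raise MissingInputError([col])
    return y.to_numpy(dtype=float)


def fit_logistic(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> FittedModel:
    """Maximum-likelihood logistic fit of ``spec`` on ``cohort``.

    Newton-Raphson with convergence tolerance ``tol`` on the log-likelihood
    change; non-convergence (typically separation) raises
    :class:`SeparationError` with iteration diagnostics instead of silently
    returning an unstable fit.
    """
    X = build_design_matrix(cohort, spec)
    y = _outcome_vector(cohort, spec.outcome)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError(f"outcome {spec.outcome!r} is not binary")
    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        result = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False,
                           warn_convergence=False)
    except Exception as exc:  # singular Hessian, perfect separation, ...
        raise SeparationError(f"logistic fit failed for model {spec.name!r}: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise SeparationError(
            f"logistic fit for model {spec.name!r} did not converge in "
            f"{result.mle_retvals.get('iterations', maxiter)} iterations "
            "(possible separation)",
            iterations=result.mle_retvals.get("iterations"),
        )
    names = list(X.columns)
    params = np.asarray(result.params, dtype=float)
    ses = np.asarray(result.bse, dtype=float)
    return FittedModel(
        spec=spec,
        intercept=float(params[0]),
        coefficients=dict(zip(names, params[1:].tolist())),
        standard_errors=dict(zip(names, ses[1:].tolist())),
        n_fit=int(len(y)),
        log_likelihood=float(result.llf),
        converged=True,
        design_columns=tuple(names),
    )


def predict(model: FittedModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Predicted probabilities; columns ``id``, ``model``, ``predicted_probability``.

    The linear predictor is clipped to +/-35 so probabilities lie strictly
    inside (0, 1) even for extreme covariate values.
    """
    X = build_design_matrix(cohort, model.spec)
    missing = [c for c in model.design_columns if c not in X.columns]
    for c in missing:  # dummy level absent from this cohort slice
        X[c] = 0.0
    X = X[list(model.design_columns)]
    beta = np.array([model.coefficients[c] for c in model.design_columns])
    lp = model.intercept + X.to_numpy(dtype=float) @ beta
    prob = expit(np.clip(lp, -_LP_CLIP, _LP_CLIP))
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy(),
            "model": model.spec.name,
            "predicted_probability": prob,
        }
    )
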