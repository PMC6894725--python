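"""Synthetic postmenopausal-cohort generator.

Cohorts are pandas DataFrames with one row per participant and the column
schema below (nullable pandas dtypes so that injected missingness survives a
CSV round trip as empty fields).  The generative model is:

* continuous covariates from truncated normals (physical function truncated to
  the 0-100 scale of the RAND-36 subscale),
* binary risk factors from independent Bernoulli draws at configured
  prevalences, falls in the past year from a four-level categorical (0/1/2/3+),
* a latent 10-year major-osteoporotic-fracture (MOF) probability
  ``p = expit(base_intercept + sum_j beta_j * (x_j - center_j))`` with
  covariates centered at their configured means/prevalences,
* hip fracture as a subset of MOF via a conditional logistic model with a
  steeper age dependence (hip fractures concentrate at older ages, so a risk
  score discriminates hip events better than all MOFs),
* loss to follow-up from an exponential dropout process plus a death hazard
  increasing log-linearly with age; an event is observed only if its uniform
  event time falls before censoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .config import ConfigError, GeneratorConfig, TRIAL_ARM_LEVELS

__all__ = [
    "generate_cohort",
    "inject_missingness",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "BOOLEAN_COLUMNS",
    "FLOAT_COLUMNS",
    "COVARIATE_COLUMNS",
]

BOOLEAN_COLUMNS = (
    "diabetes_treated",
    "vasomotor_symptoms",
    "prior_fracture_ge55",
    "parental_hip_fracture",
    "smoking_current",
    "glucocorticoid_use",
    "rheumatoid_arthritis",
    "alcohol_heavy",
    "hormone_use_self",
    "baseline_osteo_med_use",
    "mof_event",
    "hip_event",
)

FLOAT_COLUMNS = (
    "age",
    "bmi",
    "physical_function",
    "lumbar_spine_bmd",
    "followup_years",
    "true_mof_prob",
    "true_hip_prob",
)

INT_COLUMNS = ("falls_past_year",)

STRING_COLUMNS = ("id", "hormone_trial_arm", "cavd_trial_arm")

#: Columns eligible for injected missingness (baseline covariates only).
COVARIATE_COLUMNS = (
    "age",
    "bmi",
    "diabetes_treated",
    "falls_past_year",
    "vasomotor_symptoms",
    "physical_function",
    "prior_fracture_ge55",
    "parental_hip_fracture",
    "smoking_current",
    "glucocorticoid_use",
    "rheumatoid_arthritis",
    "alcohol_heavy",
    "lumbar_spine_bmd",
)

COLUMN_ORDER = (
    "id",
    "age",
    "bmi",
    "diabetes_treated",
    "falls_past_year",
    "vasomotor_symptoms",
    "physical_function",
    "prior_fracture_ge55",
    "parental_hip_fracture",
    "smoking_current",
    "glucocorticoid_use",
    "rheumatoid_arthritis",
    "alcohol_heavy",
    "lumbar_spine_bmd",
    "hormone_use_self",
    "baseline_osteo_med_use",
    "hormone_trial_arm",
    "cavd_trial_arm",
    "followup_years",
    "mof_event",
    "hip_event",
    "true_mof_prob",
    "true_hip_prob",
)


def _truncnorm_loc(mean, sd, low, high):
    """Location parameter whose [low, high]-truncated normal has mean ``mean``.

    Truncation pulls the realized mean toward the interval centre, so using the
    target mean as the location would bias marginals (e.g. a 0-100 score with
    mean 83 would come out near 77).  Solved by bisection; the truncated mean
    is strictly increasing in the location.
    """
    if sd == 0:
        return mean
    if not low < mean < high:
        raise ValueError(f"target mean {mean} outside truncation bounds ({low}, {high})")

    def truncated_mean(loc):
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    span = high - low
    return optimize.brentq(lambda loc: truncated_mean(loc) - mean,
                           low - 10 * span, high + 10 * span, xtol=1e-10)


def _truncnorm_ppf(u, mean, sd, low, high):
    """Quantile of a truncated normal whose *realized* mean is ``mean``."""
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    loc = _truncnorm_loc(mean, sd, low, high)
    a, b = (low - loc) / sd, (high - loc) / sd
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def _latent_centers(config: GeneratorConfig) -> dict[str, float]:
    falls = np.asarray(config.falls_probs, dtype=float)
    falls = falls / falls.sum()
    centers = {
        "age": config.age_mean,
        "bmi": config.bmi_mean,
        "physical_function": config.physical_function_mean,
        "lumbar_spine_bmd": config.lumbar_spine_bmd_mean,
        "falls_ge2": float(falls[2] + falls[3]),
    }
    centers.update(config.covariate_prevalences)
    return centers


def linear_predictor(config: GeneratorConfig, frame: pd.DataFrame) -> np.ndarray:
    """Latent MOF log-odds for each row of ``frame`` under ``config``."""
    centers = _latent_centers(config)
    lp = np.full(len(frame), config.base_intercept, dtype=float)
    for name, beta in config.risk_coefficients.items():
        if name == "falls_ge2":
            x = (frame["falls_past_year"].to_numpy(dtype=float) >= 2).astype(float)
        elif name in frame.columns:
            x = frame[name].to_numpy(dtype=float)
        else:
            raise ConfigError(f"risk coefficient for unknown covariate {name!r}")
        center = centers.get(name)
        if center is None:
            raise ConfigError(
                f"no centering value for risk covariate {name!r}; "
                "add it to covariate_prevalences"
            )
        lp += beta * (x - center)
    return lp


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic cohort; reproducible given ``config.seed``."""
    n = config.n_participants
    rng = np.random.default_rng(config.seed)

    # Continuous covariates.  Age and physical function share a Gaussian
    # copula so an optional (default 0) correlation can be configured.
    rho = config.corr_age_physical_function
    z_age = rng.standard_normal(n)
    z_pf = rho * z_age + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    age = _truncnorm_ppf(stats.norm.cdf(z_age), config.age_mean, config.age_sd,
                         *config.age_range)
    physical_function = _truncnorm_ppf(
        stats.norm.cdf(z_pf), config.physical_function_mean,
        config.physical_function_sd, 0.0, 100.0)
    bmi = _truncnorm_ppf(rng.random(n), config.bmi_mean, config.bmi_sd, 15.0, 60.0)
    bmd = _truncnorm_ppf(rng.random(n), config.lumbar_spine_bmd_mean,
                         config.lumbar_spine_bmd_sd, 0.4, 1.8)

    falls_probs = np.asarray(config.falls_probs, dtype=float)
    falls_probs = falls_probs / falls_probs.sum()
    falls = rng.choice(4, size=n, p=falls_probs)

    data: dict[str, np.ndarray] = {
        "age": age,
        "bmi": bmi,
        "physical_function": physical_function,
        "lumbar_spine_bmd": bmd,
        "falls_past_year": falls,
    }
    for name in sorted(config.covariate_prevalences):
        data[name] = rng.random(n) < config.covariate_prevalences[name]

    for col, probs in (("hormone_trial_arm", config.hormone_arm_probs),
                       ("cavd_trial_arm", config.cavd_arm_probs)):
        arm_p = np.asarray(probs, dtype=float)
        data[col] = rng.choice(TRIAL_ARM_LEVELS, size=n, p=arm_p / arm_p.sum())

    frame = pd.DataFrame(data)

    # Latent 10-year risks and outcomes.
    p_mof = expit(linear_predictor(config, frame))
    p_hip_given_mof = expit(
        config.hip_given_mof_intercept
        + config.hip_age_slope * (age - config.age_mean))
    latent_mof = rng.random(n) < p_mof
    latent_hip = latent_mof & (rng.random(n) < p_hip_given_mof)
    event_time = rng.uniform(0.0, config.horizon, size=n)

    # Censoring: exponential with per-subject hazard = dropout + death(age).
    hazard = config.dropout_rate_annual + config.death_rate_annual * np.exp(
        config.death_age_slope * (age - config.age_mean))
    with np.errstate(divide="ignore"):
        censor_time = np.where(
            hazard > 0, rng.exponential(1.0, size=n) / np.maximum(hazard, 1e-300),
            np.inf)
    followup = np.minimum(censor_time, config.horizon)
    observed_mof = latent_mof & (event_time <= followup)
    observed_hip = latent_hip & (event_time <= followup)

    frame["followup_years"] = followup
    frame["mof_event"] = observed_mof
    frame["hip_event"] = observed_hip
    frame["true_mof_prob"] = p_mof
    frame["true_hip_prob"] = p_mof * p_hip_given_mof
    frame["id"] = [f"S{i:07d}" for i in range(1, n + 1)]

    frame = frame[list(COLUMN_ORDER)]
    for col in BOOLEAN_COLUMNS:
        frame[col] = frame[col].astype("boolean")
    frame["falls_past_year"] = frame["falls_past_year"].astype("Int64")
    return frame


def inject_missingness(
    cohort: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
) -> pd.DataFrame:
    """Independently blank each named covariate at its configured rate."""
    for name, rate in rates.items():
        if name not in COVARIATE_COLUMNS:
            raise ConfigError(f"cannot inject missingness into {name!r}; "
                              f"known covariates: {COVARIATE_COLUMNS}")
        if not 0.0 <= rate <= 1.0:
            raise ConfigError(f"missingness rate for {name!r} must be in [0, 1]")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for name in sorted(rates):
        mask = rng.random(len(out)) < rates[name]
        if out[name].dtype == np.dtype(float):
            out[name] = out[name].astype("Float64")
        out.loc[mask, name] = pd.NA
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as RFC-4180 CSV; missing values become empty fields."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    dtype: dict[str, object] = {c: "boolean" for c in BOOLEAN_COLUMNS}
    dtype.update({c: "Float64" for c in FLOAT_COLUMNS})
    dtype.update({c: "Int64" for c in INT_COLUMNS})
    dtype.update({c: "string" for c in STRING_COLUMNS})
    frame = pd.read_csv(path, dtype=dtype)
    # Plain float64 where no values are missing keeps numerics fast downstream.
    for col in FLOAT_COLUMNS:
        if col in frame.columns and not frame[col].isna().any():
            frame[col] = frame[col].astype(float)
    return frame


def validate_cohort(cohort: pd.DataFrame, horizon: float | None = None) -> None:
    """Raise ``ValueError`` on any violated cohort invariant."""
    pf = cohort["physical_function"].dropna()
    if ((pf < 0) | (pf > 100)).any():
        raise ValueError("physical_function outside [0, 100]")
    hip = cohort["hip_event"].fillna(False).to_numpy(dtype=bool)
    mof = cohort["mof_event"].fillna(False).to_numpy(dtype=bool)
    if (hip & ~mof).any():
        raise ValueError("hip_event without mof_event (hip fracture is a MOF)")
    if (cohort["followup_years"].dropna() < 0).any():
        raise ValueError("negative followup_years")
    if horizon is not None and (cohort["followup_years"].dropna() > horizon + 1e-9).any():
        raise ValueError("followup_years exceeds horizon")
    if cohort["id"].duplicated().any():
        raise ValueError("duplicate participant ids")
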