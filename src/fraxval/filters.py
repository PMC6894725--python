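"""Eligibility filtering: produce the analytic sample and an exclusion ledger.

Exclusion counts are attributed to the first failing criterion, in this order:

1. ``osteo_med_use`` — baseline osteoporosis-medication use,
2. ``insufficient_followup`` — less than ``horizon`` years of follow-up
   without experiencing the fracture outcome,
3. ``missing_covariates`` — any required covariate missing,
4. ``min_age`` / ``hormone_use`` — scenario subgroup restrictions.

A participant whose fracture occurred before the horizon is retained under the
follow-up rule regardless of censoring time.
"""

from __future__ import annotations

import json
import warnings

import pandas as pd

from .config import ConfigError, FilterPolicy

__all__ = ["apply_filter", "hormone_user", "write_ledger"]


def hormone_user(cohort: pd.DataFrame) -> pd.Series:
    """Hormone-therapy use with trial assignment overriding self-report.

    Women randomized to active hormone therapy count as users and women
    randomized to placebo as nonusers, whatever they reported at baseline;
    self-report decides only for women outside the hormone trial.
    """
    arm = cohort["hormone_trial_arm"]
    self_report = cohort["hormone_use_self"].fillna(False).astype(bool)
    return pd.Series(
        (arm == "active") | ((arm == "not_randomized") & self_report),
        index=cohort.index,
    )


def apply_filter(
    cohort: pd.DataFrame,
    policy: FilterPolicy,
    horizon: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply ``policy`` and return ``(analytic cohort, exclusion ledger)``.

    The ledger maps criterion name -> number excluded at that step, plus
    ``input_n`` and ``output_n``; counts always satisfy
    ``input_n - output_n == sum(step counts)``.
    """
    if horizon <= 0:
        raise ConfigError(f"horizon must be > 0, got {horizon!r}")
    unknown = set(policy.require_complete_covariates) - set(cohort.columns)
    if unknown:
        raise ConfigError(f"required covariates not in cohort: {sorted(unknown)}")

    remaining = cohort
    ledger: dict[str, int] = {"input_n": len(cohort)}

    def _exclude(step: str, bad: pd.Series) -> None:
        nonlocal remaining
        bad = bad.fillna(False).astype(bool)
        ledger[step] = int(bad.sum())
        remaining = remaining.loc[~bad]

    if policy.exclude_osteo_med_users:
        _exclude("osteo_med_use", remaining["baseline_osteo_med_use"].astype("boolean"))

    if policy.require_full_followup_or_event:
        event = remaining["mof_event"].fillna(False).astype(bool)
        short = remaining["followup_years"] < horizon
        _exclude("insufficient_followup", short & ~event)

    if policy.require_complete_covariates:
        missing = remaining[list(policy.require_complete_covariates)].isna().any(axis=1)
        _exclude("missing_covariates", missing)

    if policy.min_age is not None:
        _exclude("min_age", remaining["age"] < policy.min_age)

    if policy.exclude_hormone_users:
        _exclude("hormone_use", hormone_user(remaining))

    ledger["output_n"] = len(remaining)
    if len(remaining) == 0:
        warnings.warn("analytic cohort is empty after filtering", stacklevel=2)
    return remaining.copy(), ledger


def write_ledger(ledger: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger, fh, indent=2)
        fh.write("\n")
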