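"""Calibration by decile of predicted risk: observed/expected ratios and slope.

Subjects are ranked by predicted probability and filled into ten groups of
target size n/10, but a block of tied predictions is never split across
deciles — a block is assigned wholly to the decile in which it starts.  Decile
sizes are therefore unequal in the presence of ties, exactly as in published
risk-decile tables.

Two calibration-slope estimators are provided, since different reports use
different conventions:

* :func:`decile_slope` — n-weighted least-squares slope of observed on mean
  predicted decile proportions (the estimator used in ``calibration_table``);
* :func:`logistic_recalibration_slope` — slope on logit(predicted) in a
  logistic refit (the Cox recalibration slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit

__all__ = [
    "CalibrationDecileRow",
    "CalibrationSummary",
    "decile_partition",
    "calibration_table",
    "decile_slope",
    "logistic_recalibration_slope",
]

N_DECILES = 10


@dataclass
class CalibrationDecileRow:
    decile: int
    n: int
    observed: float     # observed event proportion
    predicted: float    # mean predicted probability
    oe_ratio: float     # observed / predicted; NaN when predicted == 0

    @property
    def oe_defined(self) -> bool:
        return np.isfinite(self.oe_ratio)

    @classmethod
    def from_proportions(cls, decile, n, observed, predicted) -> "CalibrationDecileRow":
        """Build a row from published observed/predicted proportions."""
        oe = observed / predicted if predicted > 0 else np.nan
        return cls(decile=decile, n=n, observed=observed, predicted=predicted,
                   oe_ratio=oe)


@dataclass
class CalibrationSummary:
    outcome: str
    model: str
    rows: list[CalibrationDecileRow]
    overall_observed: float
    overall_predicted: float
    overall_oe: float
    slope: float
    intercept: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "decile": r.decile,
                    "n": r.n,
                    "observed": r.observed,
                    "predicted": r.predicted,
                    "oe_ratio": r.oe_ratio,
                }
                for r in self.rows
            ]
        )


def decile_partition(predictions) -> np.ndarray:
    """Assign each subject a decile 1..10 of predicted risk.

    Rank-based sort-and-fill: walk the distinct prediction values in
    increasing order and place each whole tied block into the decile where
    its first member lands (``floor(10 * rank_before / n) + 1``).  Ties are
    never split, so group sizes may differ from n/10.  Deterministic and
    invariant to any strictly monotone relabelling of the predictions.
    """
    p = np.asarray(predictions, dtype=float)
    n = len(p)
    if n < N_DECILES:
        raise ValueError(f"need at least {N_DECILES} subjects, got {n}")
    if np.isnan(p).any():
        raise ValueError("predictions contain NaN")
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    # start rank (0-based) of the tied block each sorted element belongs to
    is_new_block = np.empty(n, dtype=bool)
    is_new_block[0] = True
    np.not_equal(sorted_p[1:], sorted_p[:-1], out=is_new_block[1:])
    block_start = np.maximum.accumulate(np.where(is_new_block, np.arange(n), 0))
    decile_sorted = (N_DECILES * block_start) // n + 1
    deciles = np.empty(n, dtype=np.int64)
    deciles[order] = decile_sorted
    return deciles


def decile_slope(rows: list[CalibrationDecileRow]) -> tuple[float, float]:
    """n-weighted least squares of observed on predicted decile proportions;
    returns ``(slope, intercept)``."""
    obs = np.array([r.observed for r in rows], dtype=float)
    pred = np.array([r.predicted for r in rows], dtype=float)
    w = np.array([r.n for r in rows], dtype=float)
    X = sm.add_constant(pred)
    fit = sm.WLS(obs, X, weights=w).fit()
    return float(fit.params[1]), float(fit.params[0])


def logistic_recalibration_slope(predictions, outcomes) -> tuple[float, float]:
    """Cox recalibration: logistic fit of outcome on logit(predicted);
    returns ``(slope, intercept)``.  Slope 1, intercept 0 is ideal."""
    p = np.clip(np.asarray(predictions, dtype=float), 1e-12, 1.0 - 1e-12)
    y = np.asarray(outcomes).astype(float)
    X = sm.add_constant(logit(p))
    fit = sm.Logit(y, X).fit(disp=False)
    return float(fit.params[1]), float(fit.params[0])


def calibration_table(
    deciles,
    predictions,
    outcomes,
    outcome: str = "",
    model: str = "",
) -> CalibrationSummary:
    """Per-decile observed vs mean predicted proportions, O/E ratios, overall
    O/E, and the weighted decile calibration slope."""
    deciles = np.asarray(deciles)
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes).astype(float)
    if not (len(deciles) == len(p) == len(y)):
        raise ValueError("deciles, predictions and outcomes must align")

    rows = []
    for d in range(1, N_DECILES + 1):
        mask = deciles == d
        n_d = int(mask.sum())
        if n_d == 0:
            rows.append(CalibrationDecileRow(d, 0, np.nan, np.nan, np.nan))
            continue
        observed = float(y[mask].mean())
        predicted = float(p[mask].mean())
        oe = observed / predicted if predicted > 0 else np.nan
        rows.append(CalibrationDecileRow(d, n_d, observed, predicted, oe))

    overall_obs = float(y.mean())
    overall_pred = float(p.mean())
    overall_oe = overall_obs / overall_pred if overall_pred > 0 else np.nan
    slope, intercept = decile_slope([r for r in rows if r.n > 0])
    return CalibrationSummary(
        outcome=outcome,
        model=model,
        rows=rows,
        overall_observed=overall_obs,
        overall_predicted=overall_pred,
        overall_oe=overall_oe,
        slope=slope,
        intercept=intercept,
    )
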