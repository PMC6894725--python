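"""Category-based risk reclassification and the net reclassification index.

Subjects are cross-classified by risk category (low: p < threshold, high:
p >= threshold — the half-open clinical convention) under a base and an
expanded model, separately among events and non-events.  The two NRI
components are

* event NRI   = (events reclassified up   - events reclassified down) / n_events
* nonevent NRI = (non-events reclassified down - non-events reclassified up) / n_nonevents

interpretable as the change in sensitivity and specificity, respectively.
Each component gets a one-sided McNemar-style normal test of the null that
up- and down-moves among the off-diagonal are symmetric, with the alternative
"the expanded model improves classification" — so a component that makes
classification worse reports p near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UndefinedNRIError",
    "ReclassificationTable",
    "NRISummary",
    "build_reclass_table",
    "compute_nri",
    "nri_percent_report",
    "format_p_value",
]


class UndefinedNRIError(ValueError):
    """NRI undefined: an event/non-event stratum is empty."""


@dataclass
class ReclassificationTable:
    """2x2 counts: base-model category (rows) x expanded-model category (cols),
    within one event stratum.  Row/column order is (low, high)."""

    outcome: str
    threshold: float
    event_status: str  # "events" | "nonevents"
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 2x2 grid")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_up(self) -> int:
        """Moved from low (base) to high (expanded)."""
        return int(self.counts[0, 1])

    @property
    def n_down(self) -> int:
        """Moved from high (base) to low (expanded)."""
        return int(self.counts[1, 0])

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row_percentages(self) -> np.ndarray:
        """Row-wise percentages (each base-model category summing to 100)."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals[:, None]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(["low", "high"], name="base_category")
        return pd.DataFrame(self.counts, index=idx,
                            columns=pd.Index(["low", "high"], name="expanded_category"))


@dataclass
class NRISummary:
    outcome: str
    threshold: float
    event_nri: float
    nonevent_nri: float
    up_events: int
    down_events: int
    up_nonevents: int
    down_nonevents: int
    n_events: int
    n_nonevents: int
    p_event: float
    p_nonevent: float

    @property
    def overall_nri(self) -> float:
        """Sum of the two components (the conventional summary NRI)."""
        return self.event_nri + self.nonevent_nri


def _categories(probabilities, threshold: float) -> np.ndarray:
    p = np.asarray(probabilities, dtype=float)
    if np.isnan(p).any():
        raise ValueError("predicted probabilities contain NaN")
    return (p >= threshold).astype(int)  # 0 = low, 1 = high


def build_reclass_table(
    pred_base: pd.DataFrame,
    pred_expanded: pd.DataFrame,
    outcomes,
    threshold: float,
    outcome: str = "",
) -> tuple[ReclassificationTable, ReclassificationTable]:
    """Cross-classify subjects under two models; returns (events, nonevents).

    ``pred_base`` / ``pred_expanded`` are prediction frames with ``id`` and
    ``predicted_probability`` columns covering the same subjects; ``outcomes``
    is the binary event label aligned with ``pred_base`` order.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold!r}")
    base = pred_base.set_index("id")["predicted_probability"]
    expanded = pred_expanded.set_index("id")["predicted_probability"]
    missing = base.index.difference(expanded.index)
    extra = expanded.index.difference(base.index)
    if len(missing) or len(extra):
        raise ValueError(
            "prediction sets cover different subjects; "
            f"missing from expanded: {list(missing[:5])}, "
            f"missing from base: {list(extra[:5])}")
    expanded = expanded.loc[base.index]
    y = np.asarray(outcomes).astype(bool)
    if len(y) != len(base):
        raise ValueError("outcomes length does not match predictions")

    cat_base = _categories(base.to_numpy(), threshold)
    cat_exp = _categories(expanded.to_numpy(), threshold)

    tables = []
    for status, mask in (("events", y), ("nonevents", ~y)):
        counts = np.zeros((2, 2), dtype=np.int64)
        np.add.at(counts, (cat_base[mask], cat_exp[mask]), 1)
        tables.append(ReclassificationTable(outcome, threshold, status, counts))
    return tables[0], tables[1]


def _component_p(favorable: int, unfavorable: int) -> float:
    """One-sided normal test of net movement in the favorable direction."""
    total = favorable + unfavorable
    if total == 0:
        return 1.0
    z = (favorable - unfavorable) / np.sqrt(total)
    return float(stats.norm.sf(z))


def compute_nri(
    events: ReclassificationTable,
    nonevents: ReclassificationTable,
) -> NRISummary:
    """Event and non-event NRI components with one-sided component tests."""
    if events.event_status != "events" or nonevents.event_status != "nonevents":
        raise ValueError("pass the (events, nonevents) tables in that order")
    if events.threshold != nonevents.threshold:
        raise ValueError("event and non-event tables use different thresholds")
    if events.n == 0 or nonevents.n == 0:
        raise UndefinedNRIError(
            f"NRI undefined with {events.n} events and {nonevents.n} non-events")
    event_nri = (events.n_up - events.n_down) / events.n
    nonevent_nri = (nonevents.n_down - nonevents.n_up) / nonevents.n
    return NRISummary(
        outcome=events.outcome,
        threshold=events.threshold,
        event_nri=event_nri,
        nonevent_nri=nonevent_nri,
        up_events=events.n_up,
        down_events=events.n_down,
        up_nonevents=nonevents.n_up,
        down_nonevents=nonevents.n_down,
        n_events=events.n,
        n_nonevents=nonevents.n,
        p_event=_component_p(events.n_up, events.n_down),
        p_nonevent=_component_p(nonevents.n_down, nonevents.n_up),
    )


def format_p_value(p: float) -> str:
    """Clinical-journal convention: '<0.001', '>0.99', else two decimals."""
    if p < 0.001:
        return "<0.001"
    if p > 0.99:
        return ">0.99"
    return f"{p:.2f}"


def format_percent(proportion: float, decimals: int = 1) -> str:
    return f"{100.0 * proportion:.{decimals}f}%"


def nri_percent_report(summary: NRISummary) -> dict[str, str]:
    """Percentage-scale rendering of an :class:`NRISummary`."""
    return {
        "outcome": summary.outcome,
        "event_nri": format_percent(summary.event_nri),
        "nonevent_nri": format_percent(summary.nonevent_nri),
        "p_event": format_p_value(summary.p_event),
        "p_nonevent": format_p_value(summary.p_nonevent),
    }
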