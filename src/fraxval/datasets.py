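"""Published reference tables from the Women's Health Initiative (WHI)
fracture-risk validation analysis.

These are the printed summary tables of the WHI evaluation of a FRAX-based
10-year fracture risk score in 94,413 postmenopausal women: the risk
reclassification tables (base score vs score + clinical risk factors, at the
clinical thresholds of 20% predicted MOF risk and 3% predicted hip-fracture
risk) and the observed/expected calibration table by decile of predicted
risk.  Individual-level WHI data are not public; these aggregate counts are
the inputs for worked examples and cross-checks of the reclassification and
calibration arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reclassification import ReclassificationTable

__all__ = [
    "whi_reclassification_tables",
    "whi_calibration_deciles",
    "WHI_THRESHOLDS",
]

WHI_THRESHOLDS = {"mof": 0.20, "hip": 0.03}

# 2x2 counts [base category x expanded category], rows/cols ordered (low, high).
_WHI_RECLASS_COUNTS = {
    ("hip", "events"): [[947, 361], [91, 579]],
    ("hip", "nonevents"): [[76_119, 7_381], [1_906, 4_691]],
    ("mof", "events"): [[8_558, 959], [291, 1_902]],
    ("mof", "nonevents"): [[74_081, 2_747], [1_332, 4_543]],
}

# Decile calibration of the recalibrated baseline score:
# (decile, hip n, hip observed, hip predicted, mof n, mof observed, mof predicted)
_WHI_CALIBRATION = [
    (1, 9_218, 0.005, 0.012, 9_432, 0.054, 0.071),
    (2, 9_361, 0.007, 0.015, 9_452, 0.069, 0.080),
    (3, 9_047, 0.004, 0.015, 9_441, 0.078, 0.087),
    (4, 9_066, 0.007, 0.016, 9_432, 0.090, 0.094),
    (5, 9_267, 0.011, 0.016, 9_420, 0.102, 0.101),
    (6, 9_318, 0.015, 0.017, 9_468, 0.111, 0.109),
    (7, 9_172, 0.017, 0.018, 9_426, 0.138, 0.120),
    (8, 9_202, 0.028, 0.020, 9_467, 0.157, 0.138),
    (9, 9_223, 0.039, 0.024, 9_432, 0.178, 0.168),
    (10, 9_201, 0.083, 0.061, 9_441, 0.264, 0.273),
    ("total", 92_075, 0.021, 0.021, 94_413, 0.124, 0.124),
]


def whi_reclassification_tables(
    outcome: str,
) -> tuple[ReclassificationTable, ReclassificationTable]:
    """Published (events, nonevents) reclassification tables for an outcome."""
    if outcome not in ("mof", "hip"):
        raise ValueError(f"outcome must be 'mof' or 'hip', got {outcome!r}")
    threshold = WHI_THRESHOLDS[outcome]
    events = ReclassificationTable(
        outcome, threshold, "events",
        np.array(_WHI_RECLASS_COUNTS[(outcome, "events")]))
    nonevents = ReclassificationTable(
        outcome, threshold, "nonevents",
        np.array(_WHI_RECLASS_COUNTS[(outcome, "nonevents")]))
    return events, nonevents


def whi_calibration_deciles() -> pd.DataFrame:
    """Published decile-calibration table (hip and MOF observed/predicted)."""
    return pd.DataFrame(
        _WHI_CALIBRATION,
        columns=[
            "decile",
            "hip_n", "hip_observed", "hip_predicted",
            "mof_n", "mof_observed", "mof_predicted",
        ],
    )
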