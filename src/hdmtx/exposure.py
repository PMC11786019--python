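"""Protocol threshold flags and cohort-level exposure classification.

The consolidation protocol defines three monitoring thresholds: the
end-of-infusion (24 h) level should stay below 150 uM; post-infusion levels
above 1 uM at 42 h or 0.5 uM at 48 h indicate delayed excretion, trigger
6-hourly monitoring and intensified leucovorin rescue.

Cohort-level exposure is classified by quartiles of the per-patient mean
24 h level and mean clearance: systemic exposure is "high" when the mean
level falls in the top quartile (Q4) or the mean clearance in the bottom one
(Q1, delayed elimination).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidInputError

#: 24 h levels at or above this (uM) violate the end-of-infusion expectation
#: ("should be lower than 150 uM", hence >= is flagged).
THRESHOLD_24H_UM = 150.0
THRESHOLD_42H_UM = 1.0
THRESHOLD_48H_UM = 0.5


@dataclass(frozen=True)
class ExposureFlags:
    """Threshold flags for one course (strict '>' at 42/48 h, '>=' at 24 h)."""

    over_150_at_24h: bool
    over_1_at_42h: bool | None
    over_05_at_48h: bool | None
    delayed_excretion: bool


def flag_course(level_24h_um, level_42h_um=None, level_48h_um=None) -> ExposureFlags:
    """Evaluate the protocol thresholds for one course.

    The 24 h level is mandatory; 42/48 h levels may be missing (None), in
    which case the corresponding flags are None and do not contribute to the
    delayed-excretion flag.
    """
    if level_24h_um is None or (isinstance(level_24h_um, float) and np.isnan(level_24h_um)):
        raise InvalidInputError("24 h end-of-infusion level is required")
    f24 = bool(level_24h_um >= THRESHOLD_24H_UM)
    f42 = None if level_42h_um is None else bool(level_42h_um > THRESHOLD_42H_UM)
    f48 = None if level_48h_um is None else bool(level_48h_um > THRESHOLD_48H_UM)
    # delayed excretion: the latest available post-infusion level exceeds its
    # protocol threshold, keeping 6-hourly monitoring going
    if f48 is not None:
        delayed = f48
    elif f42 is not None:
        delayed = f42
    else:
        delayed = False
    return ExposureFlags(f24, f42, f48, delayed)


def intensified_leucovorin(course_flags) -> bool:
    """Patient-level flag: any course exceeding 0.5 uM at 48 h."""
    return any(bool(f.over_05_at_48h) for f in course_flags)


def assign_quartiles(values) -> np.ndarray:
    """Quartile labels 1-4 from the empirical 25/50/75 percentiles.

    Cut-points use linear-interpolation quantiles; values tied with a
    cut-point go to the lower quartile.  A degenerate (constant) sample puts
    everyone in Q1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(f"need >= 4 values for quartiles, got {v.size}")
    if np.isnan(v).any():
        raise InvalidInputError("quartile assignment does not accept NaN")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    if cuts[0] == cuts[2]:
        warnings.warn("degenerate distribution: all quartile cut-points equal; "
                      "assigning everyone to Q1", stacklevel=2)
    # ties at a cut-point go down: count how many cuts are strictly below
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)


def classify_exposure(summary: pd.DataFrame,
                      level_col: str = "mean_level_24h_um",
                      cl_col: str = "mean_clearance") -> pd.DataFrame:
    """Per-patient exposure class from a summary table.

    Adds ``level_quartile``, ``cl_quartile`` and ``high_exposure`` (level in
    Q4 or clearance in Q1) columns; returns a copy.
    """
    out = summary.copy()
    out["level_quartile"] = assign_quartiles(out[level_col].to_numpy())
    out["cl_quartile"] = assign_quartiles(out[cl_col].to_numpy())
    out["high_exposure"] = (out["level_quartile"] == 4) | (out["cl_quartile"] == 1)
    return out
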