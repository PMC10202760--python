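"""CSV input for applied analyses.

The applied entry point accepts any rectangular table of numeric predictors
plus one continuous outcome column.  Rows with missing values are removed
by listwise deletion — the count is logged, since silently shrinking n is a
known hazard of that practice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def load_table(path, outcome_name: str):
    """Read a header CSV and split it into predictors and outcome.

    Returns ``(raw_X, raw_y, predictor_names)`` with the file's column order
    preserved.  Raises on a missing outcome column (naming the available
    columns) or any non-numeric cell (naming row and column).
    """
    frame = pd.read_csv(path)
    if outcome_name not in frame.columns:
        raise ValueError(
            f"outcome column {outcome_name!r} not found; available columns: "
            f"{', '.join(frame.columns)}"
        )
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {frame[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        frame[col] = coerced

    n_before = len(frame)
    frame = frame.dropna()
    dropped = n_before - len(frame)
    if dropped:
        log.warning("listwise deletion dropped %d of %d rows with missing values",
                    dropped, n_before)

    predictors = [c for c in frame.columns if c != outcome_name]
    raw_X = frame[predictors].to_numpy(dtype=float)
    raw_y = frame[outcome_name].to_numpy(dtype=float)
    return raw_X, raw_y, predictors
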