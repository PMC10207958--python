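"""Reading and writing per-trial behavioral tables.

The trial table is the lingua franca of every analysis stage: one row per
trial per participant, columns

    participant, trial, orientation, response, confidence, correct[, rt]

with ``response`` in {"left", "right"}, ``confidence`` an integer 1-4,
``orientation`` the signed Gabor tilt in degrees and ``correct`` in {0, 1}
(NaN on 0-degree trials, where no response is veridical). Trial indices are
1-based and consecutive within a participant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("participant", "trial", "orientation", "response", "confidence", "correct")

VALID_RESPONSES = frozenset({"left", "right"})


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants; return the frame (for chaining).

    Raises ``ValueError`` on a malformed table.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if not set(trials["response"].unique()) <= VALID_RESPONSES:
        bad = set(trials["response"].unique()) - VALID_RESPONSES
        raise ValueError(f"invalid response values: {bad}")
    conf = trials["confidence"].to_numpy()
    if not np.isin(conf, [1, 2, 3, 4]).all():
        raise ValueError("confidence ratings must be integers in 1..4")
    for pid, sub in trials.groupby("participant", sort=False):
        t = sub["trial"].to_numpy()
        if not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValueError(f"participant {pid!r}: trial indices not consecutive from 1")
    zero = trials["orientation"] == 0
    if trials.loc[zero, "correct"].notna().any():
        raise ValueError("correct must be undefined (NaN) on 0-degree trials")
    if trials.loc[~zero, "correct"].isna().any():
        raise ValueError("correct must be defined on non-zero-degree trials")
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as comma-separated UTF-8 text with a header row."""
    validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table written by :func:`write_trials`."""
    trials = pd.read_csv(path)
    return validate_trials(trials)
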