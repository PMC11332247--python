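"""Reading and writing of trial-level behavioural tables.

The on-disk format is tab-separated text with a fixed column order; missing
values (RT/accuracy on null responses, transition on the first trial of a
block) are written as empty fields.  Booleans are encoded as 0/1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical column order of a trial table
COLUMNS = [
    "subject_id", "group", "block", "trial", "stimulus_id", "task",
    "congruency", "transition", "scheduled_high_reward", "rt_ms",
    "accuracy", "reward",
]

#: optional columns appended by specific generators (kept if present)
OPTIONAL_COLUMNS = ["previously_high_rewarded"]

_BOOL_COLS = ("scheduled_high_reward", "previously_high_rewarded")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Check that a data frame has the canonical columns, reorder them."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    extra = [c for c in OPTIONAL_COLUMNS if c in df.columns]
    return df[COLUMNS + extra]


def write_trials(df: pd.DataFrame, path) -> None:
    df = validate_trials(df).copy()
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "stimulus_id": str})
    df = validate_trials(df)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col in ("rt_ms", "accuracy", "reward"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def order_within_subject(df: pd.DataFrame) -> pd.DataFrame:
    """Rows sorted in presentation order within subject (stable for ties)."""
    return df.sort_values(["subject_id", "block", "trial"], kind="mergesort")


def is_missing(series: pd.Series) -> np.ndarray:
    return series.isna().to_numpy()
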