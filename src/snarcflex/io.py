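"""CSV reading/writing with schema validation for trial and metadata tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import META_COLUMNS, TRIAL_COLUMNS

_TRIAL_DTYPES = {
    "participant_id": str,
    "experiment": str,
    "block_index": int,
    "block_order": int,
    "range_id": str,
    "key_assignment": str,
    "number": int,
    "parity": float,
    "response_side": str,
    "rt_ms": float,
    "correct": bool,
    "practice": bool,
    "missing": bool,
}


def read_trials(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a trial CSV, validating the schema.

    Raises a ``ValueError`` naming any missing column.  Files written with
    a different separator are rejected with a hint to pass ``sep``.
    """
    df = pd.read_csv(path, sep=sep)
    if len(df.columns) == 1 and sep not in str(df.columns[0]):
        raise ValueError(
            f"{path}: parsed a single column {df.columns[0]!r} — the file "
            f"probably uses a different separator than {sep!r}; pass sep="
        )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trial table misses column(s): {missing}")
    for col, dtype in _TRIAL_DTYPES.items():
        if col == "rt_ms":
            continue  # may contain NaN for missing responses
        df[col] = df[col].astype(dtype)
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def read_participants(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a participant metadata CSV; extra columns are preserved."""
    df = pd.read_csv(path, sep=sep)
    required = [c for c in META_COLUMNS if c != "block_order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata table misses column(s): {missing}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def write_participants(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False)
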