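"""Trial-table schema, validation, and CSV round-tripping.

The trial table is a wide CSV: one row per trial, with the per-frame
external evidence of the two channels as ``ev_ch1_t01..`` / ``ev_ch2_t01..``
columns. This keeps a whole experiment in a single self-describing file
that round-trips losslessly at full float precision.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_trial_table", "write_trial_table", "validate_trial_table"]

REQUIRED_COLUMNS = (
    "subject_id",
    "session_id",
    "task",
    "condition_boost",
    "coherence",
    "world_signal_channel",
    "decision",
    "correct",
    "confidence",
)

_WORLD_VALUES = {"1", "2", "none"}
_DECISIONS = {"channel1", "channel2", "yes", "no", "1", "2"}
_TASKS = {"discrimination", "detection"}


class TrialTableValidationError(ValueError):
    """Schema violation in a trial table, with offending rows listed."""


def _fail(messages: list[str]) -> None:
    raise TrialTableValidationError("; ".join(messages))


def validate_trial_table(table: pd.DataFrame) -> None:
    """Check schema, enums and value ranges; report offenders by row."""
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        _fail([f"missing required column(s): {', '.join(missing)}"])
    ch1 = [c for c in table.columns if c.startswith("ev_ch1_t")]
    ch2 = [c for c in table.columns if c.startswith("ev_ch2_t")]
    if not ch1 or len(ch1) != len(ch2):
        problems.append(
            f"evidence columns unbalanced: {len(ch1)} for channel 1 vs "
            f"{len(ch2)} for channel 2"
        )

    def _rows(mask: pd.Series) -> str:
        idx = list(np.flatnonzero(mask.to_numpy())[:5] + 1)
        return f"rows {idx}"

    bad = ~table["task"].astype(str).isin(_TASKS)
    if bad.any():
        problems.append(f"invalid task values ({_rows(bad)})")
    bad = ~table["world_signal_channel"].astype(str).isin(_WORLD_VALUES)
    if bad.any():
        problems.append(f"invalid world_signal_channel ({_rows(bad)})")
    bad = ~table["decision"].astype(str).isin(_DECISIONS)
    if bad.any():
        problems.append(f"invalid decision values ({_rows(bad)})")
    bad = ~table["correct"].isin([0, 1])
    if bad.any():
        problems.append(f"correct must be 0 or 1 ({_rows(bad)})")
    conf = pd.to_numeric(table["confidence"], errors="coerce")
    bad = conf.isna() | (conf < 0) | (conf > 1)
    if bad.any():
        problems.append(f"confidence outside [0, 1] ({_rows(bad)})")
    if problems:
        _fail(problems)


def read_trial_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise TrialTableValidationError(f"empty input file: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    if table.empty and table.columns.empty:
        raise TrialTableValidationError(f"no header or rows in {path}")
    validate_trial_table(table)
    table["world_signal_channel"] = table["world_signal_channel"].astype(str)
    table["decision"] = table["decision"].astype(str)
    return table


def write_trial_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Validate and write a trial table as UTF-8 CSV at full precision."""
    validate_trial_table(table)
    table.to_csv(path, index=False)
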