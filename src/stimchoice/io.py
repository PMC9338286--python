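"""Canonical trial-table schema and delimited-text round-tripping.

One row per behavioral trial. The same TSV schema is used by the simulator,
the fitting layer, and the session pipeline. Missing values are encoded as
the literal string ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Mandatory columns, in canonical order.
COLUMNS = [
    "session_id",
    "trial_index",
    "condition_window",
    "condition_level",
    "q_A",
    "q_B",
    "order",
    "side_A",
    "forced",
    "stim_on",
    "choice",
    "error_code",
    "rt_ms",
]

ORDERS = ("AB", "BA")
SIDES = ("left", "right")
WINDOWS = ("offer1", "offer2", "none")
CHOICES = ("A", "B")
ERROR_CODES = (
    "no_initiation",
    "center_fix_break",
    "no_choice",
    "peripheral_fix_break",
)


class SchemaError(ValueError):
    """Raised when a trial table lacks a mandatory column."""


class TrialValidationError(ValueError):
    """Raised when trial rows violate the schema's value constraints."""


@dataclass
class TrialRecord:
    """A single behavioral trial."""

    session_id: str
    trial_index: int
    condition_window: str
    condition_level: str
    q_A: int
    q_B: int
    order: str  # AB | BA (which juice appears first)
    side_A: str  # left | right (side of juice A's target)
    forced: int  # 1 if one offer is null (0 drops)
    stim_on: int
    choice: str | None  # A | B | None
    error_code: str | None
    rt_ms: float | None


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for key in ("choice", "error_code"):
            if pd.isna(d[key]):
                d[key] = None
        if pd.isna(d["rt_ms"]):
            d["rt_ms"] = None
        out.append(TrialRecord(**d))
    return out


def validate_trials(df: pd.DataFrame) -> None:
    """Validate a trial table against the canonical schema.

    Raises :class:`SchemaError` for missing columns and
    :class:`TrialValidationError` for invalid values.
    """
    for col in COLUMNS:
        if col not in df.columns:
            raise SchemaError(col)

    if df.empty:
        return

    for col, allowed in [
        ("order", ORDERS),
        ("side_A", SIDES),
        ("condition_window", WINDOWS),
    ]:
        bad = ~df[col].isin(allowed)
        if bad.any():
            raise TrialValidationError(
                f"invalid values in column {col!r}: {sorted(df.loc[bad, col].unique())}"
            )

    for col in ("forced", "stim_on"):
        if not df[col].isin([0, 1]).all():
            raise TrialValidationError(f"column {col!r} must be 0/1")

    q_a = np.asarray(df["q_A"], dtype=float)
    q_b = np.asarray(df["q_B"], dtype=float)
    if np.any(q_a < 0) or np.any(q_b < 0):
        raise TrialValidationError("offered quantities must be >= 0")
    nonforced = df["forced"].to_numpy() == 0
    frac = (q_a != np.floor(q_a)) | (q_b != np.floor(q_b))
    if np.any(frac & nonforced):
        raise TrialValidationError("non-integer quantities on non-forced trials")
    if np.any((q_a[nonforced] < 1) | (q_b[nonforced] < 1)):
        raise TrialValidationError("non-forced trials require q_A >= 1 and q_B >= 1")
    null_count = (q_a == 0).astype(int) + (q_b == 0).astype(int)
    if np.any(null_count[~nonforced] != 1):
        raise TrialValidationError("forced trials must have exactly one null offer")

    choice = df["choice"]
    bad_choice = ~(choice.isna() | choice.isin(CHOICES))
    if bad_choice.any():
        raise TrialValidationError("choice must be A, B, or NA")
    # An error trial carries no choice.
    if (df["error_code"].notna() & choice.notna()).any():
        raise TrialValidationError("error trials must have choice NA")


_READ_DTYPES = {
    "session_id": str,
    "condition_window": str,
    "condition_level": str,
    "order": str,
    "side_A": str,
    "choice": str,
    "error_code": str,
}


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table from TSV, validating the schema."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype=_READ_DTYPES,
        na_values=["NA"],
        keep_default_na=False,
    )
    validate_trials(df)
    df = canonicalize(df)
    return df


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with canonical column order and dtypes."""
    extra = [c for c in df.columns if c not in COLUMNS]
    df = df[COLUMNS + extra].copy()
    for col in ("trial_index", "forced", "stim_on"):
        df[col] = df[col].astype(np.int64)
    for col in ("q_A", "q_B"):
        df[col] = np.asarray(df[col], dtype=float).astype(np.int64)
    df["rt_ms"] = np.asarray(df["rt_ms"], dtype=float)
    for col in ("choice", "error_code"):
        df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table to TSV with NA encoding and fixed float format."""
    validate_trials(df)
    canonicalize(df).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.3f"
    )


def trials_to_string(df: pd.DataFrame) -> str:
    """Serialize to the exact TSV text :func:`write_trials` would produce."""
    validate_trials(df)
    return canonicalize(df).to_csv(
        None, sep="\t", index=False, na_rep="NA", float_format="%.3f"
    )
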