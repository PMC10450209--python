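"""Cohort CSV input/output with schema and invariant validation.

Dialect: comma-separated, UTF-8, dot decimal, header required.  Units are
encoded in the column names (``height_m``, ``mhr_bpm``) to prevent unit
drift.  Row numbers in error messages are 1-based data rows (the header is
row 0).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import COHORT_COLUMNS, PlayerRecord

__all__ = ["read_cohort_csv", "write_cohort_csv", "validate_cohort", "SchemaError"]


class SchemaError(ValueError):
    """The file's columns do not match the cohort schema."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check every row against the PlayerRecord invariants; return df unchanged."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for idx, row in df.iterrows():
        payload = {c: row[c] for c in COHORT_COLUMNS}
        if "trainability" in df.columns and pd.notna(row.get("trainability")):
            payload["trainability"] = row["trainability"]
        try:
            PlayerRecord(**payload)
        except Exception as exc:
            raise ValueError(f"invalid player record at row {idx + 1}: {exc}") from exc
    return df


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table; raises on schema or invariant violations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns: {missing}")
    for col in COHORT_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: non-numeric value in column {col!r}: {exc}") from exc
    df["age"] = df["age"].astype(int)
    return validate_cohort(df)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table at full float precision (round-trip safe)."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in COHORT_COLUMNS
    ]
    df[cols].to_csv(path, index=False, float_format="%.17g")
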