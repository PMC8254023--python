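"""Readers/writers for the long-format trial-table CSV schema.

A trial table holds one row per (trial, recorded time, behavioural type)
with integer occupancy counts: columns ``trial_id``, ``condition``,
``type``, ``time_min``, ``n_ps``, ``n_cs``, ``n_out``.  Times are stored in
minutes (matching how the experiment reports them) while all model rates
are per second; conversion happens only at the simulator boundary.
Validation reports the first offending data row by its position in the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TRIAL_COLUMNS", "SchemaError", "validate_trials", "read_trials", "write_trials"]

TRIAL_COLUMNS = ["trial_id", "condition", "type", "time_min", "n_ps", "n_cs", "n_out"]
_COUNT_COLUMNS = ["time_min", "n_ps", "n_cs", "n_out"]


class SchemaError(ValueError):
    """A trial table violates the schema; the message names the first bad row."""


def _row_label(table: pd.DataFrame, mask) -> str:
    # +2: header line plus 1-based numbering, matching what a user sees in the file
    idx = int(np.flatnonzero(np.asarray(mask))[0])
    return f"row {idx + 2}"


def validate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Validate (and canonically sort) an in-memory trial table.

    Checks the column set, integer non-negative counts, per-trial population
    conservation across times and types, and that every trial shares the
    file's time grid.  Returns the sorted table with ``attrs`` carrying the
    time grid and an ``endpoint_only`` flag (single recorded time: settling
    times are unavailable, endpoint statistics still are).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    table = table.reset_index(drop=True)
    for col in _COUNT_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            raise SchemaError(
                f"{_row_label(table, bad)}: column {col!r} must be a non-negative integer"
            )
        table[col] = vals.astype(np.int64)

    # per (trial, time) total population, then conservation across times
    totals = table.groupby(["trial_id", "time_min"], sort=False)[
        ["n_ps", "n_cs", "n_out"]
    ].sum()
    totals_n = totals.sum(axis=1)
    for tid, sub in totals_n.groupby(level="trial_id"):
        if sub.nunique() != 1:
            n0 = sub.iloc[0]
            bad_time = sub[sub != n0].index[0][1]
            mask = (table["trial_id"] == tid) & (table["time_min"] == bad_time)
            raise SchemaError(
                f"{_row_label(table, mask)}: trial {tid!r} totals {int(sub[(tid, bad_time)])} "
                f"individuals at t={bad_time} but {int(n0)} elsewhere"
            )

    grids = table.groupby("trial_id", sort=False)["time_min"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    ref = grids.iloc[0]
    for tid, g in grids.items():
        if g != ref:
            mask = table["trial_id"] == tid
            raise SchemaError(
                f"{_row_label(table, mask)}: trial {tid!r} uses a different time grid"
            )

    table = table.sort_values(["trial_id", "time_min", "type"], kind="stable").reset_index(
        drop=True
    )
    table.attrs["time_grid"] = list(ref)
    table.attrs["endpoint_only"] = len(ref) == 1
    return table


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype={"trial_id": str, "condition": str, "type": str})
    except Exception as exc:  # noqa: BLE001 - surface the parser message
        raise SchemaError(f"{path}: {exc}") from exc
    try:
        return validate_trials(raw)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table in canonical order with integer formatting.

    Row order (trial_id, time_min, type) is invariant to the input
    permutation, so re-serializing a read file is byte-identical.  An empty
    table yields a header-only file.
    """
    if len(table):
        table = validate_trials(table)
    else:
        table = pd.DataFrame(columns=TRIAL_COLUMNS)
    table.to_csv(path, index=False, columns=TRIAL_COLUMNS)
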