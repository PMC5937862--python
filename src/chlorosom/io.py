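"""Delimited-text readers and writers for transients and feature tables.

Transient files are comma- or tab-delimited text with one time column named
``time_us`` or ``time_s`` followed by one column per sample; ``#``-prefixed
lines are comments.  Files recorded on a different time grid are resampled
onto the standard 118-point grid by linear interpolation at read time.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ojip import STANDARD_GRID, FluorescenceTransient

__all__ = [
    "read_transients",
    "write_transients",
    "read_feature_table",
    "write_feature_table",
]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sniff comma vs tab on the first non-comment line, then parse with the
    # C engine in round-trip float mode so values survive bit-for-bit
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                sep = "\t" if line.count("\t") >= line.count(",") else ","
                break
        else:
            raise ValueError(f"{path}: file contains no data")
    return pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")


def read_transients(path: str | Path) -> list[FluorescenceTransient]:
    """Read fluorescence transients from a delimited-text file.

    The first column must be named ``time_us`` or ``time_s``; every other
    column is one sample.  Times are converted to seconds and, if the file
    grid differs from the standard grid, each sample is linearly
    interpolated onto it (the file grid must span the standard grid).
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column and at least one sample column")
    time_col = df.columns[0]
    if time_col not in ("time_us", "time_s"):
        raise ValueError(f"{path}: first column must be 'time_us' or 'time_s', got {time_col!r}")
    times = df[time_col].to_numpy(dtype=float)
    if np.any(pd.isna(df[time_col])):
        row = int(np.where(pd.isna(df[time_col]))[0][0]) + 1
        raise ValueError(f"{path}: missing time value at data row {row}")
    if time_col == "time_us":
        times = times * 1e-6
    d = np.diff(times)
    if np.any(d <= 0):
        row = int(np.where(d <= 0)[0][0]) + 2
        kind = "duplicate" if np.any(d == 0) else "non-monotone"
        raise ValueError(f"{path}: {kind} time value at data row {row}")

    # 1e-8 covers the writer's 9-significant-digit time format
    on_grid = times.size == STANDARD_GRID.size and np.allclose(
        times, STANDARD_GRID, rtol=1e-8, atol=1e-12
    )
    if not on_grid:
        if times[0] > STANDARD_GRID[0] * (1 + 1e-9) or times[-1] < STANDARD_GRID[-1] * (1 - 1e-9):
            raise ValueError(
                f"{path}: file time range [{times[0]:g}, {times[-1]:g}] s does not "
                f"cover the standard grid [{STANDARD_GRID[0]:g}, {STANDARD_GRID[-1]:g}] s"
            )

    transients = []
    for col in df.columns[1:]:
        values = df[col].to_numpy(dtype=float)
        if np.any(pd.isna(values)):
            t_bad = times[np.where(pd.isna(values))[0][0]]
            raise ValueError(f"{path}: sample {col!r}: missing intensity at t={t_bad:g} s")
        if np.any(values < 0):
            t_bad = times[np.where(values < 0)[0][0]]
            raise ValueError(f"{path}: sample {col!r}: negative intensity at t={t_bad:g} s")
        if not on_grid:
            values = np.interp(STANDARD_GRID, times, values)
        transients.append(FluorescenceTransient(STANDARD_GRID, values, sample_id=str(col)))
    return transients


def write_transients(path: str | Path, transients: Sequence[FluorescenceTransient]) -> None:
    """Write transients as delimited text (``time_s`` with 9 significant digits)."""
    if not transients:
        raise ValueError("no transients to write")
    grid = transients[0].times
    for tr in transients[1:]:
        if not np.array_equal(tr.times, grid):
            raise ValueError("all transients must share one time grid")
    # time_s at 9 significant digits; intensities at full precision so that a
    # write/read cycle reproduces them bit-for-bit.
    columns = {"time_s": [f"{t:.9g}" for t in grid]}
    for tr in transients:
        columns[tr.sample_id] = [f"{v:.17g}" for v in tr.intensity]
    pd.DataFrame(columns).to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a samples-by-features table (first column = sample_id)."""
    df = _read_delimited(path)
    return df.set_index(df.columns[0])


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index_label=table.index.name or "sample_id")
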