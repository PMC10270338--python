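"""Univariate time-series container and plain-CSV ingestion/export.

Every stage of the pipeline consumes and produces :class:`TimeSeries`: an
ordered, finite, univariate real-valued sequence.  Order is meaningful (the
noise injectors guarantee they never shuffle the original points) and is
preserved by every transformation that claims to preserve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "read_series",
    "write_series",
    "read_accelerometer",
    "write_accelerometer",
]


@dataclass
class TimeSeries:
    """Ordered univariate series of length ``n >= 1`` with all values finite.

    Parameters
    ----------
    values
        The observations, coerced to a float64 array.  Units are whatever the
        domain provides (milliseconds for inter-keystroke intervals, g-units
        for acceleration magnitude, vehicles/hour for traffic counts).
    label
        Free-text description carried into reports.
    sample_interval
        Optional spacing between consecutive samples, in seconds.
    """

    values: np.ndarray
    label: str = ""
    sample_interval: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError(f"series must be one-dimensional, got shape {v.shape}")
        if v.size < 1:
            raise ValueError("series must contain at least one value")
        if not np.all(np.isfinite(v)):
            bad = int(np.count_nonzero(~np.isfinite(v)))
            raise ValueError(f"series contains {bad} non-finite value(s)")
        self.values = v

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(values, self.label if label is None else label, self.sample_interval)


def read_series(path, label: str | None = None) -> TimeSeries:
    """Read a series from CSV.

    Accepts a single-column file (one value per line, optional header) or a
    two-column file (ISO-8601 timestamp, value).  For the two-column form only
    the value column is kept; the median timestamp spacing is recorded as
    ``sample_interval`` (seconds).
    """
    df = pd.read_csv(path, header=None)
    # Header detection keys on the value (last) column: timestamps in the
    # first column are legitimately non-numeric.
    try:
        float(df.iloc[0, -1])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 1:
        values = df.iloc[:, 0].astype(float).to_numpy()
        interval = None
    elif df.shape[1] == 2:
        ts = pd.to_datetime(df.iloc[:, 0], format="ISO8601")
        values = df.iloc[:, 1].astype(float).to_numpy()
        deltas = ts.diff().dropna().dt.total_seconds()
        interval = float(deltas.median()) if len(deltas) else None
    else:
        raise ValueError(f"expected 1 or 2 columns, got {df.shape[1]}")
    return TimeSeries(values, label or str(path), interval)


def write_series(series: TimeSeries, path, header: bool = True) -> None:
    """Write a series as single-column CSV."""
    df = pd.DataFrame({"value": series.values})
    df.to_csv(path, index=False, header=header)


def read_accelerometer(path):
    """Read a 4-column accelerometer CSV (timestamp, x, y, z).

    Returns ``(timestamps_seconds, xyz)`` where timestamps are float seconds
    relative to the first sample and ``xyz`` is an (n, 3) float array.
    """
    df = pd.read_csv(path, header=None)
    try:
        float(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] != 4:
        raise ValueError(f"expected 4 columns (timestamp, x, y, z), got {df.shape[1]}")
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
    except (ValueError, TypeError):
        ts = pd.to_datetime(df.iloc[:, 0], format="ISO8601")
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    xyz = df.iloc[:, 1:4].astype(float).to_numpy()
    if not np.all(np.isfinite(xyz)):
        raise ValueError("accelerometer trace contains non-finite components")
    return t, xyz


def write_accelerometer(timestamps, xyz, path) -> None:
    """Write a triaxial trace as 4-column CSV (timestamp, x, y, z)."""
    xyz = np.asarray(xyz, dtype=np.float64)
    pd.DataFrame(
        {
            "timestamp": np.asarray(timestamps, dtype=np.float64),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    ).to_csv(path, index=False)
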