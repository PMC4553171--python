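"""Uniformly sampled scalar time series: the currency passed between stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    t : ndarray
        Strictly increasing, uniformly spaced time stamps in seconds.
    x : ndarray
        Series values (unitless), same length as ``t``.
    """

    t: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        if t.ndim != 1 or x.ndim != 1 or t.size != x.size:
            raise ValueError("t and x must be 1-d arrays of equal length")
        if t.size < 2:
            raise ValueError("a time series needs at least two samples")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9 * max(1.0, abs(dt[0]))):
            raise ValueError("time stamps must be uniformly spaced")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("non-finite values in time series")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return int(self.t.size)


def sample_series(ts: TimeSeries, every: float) -> TimeSeries:
    """Decimate a series to one sample per ``every`` seconds.

    ``every`` must be a (near-)integer multiple of the native spacing;
    time stamps of retained samples are preserved.
    """
    ratio = every / ts.dt
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-8:
        raise ValueError(
            f"sampling interval {every} is not a multiple of native spacing {ts.dt}"
        )
    return TimeSeries(ts.t[::stride], ts.x[::stride])


def write_series(ts: TimeSeries, path: str | Path) -> None:
    """Write a series as two-column delimited text with header ``t,x``."""
    pd.DataFrame({"t": ts.t, "x": ts.x}).to_csv(path, index=False, float_format="%.17g")


def read_series(path: str | Path) -> TimeSeries:
    """Read a two-column delimited text series (header ``t,x`` or none)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value)")
    return TimeSeries(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))
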