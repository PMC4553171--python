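"""Noise injection, delay embedding, normalization and train/validation split.

The forecasting benchmark corrupts the whole series with i.i.d. Gaussian
white noise (x_i = x_i^noiseless + eta_i, eta_i ~ N(0, sigma_N^2)), builds
supervised patterns from delay coordinates

    input  [x(t - (d-1)*Delta), ..., x(t - Delta), x(t)]  ->  target x(t + T)

with the standard d = 4, Delta = T = 6, and splits the patterns in temporal
order (first block trains, remainder validates).  Values are scaled to
[-1, 1] by an affine map fitted on the training half only; all reported
errors live on the raw (denormalized) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries


@dataclass(frozen=True)
class NoiseSpec:
    """White-noise corruption: std dev ``sigma_n`` per element, RNG ``seed``."""

    sigma_n: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding geometry: ``d`` taps spaced ``delta`` s, horizon ``horizon`` s."""

    d: int = 4
    delta: float = 6.0
    horizon: float = 6.0

    def __post_init__(self) -> None:
        if self.d < 1 or self.delta <= 0 or self.horizon <= 0:
            raise ValueError("d >= 1, delta > 0 and horizon > 0 are required")


@dataclass(frozen=True)
class EmbeddedDataset:
    """Supervised patterns from a delay embedding.

    ``inputs`` is (n, d) with taps ordered oldest first, ``targets`` (n,),
    ``base_times`` (n,) the time stamp of each pattern's most recent tap.
    """

    inputs: np.ndarray
    targets: np.ndarray
    base_times: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.inputs) == len(self.targets) == len(self.base_times)):
            raise ValueError("inputs, targets and base_times must have equal length")

    def __len__(self) -> int:
        return int(len(self.targets))


def add_white_noise(ts: TimeSeries, spec: NoiseSpec) -> TimeSeries:
    """Add element-wise Gaussian noise N(0, sigma_n^2); deterministic per seed."""
    if spec.sigma_n == 0:
        return ts
    rng = np.random.default_rng(spec.seed)
    return TimeSeries(ts.t, ts.x + rng.normal(0.0, spec.sigma_n, size=len(ts)))


def build_embedding(ts: TimeSeries, spec: EmbeddingSpec = EmbeddingSpec()) -> EmbeddedDataset:
    """Build delay-embedded patterns anchored at their most recent tap.

    A pattern exists for every anchor time t with all taps and the target
    inside the series: t ranges over [(d-1)*delta, t_end - horizon].
    """
    lag = spec.delta / ts.dt
    lead = spec.horizon / ts.dt
    if abs(lag - round(lag)) > 1e-8 or abs(lead - round(lead)) > 1e-8:
        raise ValueError("delta and horizon must be multiples of the sampling interval")
    lag, lead = int(round(lag)), int(round(lead))
    first = (spec.d - 1) * lag
    last = len(ts) - 1 - lead
    if last < first:
        raise ValueError("series too short for a single embedded pattern")
    anchors = np.arange(first, last + 1)
    taps = anchors[:, None] - lag * np.arange(spec.d - 1, -1, -1)[None, :]
    return EmbeddedDataset(
        inputs=ts.x[taps],
        targets=ts.x[anchors + lead],
        base_times=ts.t[anchors],
    )


def train_test_split(ds: EmbeddedDataset, n_train: int = 1000) -> tuple[EmbeddedDataset, EmbeddedDataset]:
    """Split patterns in temporal order: first ``n_train`` train, rest validate."""
    if not 0 < n_train < len(ds):
        raise ValueError(f"n_train must be in (0, {len(ds)})")
    cut = n_train
    return (
        EmbeddedDataset(ds.inputs[:cut], ds.targets[:cut], ds.base_times[:cut]),
        EmbeddedDataset(ds.inputs[cut:], ds.targets[cut:], ds.base_times[cut:]),
    )


@dataclass(frozen=True)
class Scaler:
    """Affine map [in_min, in_max] -> [out_min, out_max] with exact inverse."""

    in_min: float
    in_max: float
    out_min: float = -1.0
    out_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.in_max > self.in_min:
            raise ValueError("degenerate range: in_max must exceed in_min")

    @property
    def gain(self) -> float:
        return (self.out_max - self.out_min) / (self.in_max - self.in_min)

    def transform(self, values: np.ndarray | float) -> np.ndarray | float:
        return self.out_min + (np.asarray(values) - self.in_min) * self.gain

    def inverse(self, values: np.ndarray | float) -> np.ndarray | float:
        return self.in_min + (np.asarray(values) - self.out_min) / self.gain


def fit_scaler(train: EmbeddedDataset, out_range: tuple[float, float] = (-1.0, 1.0)) -> Scaler:
    """Fit the [-1, 1] scaler on the training inputs and targets only.

    Validation values may fall outside the output range; that is intended
    (no leakage of the validation half into the normalization).
    """
    lo = min(float(train.inputs.min()), float(train.targets.min()))
    hi = max(float(train.inputs.max()), float(train.targets.max()))
    return Scaler(lo, hi, out_range[0], out_range[1])


def write_dataset(ds: EmbeddedDataset, path: str | Path) -> None:
    """Persist patterns as delimited text: columns t, x1..xd, target."""
    d = ds.inputs.shape[1]
    df = pd.DataFrame(ds.inputs, columns=[f"x{i+1}" for i in range(d)])
    df.insert(0, "t", ds.base_times)
    df["target"] = ds.targets
    df.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> EmbeddedDataset:
    df = pd.read_csv(path)
    tap_cols = [c for c in df.columns if c.startswith("x")]
    return EmbeddedDataset(
        inputs=df[tap_cols].to_numpy(float),
        targets=df["target"].to_numpy(float),
        base_times=df["t"].to_numpy(float),
    )
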