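"""Hidden-layer size sweep and the linear noise laws.

For each noise level the hidden-layer size N_HL is swept (2..30 in the full
benchmark), the best validation RMSE over restarts recorded, and the
RMSE-minimizing size selected (ties to the smaller network).  Two linear
laws summarize the sweep: a zero-intercept fit RMSE = m * sigma_N over the
noisy levels, and an ordinary least-squares fit N_HL = a * sigma_N + b for
the selected sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Topology
from .preprocess import EmbeddedDataset, Scaler
from .pso import PSOConfig, TrainingResult, best_result, train_restarts


@dataclass
class SweepRow:
    """Best result at one (sigma_n, n_hidden) cell."""

    sigma_n: float
    n_hidden: int
    train_rmse: float
    valid_rmse: float
    seed: int


@dataclass
class SweepResult:
    """Sweep rows for one noise level plus the selected architecture."""

    sigma_n: float
    rows: list[SweepRow]
    selected_n_hidden: int
    best_valid_rmse: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def sweep_hidden(train_set: EmbeddedDataset, valid_set: EmbeddedDataset,
                 scaler: Scaler, n_hl_range=range(2, 31),
                 config: PSOConfig = PSOConfig(),
                 sigma_n: float = 0.0,
                 seeds=(0, 1, 2)) -> SweepResult:
    """Train at every hidden size in ``n_hl_range`` and select the argmin.

    Each cell runs ``len(seeds)`` independent restarts and keeps the best
    validation RMSE.  Ties across sizes break toward the smaller network.
    """
    sizes = list(n_hl_range)
    if not sizes:
        raise ValueError("empty hidden-size range")
    rows: list[SweepRow] = []
    for n_hl in sizes:
        results = train_restarts(train_set, Topology(train_set.inputs.shape[1], n_hl, 1),
                                 config, scaler, valid_set, seeds=seeds)
        best = best_result(results)
        rows.append(SweepRow(sigma_n, n_hl, best.best_rmse,
                             float(best.validation_rmse), best.seed))
    best_row = min(rows, key=lambda r: (r.valid_rmse, r.n_hidden))
    return SweepResult(sigma_n, rows, best_row.n_hidden, best_row.valid_rmse)


def performance_efficiency(rmse_noisy: float, rmse_noiseless: float) -> float:
    """Degradation ratio xi = RMSE_noisy / RMSE_noiseless (1 for the clean case)."""
    if rmse_noiseless <= 0:
        raise ValueError("noiseless RMSE must be positive")
    return rmse_noisy / rmse_noiseless


def fit_rmse_slope(sigmas: np.ndarray, rmses: np.ndarray) -> float:
    """Zero-intercept least squares RMSE = m * sigma over the noisy levels.

    The noiseless point is excluded by the caller; closed form
    m = sum(rmse*sigma) / sum(sigma^2).
    """
    sigmas = np.asarray(sigmas, dtype=float)
    rmses = np.asarray(rmses, dtype=float)
    if sigmas.size < 2:
        raise ValueError("need at least two noisy levels")
    if np.any(sigmas <= 0):
        raise ValueError("zero-intercept fit is over strictly noisy levels")
    return float(np.sum(rmses * sigmas) / np.sum(sigmas ** 2))


def fit_nhl_law(sigmas: np.ndarray, n_hls: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares N_HL = a*sigma + b; returns (a, b)."""
    sigmas = np.asarray(sigmas, dtype=float)
    n_hls = np.asarray(n_hls, dtype=float)
    if sigmas.size < 2:
        raise ValueError("need at least two levels")
    a, b = np.polyfit(sigmas, n_hls, 1)
    return float(a), float(b)


def fit_linear_laws(sweeps: list[SweepResult]) -> dict:
    """Fit both noise laws from per-level sweep results.

    Uses every level with sigma_n > 0 for the zero-intercept RMSE law and all
    levels for the N_HL law.  Returns a dict with keys ``rmse_slope``,
    ``nhl_slope``, ``nhl_intercept``.
    """
    noisy = [s for s in sweeps if s.sigma_n > 0]
    sig = np.array([s.sigma_n for s in noisy])
    rmse = np.array([s.best_valid_rmse for s in noisy])
    slope = fit_rmse_slope(sig, rmse)
    all_sig = np.array([s.sigma_n for s in sweeps])
    all_nhl = np.array([s.selected_n_hidden for s in sweeps])
    a, b = fit_nhl_law(all_sig, all_nhl)
    return {"rmse_slope": slope, "nhl_slope": a, "nhl_intercept": b}
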