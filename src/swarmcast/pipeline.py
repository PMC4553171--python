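"""End-to-end benchmark orchestration with deterministic seed management.

The three canonical experiments:

* ``run_noiseless_benchmark`` — simulate, embed, split, train with restarts,
  report train/validation RMSE and residual summaries for the clean series.
* ``run_noise_grid`` — repeat over the white-noise levels (each at its
  selected hidden size), compute the degradation ratio xi per level and fit
  the linear noise laws RMSE = m*sigma_N and N_HL = a*sigma_N + b.
* ``run_uq`` — push the noisy validation inputs through the trained network
  with Gaussian resampling and summarize the per-point uncertainties.

Every stage seed is a deterministic hash of (master seed, stage name,
repetition index), so adding stages never perturbs existing ones and reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mackey_glass import MGParams, integrate_mg
from .network import Topology
from .preprocess import (EmbeddedDataset, EmbeddingSpec, NoiseSpec, Scaler,
                         add_white_noise, build_embedding, fit_scaler,
                         train_test_split)
from .pso import PSOConfig, TrainingResult, best_result, fitness_rmse, train_restarts
from .sweep import (SweepResult, SweepRow, fit_nhl_law, fit_rmse_slope,
                    performance_efficiency, sweep_hidden)
from .timeseries import TimeSeries
from .uncertainty import EnsembleSpec, coverage_check, predict_with_uncertainty

#: hidden-layer sizes selected by the architecture sweep at each noise level
SELECTED_HIDDEN = {0.0: 6, 0.01: 6, 0.04: 11, 0.06: 14, 0.08: 15, 0.1: 20}


def stage_seed(master_seed: int, stage: str, rep: int = 0) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}/{stage}/{rep}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Aggregated settings of the full benchmark.

    Defaults are the study conditions: a 2000-point series (t = 0..1999 s),
    d=4 taps at 6 s spacing predicting 6 s ahead, first 1000 patterns for
    training, swarm settings from the tuned benchmark, five restart seeds
    per training, and a 1000-member Monte-Carlo ensemble.
    """

    mg: MGParams = field(default_factory=lambda: MGParams(t_horizon=1999.0))
    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    n_train: int = 1000
    sigmas: tuple[float, ...] = (0.01, 0.04, 0.06, 0.08, 0.1)
    pso: PSOConfig = field(default_factory=PSOConfig)
    n_restarts: int = 5
    k_sims: int = 1000
    master_seed: int = 0

    def fast_profile(self) -> "ExperimentConfig":
        """Reduced profile for smoke runs: 300 iterations, one restart."""
        return replace(self, pso=replace(self.pso, k_max=300), n_restarts=1)


@dataclass
class DataBundle:
    """Everything produced upstream of training for one noise level."""

    sigma_n: float
    series: TimeSeries
    train_set: EmbeddedDataset
    valid_set: EmbeddedDataset
    scaler: Scaler
    noise_seed: int


def prepare_data(config: ExperimentConfig, sigma_n: float = 0.0,
                 clean: TimeSeries | None = None) -> DataBundle:
    """Simulate (or reuse) the clean series, corrupt, embed, split, fit scaler."""
    if clean is None:
        clean = integrate_mg(config.mg)
    noise_seed = stage_seed(config.master_seed, f"noise/sigma={sigma_n:g}")
    series = add_white_noise(clean, NoiseSpec(sigma_n, noise_seed))
    ds = build_embedding(series, config.embedding)
    train_set, valid_set = train_test_split(ds, config.n_train)
    scaler = fit_scaler(train_set)
    return DataBundle(sigma_n, series, train_set, valid_set, scaler, noise_seed)


def train_level(bundle: DataBundle, n_hidden: int,
                config: ExperimentConfig) -> TrainingResult:
    """Best-of-restarts training at one noise level and hidden size."""
    seeds = [stage_seed(config.master_seed,
                        f"train/sigma={bundle.sigma_n:g}/nhl={n_hidden}", i)
             for i in range(config.n_restarts)]
    topo = Topology(bundle.train_set.inputs.shape[1], n_hidden, 1)
    results = train_restarts(bundle.train_set, topo, config.pso,
                             bundle.scaler, bundle.valid_set, seeds=seeds)
    return best_result(results)


def run_noiseless_benchmark(config: ExperimentConfig,
                            n_hidden: int = 6) -> dict:
    """Clean-series benchmark: train/validation RMSE and residual summary."""
    bundle = prepare_data(config, 0.0)
    best = train_level(bundle, n_hidden, config)
    report = {"n_hidden": n_hidden,
              "train_rmse": best.best_rmse,
              "valid_rmse": float(best.validation_rmse),
              "seed": best.seed,
              "master_seed": config.master_seed}
    from .network import forward
    for name, ds in (("train", bundle.train_set), ("valid", bundle.valid_set)):
        y = bundle.scaler.inverse(
            forward(best.best_network, bundle.scaler.transform(ds.inputs)))
        resid = ds.targets - y
        report[f"{name}_residual_mean"] = float(np.mean(resid))
        report[f"{name}_residual_max"] = float(np.max(np.abs(resid)))
    report["_network"] = best.best_network
    report["_scaler"] = bundle.scaler
    report["_bundle"] = bundle
    return report


def run_noise_grid(config: ExperimentConfig,
                   hidden_sizes: dict[float, int] | None = None,
                   do_sweep: bool = False) -> dict:
    """Noise-robustness grid: per-level RMSE, xi, and the linear noise laws.

    ``hidden_sizes`` maps sigma_N to the hidden size used at that level
    (defaults to the sweep-selected sizes); ``do_sweep=True`` re-runs the
    full architecture sweep at every level instead.
    """
    hidden_sizes = dict(SELECTED_HIDDEN if hidden_sizes is None else hidden_sizes)
    clean = integrate_mg(config.mg)
    levels = (0.0,) + tuple(config.sigmas)
    rows = []
    trained: dict[float, tuple[TrainingResult, DataBundle]] = {}
    for sigma in levels:
        bundle = prepare_data(config, sigma, clean=clean)
        if do_sweep:
            seeds = [stage_seed(config.master_seed,
                                f"sweep/sigma={sigma:g}", i)
                     for i in range(config.n_restarts)]
            sw = sweep_hidden(bundle.train_set, bundle.valid_set, bundle.scaler,
                              config=config.pso, sigma_n=sigma, seeds=seeds)
            n_hl, rmse = sw.selected_n_hidden, sw.best_valid_rmse
            best = None
        else:
            n_hl = hidden_sizes.get(sigma, hidden_sizes.get(round(sigma, 3), 6))
            best = train_level(bundle, n_hl, config)
            rmse = float(best.validation_rmse)
        rows.append({"sigma_n": sigma, "n_hidden": n_hl, "valid_rmse": rmse})
        trained[sigma] = (best, bundle)
    table = pd.DataFrame(rows)
    rmse0 = table.loc[table.sigma_n == 0, "valid_rmse"].iloc[0]
    table["xi"] = [performance_efficiency(r, rmse0) for r in table.valid_rmse]
    noisy = table[table.sigma_n > 0]
    laws = {
        "rmse_slope": (fit_rmse_slope(noisy.sigma_n.to_numpy(),
                                      noisy.valid_rmse.to_numpy())
                       if len(noisy) >= 2 else None),
    }
    laws["nhl_slope"], laws["nhl_intercept"] = fit_nhl_law(
        table.sigma_n.to_numpy(), table.n_hidden.to_numpy())
    return {"table": table, "laws": laws, "_trained": trained,
            "master_seed": config.master_seed}


def run_uq(config: ExperimentConfig, sigma_n: float = 0.1,
           n_hidden: int | None = None,
           trained: tuple[TrainingResult, DataBundle] | None = None) -> dict:
    """Stochastic prediction on the noisy validation half.

    Reports the mean/min/max per-point uncertainty, its ratio to the input
    noise level, agreement between ensemble and point predictions, and the
    one-sigma coverage of the noisy targets.
    """
    if trained is None:
        bundle = prepare_data(config, sigma_n)
        n_hl = n_hidden if n_hidden is not None else SELECTED_HIDDEN.get(sigma_n, 6)
        best = train_level(bundle, n_hl, config)
    else:
        best, bundle = trained
    spec = EnsembleSpec(config.k_sims, sigma_n,
                        stage_seed(config.master_seed, f"uq/sigma={sigma_n:g}"))
    pred = predict_with_uncertainty(best.best_network, bundle.scaler,
                                    bundle.valid_set.inputs, spec,
                                    times=bundle.valid_set.base_times)
    truth = bundle.valid_set.targets
    resid_ens = truth - pred.y_hat
    resid_point = truth - pred.y_point
    combined = np.sqrt(pred.sigma_y ** 2 + sigma_n ** 2)
    report = {
        "sigma_n": sigma_n,
        "n_hidden": best.best_network.topology.n_hidden,
        "mean_sigma_y": float(pred.sigma_y.mean()),
        "min_sigma_y": float(pred.sigma_y.min()),
        "max_sigma_y": float(pred.sigma_y.max()),
        "sigma_ratio": float(pred.sigma_y.mean() / sigma_n) if sigma_n else 0.0,
        "rmse_ensemble": float(np.sqrt(np.mean(resid_ens ** 2))),
        "rmse_point": float(np.sqrt(np.mean(resid_point ** 2))),
        "coverage_1sigma": coverage_check(pred, truth),
        "coverage_1sigma_combined": float(np.mean(np.abs(resid_ens) <= combined)),
        "master_seed": config.master_seed,
    }
    report["_prediction"] = pred
    return report
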