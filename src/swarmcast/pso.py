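"""Inertia-weight particle swarm optimization of network parameters.

Each particle is a full flat parameter vector of the forecasting network.
Velocities follow the standard inertia-weight rule

    v <- omega*v + c1*r1*(pbest - s) + c2*r2*(gbest - s),   s <- s + v

with r1, r2 drawn per dimension, per particle, per iteration; velocity
components are clamped to +-v_max and positions to the weight/bias box.
The inertia weight decreases linearly (0.7 -> 0.5 by default) over the run.
Fitness is the root-mean-square prediction error on the raw (denormalized)
scale, evaluated on the training patterns only; the global best is updated
synchronously after all particles are evaluated, so its fitness is
monotonically non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network import NetworkParameters, Topology, forward, forward_population, init_box
from .preprocess import EmbeddedDataset, Scaler


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyperparameters (defaults follow the tuned benchmark settings)."""

    n_particles: int = 50
    k_max: int = 1500
    c1: float = 1.494
    c2: float = 1.494
    omega_max: float = 0.7
    omega_min: float = 0.5
    v_max: float = 12.0
    min_error: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least two particles")
        if self.omega_max < self.omega_min:
            raise ValueError("omega_max must be >= omega_min")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass
class TrainingResult:
    """Outcome of one swarm training run."""

    best_network: NetworkParameters
    best_rmse: float                 # training-set RMSE of the global best
    rmse_history: np.ndarray         # global-best RMSE after each iteration
    iterations_run: int
    seed: int
    validation_rmse: float | None = None


def inertia_at(k: int, config: PSOConfig) -> float:
    """Linearly decreasing inertia weight: omega_max at k=0, omega_min at k_max-1."""
    if not 0 <= k < config.k_max:
        raise ValueError(f"iteration {k} outside [0, {config.k_max})")
    if config.k_max == 1:
        return config.omega_max
    frac = k / (config.k_max - 1)
    return config.omega_max - (config.omega_max - config.omega_min) * frac


def velocity_update(velocity: np.ndarray, position: np.ndarray,
                    personal_best: np.ndarray, global_best: np.ndarray,
                    omega: float, config: PSOConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """One velocity step; r1, r2 fresh per dimension, result clamped to +-v_max.

    Operates on a single particle (1-d arrays) or a whole swarm (2-d, one row
    per particle).
    """
    r1 = rng.uniform(size=position.shape)
    r2 = rng.uniform(size=position.shape)
    v = (omega * velocity
         + config.c1 * r1 * (personal_best - position)
         + config.c2 * r2 * (global_best - position))
    return np.clip(v, -config.v_max, config.v_max)


def position_update(position: np.ndarray, velocity: np.ndarray,
                    lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Move by the updated velocity, then clip into the search box."""
    return np.clip(position + velocity, lower, upper)


def pso_minimize(objective: Callable[[np.ndarray], np.ndarray],
                 lower: np.ndarray, upper: np.ndarray,
                 config: PSOConfig,
                 init_lower: np.ndarray | None = None,
                 init_upper: np.ndarray | None = None) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize a batched objective over a box with the inertia-weight swarm.

    ``objective`` maps a (P, D) position array to a (P,) fitness array.
    Positions are seeded uniformly in the (optional) initialization box —
    by default the full search box — and always clamped to [lower, upper]
    afterwards.  Returns (best position, best fitness, per-iteration
    best-fitness history).  Fully deterministic for a fixed ``config.seed``.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    init_lower = lower if init_lower is None else np.asarray(init_lower, dtype=float)
    init_upper = upper if init_upper is None else np.asarray(init_upper, dtype=float)
    rng = np.random.default_rng(config.seed)
    P = config.n_particles

    positions = rng.uniform(init_lower, init_upper, size=(P, lower.size))
    velocities = rng.uniform(-config.v_max, config.v_max, size=(P, lower.size))

    fitness = np.asarray(objective(positions), dtype=float)
    pbest = positions.copy()
    pbest_f = fitness.copy()
    g = int(np.argmin(pbest_f))          # ties -> lowest particle index
    gbest = pbest[g].copy()
    gbest_f = float(pbest_f[g])

    history = np.empty(config.k_max)
    history[0] = gbest_f
    k = 0
    for k in range(config.k_max):
        if k > 0:
            fitness = np.asarray(objective(positions), dtype=float)
            improved = fitness < pbest_f
            pbest[improved] = positions[improved]
            pbest_f[improved] = fitness[improved]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < gbest_f:
                gbest = pbest[g].copy()
                gbest_f = float(pbest_f[g])
            history[k] = gbest_f
        if gbest_f < config.min_error:
            break
        omega = inertia_at(k, config)
        velocities = velocity_update(velocities, positions, pbest, gbest,
                                     omega, config, rng)
        positions = position_update(positions, velocities, lower, upper)

    return gbest, gbest_f, history[:k + 1]


def _raw_scale_rmse(outputs_norm: np.ndarray, targets_raw: np.ndarray,
                    scaler: Scaler | None) -> np.ndarray:
    y = scaler.inverse(outputs_norm) if scaler is not None else outputs_norm
    resid = y - targets_raw
    return np.sqrt(np.mean(resid * resid, axis=-1))


def fitness_rmse(net: NetworkParameters, dataset: EmbeddedDataset,
                 scaler: Scaler | None = None) -> float:
    """RMSE between targets and denormalized network outputs (raw scale).

    ``dataset`` holds raw-scale patterns; inputs are normalized through
    ``scaler`` before the forward pass and outputs mapped back.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    x = scaler.transform(dataset.inputs) if scaler is not None else dataset.inputs
    y_norm = forward(net, x)
    return float(_raw_scale_rmse(np.atleast_1d(y_norm), dataset.targets, scaler))


def fitness_weighted(net: NetworkParameters, dataset: EmbeddedDataset,
                     sigma_per_element: np.ndarray | float,
                     scaler: Scaler | None = None,
                     literal: bool = False) -> float:
    """Noise-weighted fitness sqrt((1/n) sum r_i^2 / sigma_i^2).

    With constant sigma this equals ``fitness_rmse / sigma``.  ``literal=True``
    returns the unrooted weighted mean square (the dimensionally inconsistent
    variant, kept for auditing).
    """
    sigma = np.broadcast_to(np.asarray(sigma_per_element, dtype=float),
                            dataset.targets.shape)
    if np.any(sigma <= 0):
        raise ValueError("all sigma values must be positive")
    x = scaler.transform(dataset.inputs) if scaler is not None else dataset.inputs
    y_norm = np.atleast_1d(forward(net, x))
    y = scaler.inverse(y_norm) if scaler is not None else y_norm
    mean_weighted_sq = float(np.mean(((y - dataset.targets) / sigma) ** 2))
    return mean_weighted_sq if literal else float(np.sqrt(mean_weighted_sq))


def train(dataset: EmbeddedDataset, topology: Topology, config: PSOConfig,
          scaler: Scaler | None = None,
          validation: EmbeddedDataset | None = None) -> TrainingResult:
    """Train the network on ``dataset`` by swarm search over the parameter box.

    Fitness is raw-scale training RMSE; the run stops at ``k_max`` iterations
    or when the global best drops below ``min_error``.  If ``validation`` is
    given its RMSE is computed once for the final network and never touches
    the search.  Deterministic per (seed, config, dataset).
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if np.ptp(dataset.targets) == 0:
        pass  # constant targets are legal (trivially learnable), not an error
    x = scaler.transform(dataset.inputs) if scaler is not None else dataset.inputs
    x = np.ascontiguousarray(x, dtype=float)
    targets = dataset.targets
    lower, upper = topology.param_bounds()
    ini_lo, ini_hi = init_box(topology)

    def objective(thetas: np.ndarray) -> np.ndarray:
        out = forward_population(topology, thetas, x)
        return _raw_scale_rmse(out, targets, scaler)

    gbest, gbest_f, history = pso_minimize(objective, lower, upper, config,
                                           init_lower=ini_lo, init_upper=ini_hi)
    net = NetworkParameters(topology, gbest)
    result = TrainingResult(
        best_network=net,
        best_rmse=gbest_f,
        rmse_history=history,
        iterations_run=len(history),
        seed=config.seed,
    )
    if validation is not None:
        result.validation_rmse = fitness_rmse(net, validation, scaler)
    return result


def train_restarts(dataset: EmbeddedDataset, topology: Topology,
                   config: PSOConfig, scaler: Scaler | None = None,
                   validation: EmbeddedDataset | None = None,
                   seeds: Sequence[int] = (0, 1, 2, 3, 4)) -> list[TrainingResult]:
    """Run independent restarts (one per seed); returns all results.

    The swarm search is stochastic, so several restarts are run and the best
    kept; callers rank by validation RMSE when a validation set is supplied,
    else by training RMSE.
    """
    results = []
    for s in seeds:
        cfg = PSOConfig(**{**config.__dict__, "seed": int(s)})
        results.append(train(dataset, topology, cfg, scaler, validation))
    return results


def best_result(results: Sequence[TrainingResult]) -> TrainingResult:
    """Pick the best restart: lowest validation RMSE if available, else training."""
    if any(r.validation_rmse is not None for r in results):
        return min(results, key=lambda r: (r.validation_rmse
                                           if r.validation_rmse is not None
                                           else np.inf))
    return min(results, key=lambda r: r.best_rmse)
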