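"""Feed-forward 4-N_HL-1 network evaluated from a flat parameter vector.

A single hidden layer of hyperbolic-tangent units feeds a linear output
neuron.  All parameters live in one flat vector (theta) ordered as

    [hidden weights (one row per hidden neuron), hidden biases,
     output weights, output bias]

so that a network doubles as a particle position for the swarm optimizer.
Weights are confined to [-100, 100] and biases to [-10, 10], the box the
swarm searches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

WEIGHT_BOUND = 100.0
BIAS_BOUND = 10.0


@dataclass(frozen=True)
class Topology:
    """Layer sizes: ``n_in`` inputs, ``n_hidden`` tanh units, ``n_out`` linear outputs."""

    n_in: int = 4
    n_hidden: int = 6
    n_out: int = 1

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be >= 1")

    @property
    def n_params(self) -> int:
        return (self.n_in * self.n_hidden + self.n_hidden
                + self.n_hidden * self.n_out + self.n_out)

    def param_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Component-wise (lower, upper) box for the flat parameter vector."""
        lo = np.empty(self.n_params)
        hi = np.empty(self.n_params)
        nw_h = self.n_in * self.n_hidden
        nb_h = self.n_hidden
        nw_o = self.n_hidden * self.n_out
        sections = [(nw_h, WEIGHT_BOUND), (nb_h, BIAS_BOUND),
                    (nw_o, WEIGHT_BOUND), (self.n_out, BIAS_BOUND)]
        pos = 0
        for size, bound in sections:
            lo[pos:pos + size] = -bound
            hi[pos:pos + size] = bound
            pos += size
        return lo, hi


@dataclass(frozen=True)
class NetworkParameters:
    """A topology plus the flat parameter vector ``theta``."""

    topology: Topology
    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        object.__setattr__(self, "theta", theta)
        if theta.shape != (self.topology.n_params,):
            raise ValueError(
                f"theta length {theta.size} != expected {self.topology.n_params}"
            )


def tansig(v):
    """Hyperbolic-tangent sigmoid (e^v - e^-v)/(e^v + e^-v).

    Delegates to ``np.tanh``, which saturates to +-1 without overflow.
    """
    return np.tanh(v)


def unpack(topology: Topology, theta: np.ndarray):
    """Split a flat theta into (W_hidden, b_hidden, W_out, b_out).

    ``W_hidden`` is (n_hidden, n_in) with one row per hidden neuron;
    ``W_out`` is (n_out, n_hidden).  Works on a batch ``theta`` of shape
    (..., n_params) as well, returning leading batch axes intact.
    """
    t = topology
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != t.n_params:
        raise ValueError("theta length mismatch")
    batch = theta.shape[:-1]
    i = 0
    w_h = theta[..., i:i + t.n_in * t.n_hidden].reshape(*batch, t.n_hidden, t.n_in)
    i += t.n_in * t.n_hidden
    b_h = theta[..., i:i + t.n_hidden]
    i += t.n_hidden
    w_o = theta[..., i:i + t.n_hidden * t.n_out].reshape(*batch, t.n_out, t.n_hidden)
    i += t.n_hidden * t.n_out
    b_o = theta[..., i:i + t.n_out]
    return w_h, b_h, w_o, b_o


def pack(topology: Topology, w_h, b_h, w_o, b_o) -> np.ndarray:
    """Inverse of :func:`unpack`: flatten structured parameters into theta."""
    t = topology
    parts = [np.asarray(w_h).reshape(-1), np.asarray(b_h).reshape(-1),
             np.asarray(w_o).reshape(-1), np.asarray(b_o).reshape(-1)]
    theta = np.concatenate(parts)
    if theta.size != t.n_params:
        raise ValueError("structured parameter shapes do not match topology")
    return theta


def forward(net: NetworkParameters, inputs: np.ndarray) -> np.ndarray | float:
    """Evaluate the network on one input vector or a batch of rows.

    Returns a scalar for a single d-vector, a 1-d array for an (n, d) batch
    (single-output networks).
    """
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != net.topology.n_in:
        raise ValueError(f"input width {x.shape[1]} != n_in {net.topology.n_in}")
    w_h, b_h, w_o, b_o = unpack(net.topology, net.theta)
    hidden = tansig(x @ w_h.T + b_h)
    out = hidden @ w_o.T + b_o
    if net.topology.n_out == 1:
        out = out[:, 0]
    return float(out[0]) if single else out


def forward_population(topology: Topology, thetas: np.ndarray,
                       inputs: np.ndarray) -> np.ndarray:
    """Evaluate a population of parameter vectors on a shared input batch.

    ``thetas`` is (P, n_params), ``inputs`` (n, n_in); returns (P, n) outputs
    for single-output networks.  One BLAS call services the whole swarm,
    which is what keeps swarm training tractable.
    """
    if topology.n_out != 1:
        raise ValueError("population forward pass supports single-output networks")
    thetas = np.asarray(thetas, dtype=float)
    x = np.asarray(inputs, dtype=float)
    P = thetas.shape[0]
    w_h, b_h, w_o, b_o = unpack(topology, thetas)
    # (n, n_in) @ (n_in, P*H) -> (n, P, H)
    w_flat = w_h.reshape(P * topology.n_hidden, topology.n_in)
    act = (x @ w_flat.T).reshape(len(x), P, topology.n_hidden)
    hidden = tansig(act + b_h[None, :, :])
    out = np.einsum("nph,ph->pn", hidden, w_o[:, 0, :]) + b_o[:, 0][:, None]
    return out


def init_box(topology: Topology, half_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Initialization box: uniform [-half_width, +half_width] per parameter,
    intersected with the weight/bias bounds.

    Small random parameters (default +-1) keep the tanh units away from
    saturation at the start; the search itself still ranges over the full
    weight/bias box.
    """
    lo, hi = topology.param_bounds()
    return np.maximum(lo, -half_width), np.minimum(hi, half_width)


def init_random(topology: Topology, seed: int | np.random.Generator,
                half_width: float = 1.0) -> NetworkParameters:
    """Draw theta uniformly inside the initialization box, deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = init_box(topology, half_width)
    return NetworkParameters(topology, rng.uniform(lo, hi))
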