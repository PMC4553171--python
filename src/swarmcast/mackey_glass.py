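"""Mackey-Glass delay-differential simulator.

The Mackey-Glass equation

    dx/dt = -beta * x(t) + alpha * x(t - tau) / (1 + x(t - tau)^n)

was proposed as a model of delayed feedback in physiological (hematopoietic)
control.  With the standard parameters alpha=0.2, beta=0.1, n=10 the system
undergoes a cascade of bifurcations as the delay grows and is chaotic for
tau >= 17.  The simulator integrates the equation with classical fourth-order
Runge-Kutta on a fixed internal step, keeping the full solution history so the
delayed term can be evaluated at the Runge-Kutta substeps (linear
interpolation between grid points, matching the O(h^2) local accuracy needed
at h = 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .timeseries import TimeSeries, sample_series


class DivergenceError(RuntimeError):
    """Raised when the integration leaves the bounded attractor regime."""


@dataclass(frozen=True)
class MGParams:
    """Parameters of the Mackey-Glass system and its integration.

    Attributes
    ----------
    alpha : float
        Production coefficient of the delayed feedback term (default 0.2).
    beta : float
        Magnitude of the linear decay rate (default 0.1).  The decay enters
        the derivative as ``-beta * x(t)``.
    tau : float
        Feedback delay in seconds (default 17; chaotic regime for tau >= 17).
    hill_exponent : int
        Exponent of the feedback nonlinearity (fixed at 10 in the standard
        benchmark).
    x0 : float
        Initial value x(0) (default 1.2).
    t_horizon : float
        Total simulated time in seconds (default 2000).
    sample_dt : float
        Output sampling interval (default 1.0 s).
    internal_dt : float
        Runge-Kutta step (default 0.1 s); ``sample_dt`` and ``tau`` must be
        integer multiples of it.
    """

    alpha: float = 0.2
    beta: float = 0.1
    tau: float = 17.0
    hill_exponent: int = 10
    x0: float = 1.2
    t_horizon: float = 2000.0
    sample_dt: float = 1.0
    internal_dt: float = 0.1

    def __post_init__(self) -> None:
        if not (self.alpha >= 0 and self.beta > 0 and self.tau > 0):
            raise ValueError("alpha >= 0, beta > 0 and tau > 0 are required")
        if self.internal_dt <= 0:
            raise ValueError("internal_dt must be positive")
        for name, value in (("sample_dt", self.sample_dt), ("tau", self.tau)):
            ratio = value / self.internal_dt
            if abs(ratio - round(ratio)) > 1e-8:
                raise ValueError(f"{name} must be an integer multiple of internal_dt")

    @property
    def delay_steps(self) -> int:
        return int(round(self.tau / self.internal_dt))


def mg_derivative(x_now: float, x_delayed: float, params: MGParams,
                  literal_sign: bool = False) -> float:
    """Right-hand side of the Mackey-Glass equation.

    ``literal_sign=True`` flips the decay term to ``+beta*x`` (an unstable
    variant kept for auditing; the default is the canonical decay sign).
    """
    if not (math.isfinite(x_now) and math.isfinite(x_delayed)):
        raise ValueError("non-finite state in mg_derivative")
    decay = params.beta * x_now
    feedback = params.alpha * x_delayed / (1.0 + x_delayed ** params.hill_exponent)
    return (decay if literal_sign else -decay) + feedback


def integrate_mg(params: MGParams, *, history_value: float = 0.0,
                 burn_in: float = 0.0, literal_sign: bool = False,
                 guard: float = 1e6) -> TimeSeries:
    """Integrate the Mackey-Glass equation and return a sampled series.

    The pre-history is the constant ``history_value`` on [-tau, 0) (0 by
    default) with x(0) = ``params.x0``.  Classical RK4 runs on the internal
    grid; the delayed state at substeps is linearly interpolated.  ``burn_in``
    seconds may be discarded from the front (times re-zeroed), default 0.

    Raises
    ------
    DivergenceError
        If |x| exceeds ``guard`` (happens immediately with
        ``literal_sign=True`` at the standard parameters).
    """
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    h = params.internal_dt
    n_steps = int(round((params.t_horizon + burn_in) / h))
    delay = params.delay_steps
    alpha, beta, hill = params.alpha, params.beta, params.hill_exponent
    sign = 1.0 if literal_sign else -1.0

    xs = np.empty(n_steps + 1)
    xs[0] = params.x0

    def delayed_at(idx: float) -> float:
        # idx is in internal-grid units and may be half-integral
        if idx < 0:
            return history_value
        lo = int(math.floor(idx))
        frac = idx - lo
        if frac == 0.0:
            return xs[lo]
        return (1.0 - frac) * xs[lo] + frac * xs[lo + 1]

    def f(x: float, x_del: float) -> float:
        return sign * beta * x + alpha * x_del / (1.0 + x_del ** hill)

    for k in range(n_steps):
        x = xs[k]
        if abs(x) > guard:
            raise DivergenceError(
                f"|x| exceeded {guard:g} at t={k * h:.1f}; unstable parameterization"
            )
        d0 = delayed_at(k - delay)
        dh = delayed_at(k - delay + 0.5)
        # endpoint stage: left limit at the t=0 history jump, so the step
        # ending exactly at t=tau integrates the pre-jump dynamics
        d1 = history_value if k - delay + 1 == 0 else delayed_at(k - delay + 1)
        k1 = f(x, d0)
        k2 = f(x + 0.5 * h * k1, dh)
        k3 = f(x + 0.5 * h * k2, dh)
        k4 = f(x + h * k3, d1)
        xs[k + 1] = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    if not np.all(np.isfinite(xs)) or np.max(np.abs(xs)) > guard:
        raise DivergenceError("integration diverged")

    t = np.arange(n_steps + 1) * h
    full = TimeSeries(t, xs)
    if burn_in > 0:
        keep = full.t >= burn_in - 1e-9
        full = TimeSeries(full.t[keep] - burn_in, full.x[keep])
    return sample_series(full, params.sample_dt)
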