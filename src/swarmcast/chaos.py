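"""Lyapunov spectra and the Kaplan-Yorke dimension of the delayed-feedback attractor.

Two estimation routes are provided.

* Variational route (``lyapunov_spectrum_dde``): the linearization of the
  delay equation,

      d(delta)/dt = -beta*delta(t) + alpha*g'(x(t-tau))*delta(t-tau),
      g(u) = u/(1+u^n),   g'(u) = (1 - (n-1)*u^n) / (1+u^n)^2,

  is integrated alongside the nonlinear trajectory for a bundle of
  perturbation histories; periodic QR reorthonormalization of the
  discretized history segments accumulates the average logarithmic growth
  rates (the classical Benettin/Farmer procedure for delay systems).  This
  is the ground-truth route for simulated series.

* Tangent-map route (``lyapunov_spectrum_series``): from an observed scalar
  series alone, delay-embed, fit local linear maps between successive
  neighborhoods (Sano-Sawada), and accumulate the same QR product.  This is
  the route applicable to a network-predicted series.

The Kaplan-Yorke dimension D_KY = j + (sum_{i<=j} lambda_i)/|lambda_{j+1}|,
with j the largest order keeping the partial sum non-negative, estimates the
information dimension of the attractor from either spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mackey_glass import DivergenceError, MGParams
from .timeseries import TimeSeries


@dataclass(frozen=True)
class LyapunovSpectrum:
    """Ordered Lyapunov exponents (1/second) with estimation metadata."""

    exponents: np.ndarray
    method: str
    series_length: int

    def __post_init__(self) -> None:
        lam = np.asarray(self.exponents, dtype=float)
        object.__setattr__(self, "exponents", lam)
        if lam.ndim != 1 or lam.size == 0 or not np.all(np.isfinite(lam)):
            raise ValueError("exponents must be a finite 1-d array")
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("exponents must be sorted in descending order")


def delay_coordinates(ts: TimeSeries, lag: float, dim: int) -> np.ndarray:
    """Delay-coordinate points [x(t), x(t-lag), ..., x(t-(dim-1)lag)].

    Returns an (n_points, dim) array; useful both for attractor portraits
    and for tangent-map estimation.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    step = lag / ts.dt
    if dim > 1 and abs(step - round(step)) > 1e-8:
        raise ValueError("lag must be a multiple of the sampling interval")
    step = int(round(step)) if dim > 1 else 0
    first = (dim - 1) * step
    if first >= len(ts):
        raise ValueError("series too short for this embedding")
    anchors = np.arange(first, len(ts))
    cols = anchors[:, None] - step * np.arange(dim)[None, :]
    return ts.x[cols]


def _mg_gprime(u: np.ndarray, alpha: float, hill: int) -> np.ndarray:
    un = u ** hill
    return alpha * (1.0 - (hill - 1) * un) / (1.0 + un) ** 2


def lyapunov_spectrum_dde(params: MGParams, n_exponents: int = 4,
                          t_total: float = 20000.0, t_skip: float = 1000.0,
                          ortho_every: float = 5.0, seed: int = 0,
                          guard: float = 1e6) -> LyapunovSpectrum:
    """Ground-truth spectrum from the linearized delay equation.

    The nonlinear trajectory and ``n_exponents`` perturbation histories are
    advanced together with RK4 on the internal grid; every ``ortho_every``
    seconds (after a ``t_skip`` transient) the discretized perturbation
    histories are QR-reorthonormalized and log|diag R| accumulated.
    """
    if n_exponents < 1:
        raise ValueError("n_exponents must be >= 1")
    h = params.internal_dt
    delay = params.delay_steps
    n_steps = int(round(t_total / h))
    alpha, beta, hill = params.alpha, params.beta, params.hill_exponent
    m = n_exponents

    xs = np.empty(n_steps + 1)
    xs[0] = params.x0
    deltas = np.zeros((n_steps + 1, m))
    rng = np.random.default_rng(seed)
    deltas[0] = rng.standard_normal(m)

    def x_at(idx: float) -> float:
        if idx < 0:
            return 0.0
        lo = int(math.floor(idx))
        frac = idx - lo
        return xs[lo] if frac == 0.0 else (1 - frac) * xs[lo] + frac * xs[lo + 1]

    def d_at(idx: float) -> np.ndarray:
        if idx < 0:
            return np.zeros(m)
        lo = int(math.floor(idx))
        frac = idx - lo
        return deltas[lo] if frac == 0.0 else (1 - frac) * deltas[lo] + frac * deltas[lo + 1]

    def f(x: float, x_del: float) -> float:
        return -beta * x + alpha * x_del / (1.0 + x_del ** hill)

    skip_steps = int(round(t_skip / h))
    ortho_steps = max(1, int(round(ortho_every / h)))
    log_r = np.zeros(m)
    t_accum = 0.0
    last_ortho = None

    for k in range(n_steps):
        x = xs[k]
        if abs(x) > guard:
            raise DivergenceError("nonlinear trajectory diverged")
        xd0, xdh, xd1 = x_at(k - delay), x_at(k - delay + 0.5), x_at(k - delay + 1)
        k1 = f(x, xd0)
        k2 = f(x + 0.5 * h * k1, xdh)
        k3 = f(x + 0.5 * h * k2, xdh)
        k4 = f(x + h * k3, xd1)
        xs[k + 1] = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

        c0, ch, c1 = (_mg_gprime(np.array([xd0, xdh, xd1]), alpha, hill))
        dd0, ddh, dd1 = d_at(k - delay), d_at(k - delay + 0.5), d_at(k - delay + 1)
        dlt = deltas[k]
        l1 = -beta * dlt + c0 * dd0
        l2 = -beta * (dlt + 0.5 * h * l1) + ch * ddh
        l3 = -beta * (dlt + 0.5 * h * l2) + ch * ddh
        l4 = -beta * (dlt + h * l3) + c1 * dd1
        deltas[k + 1] = dlt + (h / 6.0) * (l1 + 2 * l2 + 2 * l3 + l4)

        step = k + 1
        if step >= skip_steps and step % ortho_steps == 0 and step >= delay:
            window = slice(step - delay, step + 1)
            q, r = np.linalg.qr(deltas[window])
            # fix signs so diagonal of R is positive
            signs = np.sign(np.diag(r))
            signs[signs == 0] = 1.0
            q *= signs
            r = (r.T * signs).T
            deltas[window] = q
            if last_ortho is not None:
                log_r += np.log(np.abs(np.diag(r)))
                t_accum += (step - last_ortho) * h
            last_ortho = step

    if t_accum <= 0:
        raise ValueError("integration too short for any accumulation interval")
    lam = np.sort(log_r / t_accum)[::-1]
    return LyapunovSpectrum(lam, method="dde-variational-qr",
                            series_length=n_steps + 1)


def lyapunov_spectrum_series(ts: TimeSeries, dim: int = 4, lag: float = 6.0,
                             n_exponents: int = 4, n_neighbors: int = 30,
                             min_separation: int | None = None) -> LyapunovSpectrum:
    """Tangent-map (Sano-Sawada) spectrum estimate from a scalar series.

    The series is delay-embedded in ``dim`` dimensions; at each step a local
    linear map is fitted by least squares from the displacements of the
    ``n_neighbors`` nearest neighbors to their one-step-ahead images, and the
    QR product of these maps yields the exponents per unit time.  Needs a
    long, approximately noise-free series.
    """
    if n_exponents > dim:
        raise ValueError("cannot estimate more exponents than embedding dimensions")
    pts = delay_coordinates(ts, lag, dim)
    n = len(pts) - 1
    if n < 10 * n_neighbors:
        raise ValueError("series too short for reliable neighbor statistics")
    if min_separation is None:
        min_separation = max(1, int(round(lag / ts.dt)))
    tree = cKDTree(pts[:n])
    q = np.eye(dim)
    log_r = np.zeros(dim)
    used = 0
    for i in range(n):
        k_query = n_neighbors + 2 * min_separation + 1
        dists, idx = tree.query(pts[i], k=min(k_query, n))
        idx = np.atleast_1d(idx)
        keep = idx[np.abs(idx - i) >= min_separation][:n_neighbors]
        if len(keep) < dim + 1:
            continue
        dx = pts[keep] - pts[i]
        dy = pts[keep + 1] - pts[i + 1]
        a, *_ = np.linalg.lstsq(dx, dy, rcond=None)
        m = a.T @ q
        q, r = np.linalg.qr(m)
        diag = np.abs(np.diag(r))
        diag[diag == 0] = np.finfo(float).tiny
        log_r += np.log(diag)
        used += 1
    if used == 0:
        raise ValueError("no usable neighborhoods found")
    lam = np.sort(log_r / (used * ts.dt))[::-1][:n_exponents]
    return LyapunovSpectrum(lam, method="tangent-map-qr", series_length=len(ts))


def kaplan_yorke(spectrum: LyapunovSpectrum | np.ndarray) -> float:
    """Kaplan-Yorke (Lyapunov) dimension from an ordered spectrum.

    D_KY = j + (sum_{i<=j} lambda_i) / |lambda_{j+1}| with j the largest
    order whose partial sum is non-negative; 0 if even the leading exponent
    is negative.  Raises if every partial sum is non-negative (the spectrum
    is too short to close the dimension estimate).
    """
    lam = spectrum.exponents if isinstance(spectrum, LyapunovSpectrum) \
        else np.sort(np.asarray(spectrum, dtype=float))[::-1]
    if lam[0] < 0:
        return 0.0
    partial = np.cumsum(lam)
    if partial[-1] >= 0:
        raise ValueError("all partial sums non-negative: spectrum too short for D_KY")
    j = int(np.max(np.nonzero(partial >= 0)[0])) + 1   # number of leading exponents
    return float(j + partial[j - 1] / abs(lam[j]))
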