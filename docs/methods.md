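# Methods

## The forecasting problem

The Mackey-Glass equation

    dx/dt = -beta x(t) + alpha x(t - tau) / (1 + x(t - tau)^10)

models delayed feedback in physiological control (originally blood-cell
production, where the delay is the maturation time of precursor cells).
At the standard parameters alpha = 0.2, beta = 0.1 it produces a bounded,
aperiodic, chaotic trajectory for delays tau >= 17 s.  The benchmark task is
short-term forecasting: predict x(t + 6) from the four delay coordinates
[x(t - 18), x(t - 12), x(t - 6), x(t)] (d = 4 taps, spacing and horizon
Delta = T = 6 s), on a 2000-point series sampled at 1 s, with the first 1000
embedded patterns used for training and the remaining 976 for validation.
Robustness to measurement noise is probed by corrupting the whole series —
inputs and targets alike — with i.i.d. Gaussian white noise of level
sigma_N in {0.01, 0.04, 0.06, 0.08, 0.1} before embedding.

## Simulator

The delay equation is integrated with classical fourth-order Runge-Kutta on
a fixed internal step h = 0.1 s (tau and the 1 s output sampling are integer
multiples of h).  Delayed states at the half-step stages are linearly
interpolated on the solution history.  The benchmark initial data are a zero
pre-history on [-tau, 0) with x(0) = 1.2 and no burn-in; an optional burn-in
argument discards an initial transient when a statistically stationary
segment is wanted.

Two numerical details matter:

* The equation as sometimes transcribed with a positive decay term
  (+beta x) diverges; the canonical decay sign is the default and a
  `literal_sign` flag reproduces the divergent variant, which trips the
  integrator's |x| > 1e6 guard.
* The jump from the zero pre-history to x(0) = 1.2 makes the delayed term
  discontinuous at t = tau.  The endpoint stage of the step that lands
  exactly on t = tau evaluates the delayed value as its left limit (the
  history value), so each step integrates one-sided dynamics.  Without this
  the stage samples the jump itself and injects an O(h) error that chaos
  then amplifies.

Step-halving agreement is below 1e-4 through t = 300 s.  Beyond that,
pointwise comparison between step sizes is
meaningless for a chaotic trajectory — the difference grows like
exp(lambda_1 t) — so full-horizon validation is statistical (series mean and
standard deviation stable to < 1e-2 under step halving).

## Network and swarm training

The forecaster is a feed-forward 4-N_HL-1 network: one hidden layer of
hyperbolic-tangent units, a linear output.  All parameters live in a flat
vector ordered [hidden weights, hidden biases, output weights, output bias];
weights are confined to [-100, 100] and biases to [-10, 10].

Training is inertia-weight particle swarm optimization: each particle is a
full parameter vector, velocities follow

    v <- omega v + c1 r1 (pbest - s) + c2 r2 (gbest - s),    s <- s + v,

with r1, r2 drawn per dimension, per particle, per iteration.  Defaults: 50
particles, 1500 iterations, c1 = c2 = 1.494, omega decreasing linearly from
0.7 to 0.5, velocity clamp +-12, position clamp to the weight/bias box, stop
early only if training RMSE falls below 1e-3 (never reached on this task).
Personal bests start at the initial positions; the global best is updated
synchronously after all fitness evaluations each iteration (ties to the
lowest particle index), so its fitness is monotonically non-increasing.
Fitness is the root-mean-square error between raw-scale targets and
denormalized outputs on the training patterns only.  A noise-weighted
variant sqrt((1/n) sum r_i^2 / sigma_i^2) is available when the per-element
noise level is known; with constant sigma it rescales the plain RMSE and
leaves the search trajectory unchanged, so the plain RMSE is used
throughout.  Inputs and targets are scaled to [-1, 1] by an affine map
fitted on the training half only (validation values may leave the interval;
all reported errors are on the raw scale).

Initialization is uniform in [-1, 1] per parameter — the standard
small-random-weights convention — rather than across the full search box.
With all 2000 training-input components normalized into [-1, 1], weights of
order 100 saturate every tanh unit, and a swarm seeded across the full box
stalls an order of magnitude above the achievable error (measured train
RMSE 0.03-0.09 across seeds at 1500 iterations, versus 0.010-0.014 with the
small init).  The search box and clamping are unchanged; only the seeding
is narrow.  Initial velocities are uniform in the +-v_max clamp range.

PSO is stochastic, so every reported figure is the best of five restarts
with distinct seeds derived deterministically from a master seed
(SHA-256 of "master/stage/repetition", truncated below 2^31).  Restarts are
ranked by validation RMSE, which is computed once per trained network and
never influences the search.

## Architecture selection and the noise laws

For each noise level the hidden-layer size is swept (2..30 in the full
protocol) and the validation-RMSE-minimizing size selected, ties toward the
smaller network.  The full sweep at five noise levels is expensive and the
minima at high noise are shallow (fourth-decimal differences across
adjacent sizes), so the pipeline defaults to the selected sizes
{0: 6, 0.01: 6, 0.04: 11, 0.06: 14, 0.08: 15, 0.1: 20} and re-runs the sweep
only on request (`do_sweep=True`, or the `sweep` CLI command).

Two linear summaries are fitted: RMSE = m sigma_N by zero-intercept least
squares over the noisy levels only (closed form m = sum(r s)/sum(s^2);
expected slope ~1.3), and N_HL = a sigma_N + b by ordinary least squares
over all levels.  The degradation ratio xi = RMSE_noisy / RMSE_noiseless is
reported per level.

## Monte-Carlo prediction uncertainty

A trained network is a deterministic map of its input vector, so input
noise propagates through it directly: each raw-scale input vector is
resampled k = 1000 times from N(d_i, sigma_N^2 I), every draw is normalized,
evaluated, and denormalized, and the output ensemble is summarized by its
mean (the stochastic prediction) and its standard deviation about that mean
(the per-point uncertainty sigma_y).  k = 1000 keeps the Monte-Carlo error
on sigma_y near 1/sqrt(2k) ~ 2%.  A `literal_second_moment` flag returns
sqrt(<y^2>) instead — the raw second moment, which conflates the signal
magnitude (~1) with the spread and is kept only for auditing.

For an affine map y = a.p + c the ensemble spread converges to
sigma_N ||a||_2, which the tests verify against a near-linear network.  On
the sigma_N = 0.1 task the trained network's mean sigma_y is ~0.07
(ratio ~0.7 to the input noise): the network averages over four noisy taps
and smooths the noise, so the propagated uncertainty is smaller than the
input level.  One-sigma coverage of the noisy targets is reported both
against sigma_y alone and against sqrt(sigma_y^2 + sigma_N^2) (the target
itself carries noise that sigma_y does not describe).

## Chaos diagnostics

Ground-truth Lyapunov exponents come from the linearized delay equation,

    d(delta)/dt = -beta delta(t) + alpha g'(x(t-tau)) delta(t-tau),

integrated alongside the nonlinear trajectory for a bundle of perturbation
histories, with QR reorthonormalization of the discretized history segments
(171 grid points per segment at h = 0.1) every 5 s after a 1000 s
transient; exponents are the time-averaged logarithms of the R diagonal.
Defaults: 20000 s of integration (the spectrum tests use 10000 s, where the
leading exponent is stable to ~10%).  For alpha = 0 the route reproduces the
exact single exponent -beta to 1e-6.

The data-driven route is a tangent-map (Sano-Sawada) estimator: delay-embed
the scalar series (dim 4, lag 6 s for this system), fit a local linear map
at each step by least squares from the displacements of the 30 nearest
neighbors (temporal neighbors excluded) to their one-step images, and
accumulate the same QR product.  It recovers the exponent of a skew tent
map to ~1% and the leading exponent of the Henon attractor to ~2%; its most
negative exponent for the delay system is biased (a known limitation of
finite embeddings of infinite-dimensional dynamics), but the sign pattern
(+, ~0, -, -) and the leading exponent agree with the variational route.

D_KY = j + (sum_{i<=j} lambda_i)/|lambda_{j+1}| is evaluated on either
spectrum; for this attractor j = 2 and D_KY falls in 2.1-2.25 depending on
the estimate.  Published four-exponent tables for this system give 2.24-2.25
under direct evaluation of the formula while ~2.10 is the figure usually
quoted from longer spectra, so the package treats [2.0, 2.35] as the
plausibility band rather than asserting a point value.

## Problem sizes and profiles

The full protocol (2000-point series, 1500 swarm iterations, five restarts
per level, six noise levels, k = 1000 ensembles) runs in minutes on one
core because the fitness of all 50 particles is evaluated in a single
batched pass (one BLAS multiply plus one tanh over a 50 x 1000 x N_HL
block per iteration).  A `--fast` profile (300 iterations, one restart)
runs the whole benchmark in about a minute for smoke testing; headline
figures quoted anywhere in this repository come from the full profile.

## Known limitations

* The swarm reaches the benchmark error as the best of five restarts;
  individual seeds scatter noticeably around it, which is why every
  reported figure fixes the restart protocol.
* Because the clean-series baseline can come out better than the reference
  figure while the strong-noise error is pinned near the irreducible target
  noise, the degradation ratio xi is the least stable summary of the grid
  and should be read alongside the absolute RMSE column.
* The selected hidden sizes at high noise are weakly identified (shallow
  minima); the fixed size table reflects one defensible selection.
* The tangent-map spectrum should only be trusted for the leading one or
  two exponents at these series lengths.
* The synthetic data are exactly the stated study conditions (Gaussian
  white noise, uniform sampling, no missing values); real measured series
  with calibration drift or signal-proportional noise are outside what the
  tests demonstrate.
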