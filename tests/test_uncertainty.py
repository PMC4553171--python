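"""Monte-Carlo noise propagation: ensembles, uncertainties, coverage."""

import numpy as np
import pytest
from scipy import stats

from swarmcast import (EnsembleSpec, NetworkParameters, Scaler, Topology,
                       coverage_check, pack, predict_with_uncertainty,
                       simulate_input_ensemble)
from swarmcast.uncertainty import PredictionWithUncertainty


def near_linear_net(a, hidden_gain=1e-4):
    """A network that is affine to first order: y ~ a.p + 0 via tiny hidden weights.

    Hidden pre-activations stay within +-~1e-3 where tanh(v) = v to 1e-9,
    so the map is effectively linear with gradient a.
    """
    a = np.asarray(a, dtype=float)
    topo = Topology(len(a), len(a), 1)
    w_h = np.diag(np.full(len(a), hidden_gain))
    b_h = np.zeros(len(a))
    w_o = (a / hidden_gain)[None, :]
    b_o = np.zeros(1)
    return NetworkParameters(topo, pack(topo, w_h, b_h, w_o, b_o))


class TestEnsemble:
    def test_zero_sigma_copies_are_identical(self):
        x = np.arange(12.0).reshape(3, 4)
        draws = simulate_input_ensemble(x, EnsembleSpec(5, 0.0, 0))
        assert draws.shape == (5, 3, 4)
        assert np.all(draws == x)

    def test_component_means_converge(self):
        x = np.array([[1.0, -2.0, 0.5, 3.0]])
        spec = EnsembleSpec(10_000, 0.2, 1)
        draws = simulate_input_ensemble(x, spec)
        err = np.abs(draws.mean(axis=0) - x)
        assert np.all(err < 4 * 0.2 / np.sqrt(spec.k_sims))

    def test_seed_reproducibility(self):
        x = np.ones((2, 4))
        a = simulate_input_ensemble(x, EnsembleSpec(50, 0.1, 3))
        b = simulate_input_ensemble(x, EnsembleSpec(50, 0.1, 3))
        assert np.array_equal(a, b)


class TestPrediction:
    def test_degenerate_ensemble_equals_point_prediction(self):
        net = near_linear_net([0.5, -0.25, 0.1, 0.3])
        x = np.random.default_rng(0).normal(size=(10, 4))
        pred = predict_with_uncertainty(net, None, x, EnsembleSpec(100, 0.0, 0))
        assert np.allclose(pred.y_hat, pred.y_point)
        assert np.all(pred.sigma_y == 0.0)

    def test_affine_gaussian_propagation_closed_form(self):
        """For y = a.p the uncertainty tends to sigma_N * ||a||_2."""
        a = np.array([0.8, -0.4, 0.2, 0.6])
        net = near_linear_net(a)
        sigma_n = 0.05
        x = np.random.default_rng(1).normal(scale=0.01, size=(50, 4))
        pred = predict_with_uncertainty(net, None, x,
                                        EnsembleSpec(4000, sigma_n, 2))
        expected = sigma_n * np.linalg.norm(a)
        # Monte-Carlo error on an std with k=4000 is ~1.1% (1/sqrt(2k))
        assert np.allclose(pred.sigma_y, expected, rtol=0.06)

    def test_sigma_scales_linearly_in_small_noise_regime(self):
        net = near_linear_net([0.3, 0.3, -0.2, 0.1])
        x = np.zeros((5, 4))
        s1 = predict_with_uncertainty(net, None, x, EnsembleSpec(3000, 0.01, 3)).sigma_y
        s2 = predict_with_uncertainty(net, None, x, EnsembleSpec(3000, 0.02, 3)).sigma_y
        assert np.allclose(s2 / s1, 2.0, rtol=0.1)

    def test_scaler_round_trip_in_pipeline(self):
        """Normalization before the forward pass must not distort an affine map."""
        a = np.array([0.5, 0.5, 0.5, 0.5])
        net = near_linear_net(a)
        scaler = Scaler(-1.0, 1.0)  # identity on [-1, 1]
        x = np.random.default_rng(2).uniform(-0.1, 0.1, size=(8, 4))
        with_sc = predict_with_uncertainty(net, scaler, x, EnsembleSpec(500, 0.01, 4))
        without = predict_with_uncertainty(net, None, x, EnsembleSpec(500, 0.01, 4))
        assert np.allclose(with_sc.y_hat, without.y_hat, atol=1e-12)

    def test_nan_parameters_rejected(self):
        topo = Topology(4, 2, 1)
        net = NetworkParameters(topo, np.full(topo.n_params, np.nan))
        with pytest.raises(ValueError):
            predict_with_uncertainty(net, None, np.zeros((3, 4)),
                                     EnsembleSpec(10, 0.1, 0))


class TestCoverage:
    def _pred(self, y_hat, sigma_y):
        n = len(y_hat)
        return PredictionWithUncertainty(np.arange(float(n)), np.asarray(y_hat),
                                         np.asarray(sigma_y), np.asarray(y_hat))

    def test_infinite_bars_cover_everything(self):
        pred = self._pred(np.zeros(10), np.full(10, np.inf))
        assert coverage_check(pred, np.random.default_rng(0).normal(size=10)) == 1.0

    def test_zero_bars_cover_nothing(self):
        pred = self._pred(np.zeros(10), np.zeros(10))
        assert coverage_check(pred, np.ones(10)) == 0.0

    def test_matched_gaussian_residuals_near_683(self):
        """One-sigma coverage of matched Gaussian errors ~ Phi(1)-Phi(-1)."""
        rng = np.random.default_rng(5)
        n = 20_000
        sigma = 0.07
        truth = rng.normal(0.0, sigma, size=n)
        pred = self._pred(np.zeros(n), np.full(n, sigma))
        cov = coverage_check(pred, truth)
        expected = 2 * stats.norm.cdf(1) - 1  # 0.6827
        assert cov == pytest.approx(expected, abs=4 * np.sqrt(expected * (1 - expected) / n))

    def test_misaligned_times_rejected(self):
        pred = self._pred(np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            coverage_check(pred, np.zeros(5), times=np.arange(5.0) + 1)
        with pytest.raises(ValueError):
            coverage_check(pred, np.zeros(4))
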