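"""Swarm optimizer: update rules, fitness, convergence and determinism."""

import numpy as np
import pytest

from swarmcast import (EmbeddedDataset, NetworkParameters, PSOConfig, Scaler,
                       Topology, fitness_rmse, fitness_weighted, inertia_at,
                       pso_minimize, train)
from swarmcast.pso import position_update, velocity_update


class QueuedRng:
    """Deterministic stand-in feeding preset uniform draws to the update rule."""

    def __init__(self, draws):
        self.draws = list(draws)

    def uniform(self, size=None):
        return np.asarray(self.draws.pop(0))


def toy_dataset(inputs, targets):
    inputs = np.asarray(inputs, dtype=float)
    return EmbeddedDataset(inputs, np.asarray(targets, dtype=float),
                           np.arange(float(len(inputs))))


class TestFitness:
    def test_perfect_prediction_is_zero(self):
        theta = np.zeros(13)
        net = NetworkParameters(Topology(4, 2, 1), theta)
        ds = toy_dataset(np.zeros((5, 4)), np.zeros(5))
        assert fitness_rmse(net, ds) == 0.0

    def test_constant_offset_closed_form(self):
        theta = np.zeros(13)
        theta[-1] = 0.4  # output bias only -> constant prediction 0.4
        net = NetworkParameters(Topology(4, 2, 1), theta)
        ds = toy_dataset(np.zeros((7, 4)), np.full(7, 1.1))
        assert fitness_rmse(net, ds) == pytest.approx(abs(0.4 - 1.1))

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(2)
        topo = Topology(4, 3, 1)
        net = NetworkParameters(topo, rng.normal(size=topo.n_params))
        ds = toy_dataset(rng.normal(size=(5, 4)), rng.normal(size=5))
        from swarmcast import forward
        resid = [forward(net, row) - t for row, t in zip(ds.inputs, ds.targets)]
        expected = np.sqrt(sum(r * r for r in resid) / 5)
        assert fitness_rmse(net, ds) == pytest.approx(expected, rel=1e-12)

    def test_empty_dataset_rejected(self):
        net = NetworkParameters(Topology(4, 2, 1), np.zeros(13))
        ds = EmbeddedDataset(np.zeros((0, 4)), np.zeros(0), np.zeros(0))
        with pytest.raises(ValueError):
            fitness_rmse(net, ds)


class TestWeightedFitness:
    def test_residuals_equal_to_sigma_normalize_to_one(self):
        theta = np.zeros(13)
        theta[-1] = 0.05
        net = NetworkParameters(Topology(4, 2, 1), theta)
        ds = toy_dataset(np.zeros((4, 4)), np.zeros(4))  # residuals all 0.05
        assert fitness_weighted(net, ds, 0.05) == pytest.approx(1.0)

    def test_unit_sigma_reduces_to_rmse(self):
        rng = np.random.default_rng(3)
        topo = Topology(4, 2, 1)
        net = NetworkParameters(topo, rng.normal(size=topo.n_params))
        ds = toy_dataset(rng.normal(size=(6, 4)), rng.normal(size=6))
        assert fitness_weighted(net, ds, 1.0) == pytest.approx(fitness_rmse(net, ds))

    def test_mixed_sigma_hand_oracle(self):
        theta = np.zeros(13)
        theta[-1] = 1.0
        net = NetworkParameters(Topology(4, 2, 1), theta)
        ds = toy_dataset(np.zeros((3, 4)), np.array([0.0, 0.5, 2.0]))
        sig = np.array([0.5, 1.0, 2.0])
        expected = np.sqrt(((1.0 / 0.5) ** 2 + (0.5 / 1.0) ** 2 + (1.0 / 2.0) ** 2) / 3)
        assert fitness_weighted(net, ds, sig) == pytest.approx(expected)

    def test_literal_variant_is_square(self):
        theta = np.zeros(13)
        theta[-1] = 0.1
        net = NetworkParameters(Topology(4, 2, 1), theta)
        ds = toy_dataset(np.zeros((4, 4)), np.zeros(4))
        rooted = fitness_weighted(net, ds, 0.05)
        literal = fitness_weighted(net, ds, 0.05, literal=True)
        assert literal == pytest.approx(rooted ** 2)

    def test_zero_sigma_rejected(self):
        net = NetworkParameters(Topology(4, 2, 1), np.zeros(13))
        ds = toy_dataset(np.zeros((2, 4)), np.zeros(2))
        with pytest.raises(ValueError):
            fitness_weighted(net, ds, 0.0)


class TestInertia:
    def test_endpoints_and_midpoint(self):
        cfg = PSOConfig(k_max=1501)
        assert inertia_at(0, cfg) == pytest.approx(0.7)
        assert inertia_at(1500, cfg) == pytest.approx(0.5)
        assert inertia_at(750, cfg) == pytest.approx(0.6)

    def test_out_of_range_rejected(self):
        cfg = PSOConfig(k_max=100)
        for k in (-1, 100):
            with pytest.raises(ValueError):
                inertia_at(k, cfg)


class TestUpdateRules:
    def test_pure_inertia_keeps_velocity(self):
        cfg = PSOConfig(c1=0.0, c2=0.0, v_max=100.0)
        v = np.array([1.5, -2.0])
        out = velocity_update(v, np.zeros(2), np.ones(2), np.ones(2),
                              1.0, cfg, QueuedRng([np.zeros(2), np.zeros(2)]))
        assert np.array_equal(out, v)

    def test_fixed_point_at_shared_best(self):
        cfg = PSOConfig()
        s = np.array([0.3, -0.7])
        out = velocity_update(np.array([5.0, -3.0]), s, s, s, 0.0, cfg,
                              QueuedRng([np.ones(2), np.ones(2)]))
        assert np.array_equal(out, np.zeros(2))

    def test_velocity_clamped_to_vmax(self):
        cfg = PSOConfig(c1=1.0, c2=0.0, v_max=12.0)
        out = velocity_update(np.array([10.0]), np.array([0.0]),
                              np.array([10.0]), np.array([0.0]), 1.0, cfg,
                              QueuedRng([np.array([0.5]), np.array([0.0])]))
        # raw value 10 + 1*0.5*10 = 15 -> clamped to 12
        assert out[0] == 12.0

    def test_one_step_hand_oracle(self):
        """Velocity and position arithmetic on a 2-d toy with preset draws."""
        cfg = PSOConfig(c1=2.0, c2=1.0, v_max=10.0)
        s = np.array([1.0, -2.0])
        v = np.array([0.5, 0.5])
        pb = np.array([2.0, 0.0])
        gb = np.array([0.0, 1.0])
        r1 = np.array([0.25, 0.5])
        r2 = np.array([0.5, 0.25])
        out_v = velocity_update(v, s, pb, gb, 0.6, cfg, QueuedRng([r1, r2]))
        expected_v = 0.6 * v + 2.0 * r1 * (pb - s) + 1.0 * r2 * (gb - s)
        assert np.allclose(out_v, expected_v)
        lo, hi = -np.ones(2) * 100, np.ones(2) * 100
        assert np.allclose(position_update(s, out_v, lo, hi), s + expected_v)

    def test_position_clipped_into_box(self):
        lo = np.array([-100.0])
        hi = np.array([100.0])
        assert position_update(np.array([99.0]), np.array([5.0]), lo, hi)[0] == 100.0
        assert position_update(np.array([50.0]), np.array([0.0]), lo, hi)[0] == 50.0


class TestCoreSearch:
    def test_sphere_function_minimized(self):
        """The same swarm core drives x^2 + y^2 below 1e-6 within 1500 iters."""
        cfg = PSOConfig(n_particles=50, k_max=1500, seed=0, min_error=0.0)
        obj = lambda p: np.sum(p * p, axis=1)
        _, best_f, _ = pso_minimize(obj, np.full(2, -100.0), np.full(2, 100.0), cfg)
        assert best_f < 1e-6

    def test_running_minimum_monotone(self):
        cfg = PSOConfig(n_particles=10, k_max=200, seed=1, min_error=0.0)
        obj = lambda p: np.sum(np.abs(p), axis=1)
        _, _, hist = pso_minimize(obj, np.full(3, -5.0), np.full(3, 5.0), cfg)
        assert np.all(np.diff(hist) <= 0)

    def test_tiny_vmax_freezes_swarm(self):
        cfg = PSOConfig(n_particles=8, k_max=50, v_max=1e-12, seed=2, min_error=0.0)
        obj = lambda p: np.sum(p * p, axis=1)
        best, best_f, hist = pso_minimize(obj, np.full(2, -5.0), np.full(2, 5.0), cfg)
        # positions can drift at most k_max * v_max from their start
        assert hist[0] - hist[-1] < 1e-6

    def test_determinism(self):
        cfg = PSOConfig(n_particles=12, k_max=80, seed=9, min_error=0.0)
        obj = lambda p: np.sum((p - 1.3) ** 2, axis=1)
        a = pso_minimize(obj, np.full(2, -5.0), np.full(2, 5.0), cfg)
        b = pso_minimize(obj, np.full(2, -5.0), np.full(2, 5.0), cfg)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]
        assert np.array_equal(a[2], b[2])


class TestTraining:
    def test_constant_zero_target_trivially_learned(self):
        rng = np.random.default_rng(4)
        ds = EmbeddedDataset(rng.normal(size=(30, 4)), np.zeros(30),
                             np.arange(30.0))
        cfg = PSOConfig(n_particles=20, k_max=200, seed=0)
        res = train(ds, Topology(4, 2, 1), cfg)
        assert res.best_rmse < 1e-3
        assert res.iterations_run < 200  # min_error stopping fired

    def test_history_monotone_and_best_matches(self, benchmark_data, quick_pso_config):
        res = train(benchmark_data["train"], Topology(4, 4, 1),
                    quick_pso_config, benchmark_data["scaler"])
        assert np.all(np.diff(res.rmse_history) <= 0)
        assert res.best_rmse == res.rmse_history[-1]

    def test_bit_identical_reruns(self, benchmark_data, quick_pso_config):
        args = (benchmark_data["train"], Topology(4, 3, 1), quick_pso_config,
                benchmark_data["scaler"], benchmark_data["valid"])
        a, b = train(*args), train(*args)
        assert np.array_equal(a.best_network.theta, b.best_network.theta)
        assert a.best_rmse == b.best_rmse
        assert a.validation_rmse == b.validation_rmse
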