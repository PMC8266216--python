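import numpy as np
import pytest
from scipy.optimize import minimize

import placemap as pm
from placemap.network import fit_dictionary


def random_instance(rng, n_e=6, n_h=4):
    state = pm.init_network(n_e, n_h, rng)
    s_e = rng.random(n_e)
    return state, s_e


class TestConfig:
    def test_euler_stability_guard(self):
        with pytest.raises(ValueError, match="unstable"):
            pm.ModelConfig(tau_ms=1.0, dt_ms=2.5)

    def test_defaults(self):
        cfg = pm.ModelConfig()
        assert (cfg.tau_ms, cfg.beta, cfg.dt_ms, cfg.n_steps) == (10.0, 0.3, 0.8, 200)
        assert (cfg.eta, cfg.n_epochs, cfg.n_hippocampal) == (0.03, 20000, 100)


class TestInit:
    def test_shapes_and_norms(self, rng):
        state = pm.init_network(600, 100, rng)
        assert state.A.shape == (600, 100)
        np.testing.assert_allclose(np.linalg.norm(state.A, axis=0), 1.0, atol=1e-12)
        assert state.A.min() >= 0

    def test_single_unit_has_zero_recurrence(self, rng):
        state = pm.init_network(5, 1, rng)
        assert state.W.shape == (1, 1)
        assert abs(state.W[0, 0]) < 1e-12

    def test_seed_determinism(self):
        a = pm.init_network(20, 4, np.random.default_rng(5)).A
        b = pm.init_network(20, 4, np.random.default_rng(5)).A
        np.testing.assert_array_equal(a, b)


class TestInference:
    def test_zero_input_zero_fixed_point(self, rng):
        state, _ = random_instance(rng)
        res = pm.lca_infer(state, np.zeros(6), pm.ModelConfig())
        np.testing.assert_array_equal(res.s_h, 0.0)
        np.testing.assert_array_equal(res.u_h, 0.0)

    def test_single_unit_closed_form(self, rng):
        """With one unit (W = 0) the ODE is linear: s* = max(A^T s_e - beta, 0)."""
        cfg = pm.ModelConfig()
        for _ in range(5):
            state, s_e = random_instance(rng, n_e=8, n_h=1)
            res = pm.lca_infer(state, s_e, cfg)
            expected = max(float(state.A[:, 0] @ s_e) - cfg.beta, 0.0)
            assert res.s_h[0] == pytest.approx(expected, abs=1e-3)

    def test_rates_are_thresholded_potentials(self, rng):
        state, s_e = random_instance(rng)
        cfg = pm.ModelConfig()
        res = pm.lca_infer(state, s_e, cfg)
        np.testing.assert_allclose(res.s_h, np.maximum(res.u_h - cfg.beta, 0.0))

    def test_fixed_point_matches_bounded_minimizer(self, rng):
        """LCA solutions minimize the non-negative l1-penalized cost.

        Compared on small instances against an independent bounded
        quasi-Newton minimizer of 1/2||s_e - As||^2 + beta sum(s).
        """
        cfg = pm.ModelConfig(n_steps=1000)
        for _ in range(10):
            state, s_e = random_instance(rng, n_e=6, n_h=4)
            s_lca = pm.lca_infer(state, s_e, cfg).s_h

            def cost(s):
                r = s_e - state.A @ s
                return 0.5 * r @ r + cfg.beta * s.sum()

            def grad(s):
                return -state.A.T @ (s_e - state.A @ s) + cfg.beta

            res = minimize(
                cost,
                np.full(4, 0.1),
                jac=grad,
                bounds=[(0, None)] * 4,
                method="L-BFGS-B",
                options={"ftol": 1e-15, "gtol": 1e-12},
            )
            assert cost(s_lca) <= res.fun + 1e-4
            # KKT stationarity on the active set
            active = s_lca > 1e-6
            if active.any():
                g = state.A[:, active].T @ (s_e - state.A @ s_lca)
                np.testing.assert_allclose(g, cfg.beta, atol=1e-3)

    def test_batch_matches_single(self, rng):
        state, _ = random_instance(rng, n_e=10, n_h=5)
        cfg = pm.ModelConfig()
        S_e = rng.random((7, 10))
        batch = pm.lca_infer_batch(state, S_e, cfg)
        for i in range(7):
            single = pm.lca_infer(state, S_e[i], cfg).s_h
            np.testing.assert_allclose(batch[i], single, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        state, _ = random_instance(rng)
        with pytest.raises(ValueError):
            pm.lca_infer(state, np.zeros(7), pm.ModelConfig())


class TestLearningStep:
    def test_inactive_rates_leave_dictionary_unchanged(self, rng):
        state, s_e = random_instance(rng)
        A0 = state.A.copy()
        pm.learning_step(state, s_e, np.zeros(4), eta=0.03)
        np.testing.assert_array_equal(state.A, A0)

    def test_single_active_unit_touches_one_column(self, rng):
        state, s_e = random_instance(rng)
        A0 = state.A.copy()
        s_h = np.array([0.0, 0.7, 0.0, 0.0])
        pm.learning_step(state, s_e, s_h, eta=0.03)
        np.testing.assert_array_equal(state.A[:, [0, 2, 3]], A0[:, [0, 2, 3]])
        assert not np.array_equal(state.A[:, 1], A0[:, 1])

    def test_hand_computed_update(self):
        """One step on a 3x2 instance against explicit arithmetic."""
        A = np.array([[0.6, 0.1], [0.8, 0.2], [0.0, 0.97467943]])
        A = A / np.linalg.norm(A, axis=0)
        state = pm.NetworkState(A=A.copy(), W=A.T @ A - np.eye(2))
        s_e = np.array([1.0, 0.0, 0.5])
        s_h = np.array([0.5, 0.2])
        eta = 0.1
        # manual outer-product update, clip, renormalize
        resid = s_e - A @ s_h
        A_new = A + eta * np.outer(resid, s_h)
        A_new[A_new < 0] = 0.0
        A_new = A_new / np.linalg.norm(A_new, axis=0)
        pm.learning_step(state, s_e, s_h, eta)
        np.testing.assert_allclose(state.A, A_new, atol=1e-12)
        np.testing.assert_allclose(state.W, A_new.T @ A_new - np.eye(2), atol=1e-12)

    def test_invariants_after_random_updates(self, rng):
        """Non-negativity, unit columns and W = A^T A - I hold after every step."""
        state, _ = random_instance(rng, n_e=12, n_h=6)
        cfg = pm.ModelConfig()
        for _ in range(20):
            s_e = rng.random(12)
            s_h = pm.lca_infer(state, s_e, cfg).s_h
            pm.learning_step(state, s_e, s_h, eta=0.05, rng=rng)
            assert state.A.min() >= 0
            np.testing.assert_allclose(
                np.linalg.norm(state.A, axis=0), 1.0, atol=1e-9
            )
            np.testing.assert_allclose(
                state.W,
                state.A.T @ state.A - np.eye(6),
                atol=1e-9,
            )


class TestSparseCost:
    def test_zero_rates_cost_is_input_energy(self, rng):
        state, s_e = random_instance(rng)
        assert pm.sparse_cost(state, s_e, np.zeros(4), 0.3) == pytest.approx(
            0.5 * s_e @ s_e
        )

    def test_perfect_reconstruction_no_penalty(self, rng):
        state, _ = random_instance(rng)
        s_h = rng.random(4)
        s_e = state.A @ s_h
        assert pm.sparse_cost(state, s_e, s_h, beta=0.0) == pytest.approx(0.0, abs=1e-12)

    def test_arbitrary_instance_matches_direct_evaluation(self, rng):
        state, s_e = random_instance(rng)
        s_h = rng.random(4)
        expected = 0.5 * np.sum((s_e - state.A @ s_h) ** 2) + 0.3 * s_h.sum()
        assert pm.sparse_cost(state, s_e, s_h, 0.3) == pytest.approx(expected)


class TestTraining:
    def test_zero_epochs_returns_initial_state(self, small_grid_pop):
        cfg = pm.ModelConfig(n_hippocampal=10, n_epochs=0)
        state = pm.train(small_grid_pop, cfg, np.random.default_rng(1))
        ref = pm.init_network(small_grid_pop.n_cells, 10, np.random.default_rng(1))
        np.testing.assert_array_equal(state.A, ref.A)

    def test_training_is_bitwise_deterministic(self, small_grid_pop):
        cfg = pm.ModelConfig(n_hippocampal=8, n_epochs=300)
        a = pm.train(small_grid_pop, cfg, np.random.default_rng(42))
        b = pm.train(small_grid_pop, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a.A, b.A)
        np.testing.assert_array_equal(a.W, b.W)

    def test_fused_kernel_agrees_with_reference_operations(self, small_grid_pop):
        """The fused training loop equals explicit infer + learning_step calls."""
        cfg = pm.ModelConfig(n_hippocampal=6, n_epochs=40)
        rng = np.random.default_rng(9)
        state = pm.train(small_grid_pop, cfg, rng)
        # replay with the reference operations and the same random stream
        rng2 = np.random.default_rng(9)
        ref = pm.init_network(small_grid_pop.n_cells, 6, rng2)
        locs = rng2.integers(0, small_grid_pop.n_locations, size=40)
        rng2.random((4, small_grid_pop.n_cells))  # respawn pool draw in fit_dictionary
        for loc in locs:
            s_e = small_grid_pop.E[loc]
            s_h = pm.lca_infer(ref, s_e, cfg).s_h
            pm.learning_step(ref, s_e, s_h, cfg.eta)
        np.testing.assert_allclose(state.A, ref.A, atol=1e-10)

    def test_cost_decreases_over_early_training(self, small_grid_pop):
        """Held-out sparse coding cost trends down during learning."""
        cfg = pm.ModelConfig(n_hippocampal=20, n_epochs=3000)
        state = pm.train(small_grid_pop, cfg, np.random.default_rng(3), log_every=50)
        log = state.training_log
        early = log[log.epoch < 500].cost.mean()
        late = log[log.epoch > 2500].cost.mean()
        assert late < early

    def test_training_log_contents(self, small_trained):
        state, _, cfg = small_trained
        log = state.training_log
        assert list(log.columns) == ["epoch", "cost", "active_fraction"]
        assert (log.active_fraction >= 0).all() and (log.active_fraction <= 1).all()

    def test_trajectory_sequence_training(self, small_grid_pop):
        cfg = pm.ModelConfig(n_hippocampal=6, n_epochs=100)
        seq = np.arange(50)  # shorter than n_epochs: cycled
        state = pm.train(
            small_grid_pop, cfg, np.random.default_rng(0), location_source=seq
        )
        assert state.A.shape == (small_grid_pop.n_cells, 6)

    def test_noise_training_runs(self, small_grid_pop):
        cfg = pm.ModelConfig(n_hippocampal=6, n_epochs=100, noise_amp=0.3)
        state = pm.train(small_grid_pop, cfg, np.random.default_rng(0))
        assert np.isfinite(state.A).all()
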