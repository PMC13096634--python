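"""Aquila Optimizer: coefficients, spiral, the four updates, iteration invariants."""

import numpy as np
import pytest

from aohho.aquila import (
    AOParams,
    AquilaOptimizer,
    ao_coefficients,
    ao_iteration,
    ao_select_mode,
    ao_update,
    mean_position,
    spiral_offsets,
)
from aohho.space import SearchBounds

from conftest import ScriptedRng, make_state

PARAMS = AOParams()


class TestMeanPosition:
    def test_single_agent_is_its_own_mean(self):
        state = make_state([[0.3, 0.7], [0.3, 0.7]])
        np.testing.assert_allclose(mean_position(state), [0.3, 0.7])

    def test_hand_computed_mean(self):
        state = make_state([[1, 2], [3, 4], [5, 6]])
        np.testing.assert_allclose(mean_position(state), [3.0, 4.0])


class TestSpiral:
    def test_direct_substitution(self):
        # r1 forced to 1 via scripted uniform -> r = 1 + 0.00565*D1
        rng = ScriptedRng(uniforms=[0.0])
        x, y = spiral_offsets(2, PARAMS, rng)
        r1 = 1.0 + 0.00565 * 1
        theta1 = -0.005 * 1 + 3 * np.pi / 2
        assert x[0] == pytest.approx(r1 * np.sin(theta1))
        assert y[0] == pytest.approx(r1 * np.cos(theta1))

    def test_omega_zero_gives_negative_r_and_zero_y(self):
        params = AOParams(omega=0.0)
        rng = ScriptedRng(uniforms=[0.0])
        x, y = spiral_offsets(1, params, rng)
        assert x[0] == pytest.approx(-(1.0 + 0.00565), abs=1e-12)
        assert y[0] == pytest.approx(0.0, abs=1e-12)

    def test_offsets_bounded_by_max_radius(self):
        rng = np.random.default_rng(0)
        x, y = spiral_offsets(50, PARAMS, rng)
        cap = PARAMS.r1_max + 0.00565 * 50
        assert np.all(np.abs(x) <= cap) and np.all(np.abs(y) <= cap)


class TestCoefficients:
    def test_midpoint_rand_neutralizes_qf_and_g1(self):
        qf, g1, _ = ao_coefficients(5, 10, 0.5)
        assert qf == pytest.approx(1.0)
        assert g1 == pytest.approx(0.0)

    def test_endpoints(self):
        _, g1_lo, _ = ao_coefficients(2, 10, 0.0)
        _, g1_hi, _ = ao_coefficients(2, 10, 1.0)
        assert (g1_lo, g1_hi) == (-1.0, 1.0)
        *_, g2_end = ao_coefficients(10, 10, 0.3)
        assert g2_end == 0.0
        qf_first, *_ = ao_coefficients(1, 10, 0.9)
        assert qf_first == pytest.approx(1.0)  # 1^x = 1

    def test_g2_is_exactly_linear(self):
        i_max = 37
        g2 = [ao_coefficients(t, i_max, 0.5)[2] for t in range(1, i_max + 1)]
        diffs = np.diff(g2)
        np.testing.assert_allclose(diffs, -2.0 / i_max, atol=1e-12)

    def test_single_iteration_budget_rejected(self):
        with pytest.raises(ValueError):
            ao_coefficients(1, 1, 0.5)


class TestModeSelection:
    def test_phases(self):
        rng = np.random.default_rng(0)
        assert ao_select_mode(1, 100, rng) in ("X1", "X2")
        assert ao_select_mode(100, 100, rng) in ("X3", "X4")

    def test_within_phase_split_is_even(self):
        rng = np.random.default_rng(1)
        draws = [ao_select_mode(1, 100, rng) for _ in range(10_000)]
        freq = draws.count("X1") / len(draws)
        assert abs(freq - 0.5) < 0.02


class TestUpdates:
    """Frozen-draw checks of each update against its formula."""

    def setup_method(self):
        self.bounds = SearchBounds(np.array([-10.0, -10.0]), np.array([10.0, 10.0]))

    def test_x1_final_iteration_zero_rand_returns_population_mean(self):
        state = make_state([[1.0, 2.0], [3.0, 4.0]], iteration=10, max_iterations=10)
        rng = ScriptedRng(uniforms=[0.0])
        out = ao_update("X1", state.positions[0], state, PARAMS, self.bounds, rng, 0)
        np.testing.assert_allclose(out, mean_position(state))

    def test_x3_zero_rand_substitution(self):
        state = make_state([[1.0, 2.0], [3.0, 4.0]])
        rng = ScriptedRng(uniforms=[0.0, 0.0])
        out = ao_update("X3", state.positions[0], state, PARAMS, self.bounds, rng, 0)
        expected = (state.best_position - mean_position(state)) * 0.1 + self.bounds.lower * 0.1
        np.testing.assert_allclose(out, np.clip(expected, -10, 10))

    def test_x4_midpoint_rand_and_zero_levy_returns_best(self):
        state = make_state([[0.5, 0.5], [2.0, 2.0]])
        params = AOParams(s=0.0)  # kills the Lévy term
        rng = ScriptedRng(uniforms=[0.5, 0.5, 0.5], normals=[0.1, 0.2, 0.3, 0.4])
        out = ao_update("X4", state.positions[1], state, params, self.bounds, rng, 1)
        np.testing.assert_allclose(out, state.best_position)

    def test_x2_transcription_with_frozen_draws(self):
        from aohho.levy import levy_sigma

        state = make_state([[1.0, -1.0], [0.2, 0.4], [2.0, 3.0]])
        u_norm, v_norm = [0.3, -0.8], [1.1, -0.9]
        r1_u, rand = 0.25, 0.7
        rng = ScriptedRng(uniforms=[r1_u, rand], normals=u_norm + v_norm, integers=[1])
        out = ao_update("X2", state.positions[0], state, PARAMS, self.bounds, rng, 0)

        # independent transcription
        sigma = levy_sigma(1.5)
        lf = 0.01 * np.array(u_norm) * sigma / np.abs(v_norm) ** (1 / 1.5)
        x_r = state.positions[2]  # index 1 skips self at position 0 -> 2
        r1 = 1.0 + r1_u * 19.0
        d1 = np.array([1.0, 2.0])
        r = r1 + 0.00565 * d1
        theta = -0.005 * d1 + 3 * np.pi / 2
        sx, sy = r * np.sin(theta), r * np.cos(theta)
        expected = state.best_position * lf + x_r + (sy - sx) * rand
        np.testing.assert_allclose(out, np.clip(expected, -10, 10), rtol=1e-12)

    def test_unknown_mode_rejected(self):
        state = make_state([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            ao_update("X9", state.positions[0], state, PARAMS, self.bounds,
                      np.random.default_rng(0), 0)

    def test_updates_stay_in_bounds(self, sphere):
        bounds = SearchBounds.unit(3)
        rng = np.random.default_rng(5)
        state = make_state(np.random.default_rng(0).random((6, 3)), max_iterations=20)
        for mode in ("X1", "X2", "X3", "X4"):
            out = ao_update(mode, state.positions[0], state, PARAMS, bounds, rng, 0)
            assert np.all(out >= 0.0) and np.all(out <= 1.0)


class TestIteration:
    def test_monotone_history_and_conserved_population(self, sphere):
        bounds = SearchBounds(np.full(3, -5.0), np.full(3, 5.0))
        rng = np.random.default_rng(2)
        state = make_state(rng.uniform(-5, 5, (8, 3)), max_iterations=30)
        for _ in range(30):
            ao_iteration(state, PARAMS, bounds, sphere, rng)
        assert state.positions.shape == (8, 3)
        assert np.all(np.diff(state.history) <= 0)
        assert np.all(state.positions >= -5.0) and np.all(state.positions <= 5.0)

    def test_elitism_keeps_agent_at_optimum(self, sphere):
        bounds = SearchBounds(np.full(2, -1.0), np.full(2, 1.0))
        positions = np.array([[0.0, 0.0], [0.5, 0.5], [0.9, -0.2]])
        state = make_state(positions, max_iterations=15)
        rng = np.random.default_rng(3)
        for _ in range(15):
            ao_iteration(state, PARAMS, bounds, sphere, rng)
        assert state.best_fitness == 0.0

    def test_failing_objective_reports_agent_context(self):
        bounds = SearchBounds.unit(2)
        state = make_state([[0.5, 0.5], [0.2, 0.8]])

        def broken(x):
            raise FloatingPointError("boom")

        with pytest.raises(RuntimeError, match="agent"):
            ao_iteration(state, PARAMS, bounds, broken, np.random.default_rng(0))


def test_driver_converges_on_sphere(sphere):
    opt = AquilaOptimizer(population_size=10, max_iterations=60, seed=0)
    result = opt.minimize(sphere, SearchBounds(np.full(3, -5.0), np.full(3, 5.0)))
    assert result.fun < 1e-1
    assert result.nfev == 10 * 61
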