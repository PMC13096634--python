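"""Aquila Optimizer (AO): four eagle-hunting position updates.

AO models four hunting behaviors of the Aquila.  With ``X`` the agent,
``X_best`` the incumbent best, ``X_M`` the population mean, ``t``/``T`` the
current/maximum iteration and ``LF(D)`` a Lévy-flight step:

* X1 (expanded exploration, high soar with vertical stoop)::

      X(t+1) = X_best * (1 - t/T) + (X_M - X_best * rand)

* X2 (narrowed exploration, contour flight with short glide attack)::

      X(t+1) = X_best * LF(D) + X_R + (y - x) * rand

  where ``X_R`` is a uniformly chosen other agent and ``(x, y)`` trace a
  spiral: per coordinate index ``D1``, ``r = r1 + 0.00565 * D1`` with
  ``r1 ~ U[1, 20]``, ``theta = -omega * D1 + 3*pi/2``, ``x = r sin(theta)``,
  ``y = r cos(theta)``.

* X3 (enhanced exploitation, low-flying strike)::

      X(t+1) = (X_best - X_M) * alpha - rand + ((UB - LB) * rand + LB) * delta

* X4 (bow hunting, stalking on foot)::

      X(t+1) = QF * X_best - (G1 * X * rand) - G2 * LF(D) + rand * G1

  with quality function ``QF = t^((2 rand - 1) / (1 - T)^2)``,
  mobility ``G1 = 2 rand - 1`` and flight slope ``G2 = 2 (1 - t/T)``
  (linear from 2 to 0).

The first two-thirds of the iteration budget uses the exploration updates
(X1/X2, 50/50), the rest the exploitation updates (X3/X4).  Each scalar
``rand`` appearance draws one fresh uniform; proposals are clipped to the
box and kept only if not worse (greedy retention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .driver import OptimizerState, PopulationOptimizer
from .levy import levy_flight
from .space import SearchBounds, clip_to_bounds

__all__ = [
    "AOParams",
    "mean_position",
    "spiral_offsets",
    "ao_coefficients",
    "ao_select_mode",
    "ao_update",
    "ao_iteration",
    "AquilaOptimizer",
]

AO_MODES = ("X1", "X2", "X3", "X4")


@dataclass(frozen=True)
class AOParams:
    """AO constants: Lévy scale ``s`` and exponent ``beta``, spiral decay
    ``omega`` and slope, exploitation adjustments ``alpha``/``delta``, the
    spiral radius cap ``r1_max`` and the exploration fraction of the budget."""

    s: float = 0.01
    beta: float = 1.5
    omega: float = 0.005
    alpha: float = 0.1
    delta: float = 0.1
    spiral_slope: float = 0.00565
    r1_max: float = 20.0
    exploration_fraction: float = 2.0 / 3.0
    strict_levy_exponent: bool = False

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not (0 < self.beta <= 2):
            raise ValueError("beta must lie in (0, 2]")
        if not (0 < self.alpha <= 1) or not (0 < self.delta <= 1):
            raise ValueError("alpha and delta must lie in (0, 1]")
        if not (0 < self.exploration_fraction < 1):
            raise ValueError("exploration_fraction must lie in (0, 1)")

    def levy(self, dim: int, rng) -> np.ndarray:
        return levy_flight(dim, rng, s=self.s, beta=self.beta,
                           strict_exponent_beta=self.strict_levy_exponent)


def mean_position(state: OptimizerState) -> np.ndarray:
    """Component-wise mean of the current population, ``X_M(t)``."""
    return state.mean_position()


def spiral_offsets(dim: int, params: AOParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Spiral-search offsets ``(x, y)`` for the contour-flight update.

    One radius draw ``r1 ~ U[1, r1_max]`` per call; the coordinate index
    ``D1 = 1..dim`` sweeps the spiral.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    r1 = rng.uniform(1.0, params.r1_max)
    d1 = np.arange(1, dim + 1, dtype=float)
    r = r1 + params.spiral_slope * d1
    theta = -params.omega * d1 + 3.0 * np.pi / 2.0
    return r * np.sin(theta), r * np.cos(theta)


def ao_coefficients(t: int, i_max: int, rand: float) -> tuple[float, float, float]:
    """Quality function QF, mobility G1 and flight slope G2 at iteration ``t``."""
    if not (1 <= t <= i_max):
        raise ValueError("t must satisfy 1 <= t <= i_max")
    if i_max == 1:
        raise ValueError("i_max must exceed 1 (QF exponent denominator is (1 - i_max)^2)")
    if not (0.0 <= rand <= 1.0):
        raise ValueError("rand must lie in [0, 1]")
    qf = float(t) ** ((2.0 * rand - 1.0) / (1.0 - i_max) ** 2)
    g1 = 2.0 * rand - 1.0
    g2 = 2.0 * (1.0 - t / i_max)
    return qf, g1, g2


def ao_select_mode(t: int, i_max: int, rng, exploration_fraction: float = 2.0 / 3.0) -> str:
    """Exploration updates (X1/X2) early, exploitation (X3/X4) late, 50/50 within phase."""
    if not (1 <= t <= i_max):
        raise ValueError("t must satisfy 1 <= t <= i_max")
    pair = ("X1", "X2") if t <= exploration_fraction * i_max else ("X3", "X4")
    return pair[0] if rng.uniform() < 0.5 else pair[1]


def _random_other_index(n: int, exclude: int | None, rng) -> int:
    idx = int(rng.integers(0, n - 1 if exclude is not None else n))
    if exclude is not None and idx >= exclude:
        idx += 1
    return idx


def ao_update(
    mode: str,
    agent: np.ndarray,
    state: OptimizerState,
    params: AOParams,
    bounds: SearchBounds,
    rng,
    agent_index: int | None = None,
) -> np.ndarray:
    """Propose a new position via the selected AO strategy, clipped to bounds.

    Scripted-rng draw order: X1: rand.  X2: Lévy (u then v normals), random
    other-agent index, r1, rand.  X3: rand, rand.  X4: coefficient rand,
    body rand, Lévy (u, v), trailing rand.
    """
    x = np.asarray(agent, dtype=float)
    best = state.best_position
    t, i_max = state.iteration, state.max_iterations
    if mode == "X1":
        rand = rng.uniform()
        new = best * (1.0 - t / i_max) + (state.mean_position() - best * rand)
    elif mode == "X2":
        lf = params.levy(x.shape[0], rng)
        other = _random_other_index(state.population_size, agent_index, rng)
        x_r = state.positions[other]
        sx, sy = spiral_offsets(x.shape[0], params, rng)
        rand = rng.uniform()
        new = best * lf + x_r + (sy - sx) * rand
    elif mode == "X3":
        rand_a = rng.uniform()
        rand_b = rng.uniform()
        new = (best - state.mean_position()) * params.alpha - rand_a + (
            (bounds.upper - bounds.lower) * rand_b + bounds.lower
        ) * params.delta
    elif mode == "X4":
        qf, g1, g2 = ao_coefficients(t, i_max, rng.uniform())
        rand_b = rng.uniform()
        lf = params.levy(x.shape[0], rng)
        rand_c = rng.uniform()
        new = qf * best - (g1 * x * rand_b) - g2 * lf + rand_c * g1
    else:
        raise ValueError(f"unknown AO mode {mode!r}; expected one of {AO_MODES}")
    return clip_to_bounds(new, bounds)


def ao_iteration(state: OptimizerState, params: AOParams, bounds: SearchBounds, fitness_fn, rng) -> OptimizerState:
    """One AO sweep: propose per agent, greedily retain, advance the counter."""
    n = state.population_size
    for i in range(n):
        mode = ao_select_mode(state.iteration, state.max_iterations, rng, params.exploration_fraction)
        candidate = ao_update(mode, state.positions[i], state, params, bounds, rng, agent_index=i)
        try:
            fitness = float(fitness_fn(candidate))
        except Exception as exc:  # annotate which agent failed
            raise RuntimeError(f"objective evaluation failed for agent {i} at t={state.iteration}") from exc
        state.consider(i, candidate, fitness)
    state.iteration += 1
    state.history.append(state.best_fitness)
    return state


class AquilaOptimizer(PopulationOptimizer):
    """AO as a box-constrained minimizer (``minimize(fn, bounds)``)."""

    phase_label = "AO"

    def __init__(self, population_size: int = 15, max_iterations: int = 100,
                 seed=None, params: AOParams | None = None, **kwargs):
        super().__init__(population_size, max_iterations, seed, **kwargs)
        self.params = params or AOParams()

    def _iterate(self, state, bounds, fn, rng) -> None:
        ao_iteration(state, self.params, bounds, fn, rng)
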