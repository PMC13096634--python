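"""Harris Hawks Optimization (HHO): energy-gated exploration and besiege modes.

HHO models cooperative hawk hunting.  A per-agent escape energy

    E = 2 * E0 * (1 - t/T),   E0 ~ U[-1, 1]

decays with the iteration count and, together with an escape probability
``r ~ U[0, 1]``, gates which update applies:

* ``|E| >= 1`` — exploration (two perching strategies chosen by ``q``)::

      q >= 0.5:  X(t+1) = X_R - rand * |X_R - 2 * rand * X|
      q <  0.5:  X(t+1) = (X_best - X_M) - rand * (LB + rand * (UB - LB))

* soft besiege (``r >= 0.5``, ``|E| >= 0.5``)::

      X(t+1) = dX - E * |J * X_best - X|,  dX = X_best - X,  J = 2 (1 - rand)

* hard besiege (``r >= 0.5``, ``|E| < 0.5``)::

      X(t+1) = X_best - E * |dX|

* soft/hard besiege with progressive rapid dives (``r < 0.5``)::

      Y = X_best - E * |J * X_best - X|
      Z = Y + S * LF(D),  S ~ U[0, 1]^D

  the fitter of Y and Z replaces the agent if it improves on it, otherwise
  the agent is kept unchanged.

``|.|`` is the component-wise absolute value.  All proposals are clipped to
the box; non-dive proposals are greedily retained (kept iff not worse).
The hard-dive mode reuses the Y/Z equations literally; the variant that
replaces ``X`` with the population mean in Y is available behind
``canonical_hard_dive``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .driver import OptimizerState, PopulationOptimizer
from .levy import levy_flight
from .space import SearchBounds, clip_to_bounds

__all__ = [
    "HHOParams",
    "escape_energy",
    "jump_strength",
    "hho_select_mode",
    "hho_explore",
    "hho_besiege",
    "hho_iteration",
    "HarrisHawksOptimizer",
]

HHO_MODES = ("explore", "soft", "hard", "soft_dive", "hard_dive")


@dataclass(frozen=True)
class HHOParams:
    """Random-variable conventions for HHO.

    ``q``, the escape probability ``r`` and the dive vector ``S`` are uniform
    reals; ``E0`` is redrawn per agent per iteration, uniform in [-1, 1].
    The Lévy step shares the AO generator defaults (s=0.01, beta=1.5).
    """

    s: float = 0.01
    beta: float = 1.5
    canonical_hard_dive: bool = False
    strict_levy_exponent: bool = False

    def levy(self, dim: int, rng) -> np.ndarray:
        return levy_flight(dim, rng, s=self.s, beta=self.beta,
                           strict_exponent_beta=self.strict_levy_exponent)


def escape_energy(e0: float, t: int, i_max: int) -> float:
    """Prey escape energy ``E = 2 * E0 * (1 - t/i_max)``."""
    if not (1 <= t <= i_max):
        raise ValueError("t must satisfy 1 <= t <= i_max")
    return 2.0 * e0 * (1.0 - t / i_max)


def jump_strength(rand: float) -> float:
    """Prey jump magnitude ``J = 2 * (1 - rand)`` in [0, 2]."""
    if not (0.0 <= rand <= 1.0):
        raise ValueError("rand must lie in [0, 1]")
    return 2.0 * (1.0 - rand)


def hho_select_mode(e: float, escape_prob: float) -> str:
    """Pick the update mode from escape energy ``E`` and escape probability ``r``."""
    if not (0.0 <= escape_prob <= 1.0):
        raise ValueError("escape_prob must lie in [0, 1]")
    if abs(e) >= 1.0:
        return "explore"
    if escape_prob >= 0.5:
        return "soft" if abs(e) >= 0.5 else "hard"
    return "soft_dive" if abs(e) >= 0.5 else "hard_dive"


def _random_other_index(n: int, exclude: int | None, rng) -> int:
    idx = int(rng.integers(0, n - 1 if exclude is not None else n))
    if exclude is not None and idx >= exclude:
        idx += 1
    return idx


def hho_explore(
    agent: np.ndarray,
    state: OptimizerState,
    bounds: SearchBounds,
    rng,
    agent_index: int | None = None,
) -> np.ndarray:
    """Perching exploration update, clipped to bounds.

    Scripted-rng draw order: q; then (q >= 0.5) other-agent index, rand, rand
    or (q < 0.5) rand, rand.
    """
    x = np.asarray(agent, dtype=float)
    q = rng.uniform()
    if q >= 0.5:
        other = _random_other_index(state.population_size, agent_index, rng)
        x_r = state.positions[other]
        r1, r2 = rng.uniform(), rng.uniform()
        new = x_r - r1 * np.abs(x_r - 2.0 * r2 * x)
    else:
        r3, r4 = rng.uniform(), rng.uniform()
        new = (state.best_position - state.mean_position()) - r3 * (
            bounds.lower + r4 * (bounds.upper - bounds.lower)
        )
    return clip_to_bounds(new, bounds)


def hho_besiege(
    mode: str,
    agent: np.ndarray,
    state: OptimizerState,
    e: float,
    bounds: SearchBounds,
    fitness_fn,
    rng,
    params: HHOParams | None = None,
    agent_fitness: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Besiege update; returns ``(position, fitness_or_None)``.

    Soft/hard besiege return the clipped proposal with fitness ``None`` (the
    caller evaluates and greedily retains).  Dive modes evaluate both dive
    candidates Y and Z themselves and return the fitter one if it improves on
    the agent, else the agent unchanged with its known fitness.

    Scripted-rng draw order: soft: J-rand.  dives: J-rand, S vector,
    Lévy (u, v).
    """
    params = params or HHOParams()
    x = np.asarray(agent, dtype=float)
    best = state.best_position
    if mode == "soft":
        j = jump_strength(rng.uniform())
        new = (best - x) - e * np.abs(j * best - x)
        return clip_to_bounds(new, bounds), None
    if mode == "hard":
        new = best - e * np.abs(best - x)
        return clip_to_bounds(new, bounds), None
    if mode in ("soft_dive", "hard_dive"):
        j = jump_strength(rng.uniform())
        anchor = state.mean_position() if (mode == "hard_dive" and params.canonical_hard_dive) else x
        y = best - e * np.abs(j * best - anchor)
        y = clip_to_bounds(y, bounds)
        s = rng.uniform(size=x.shape[0])
        z = y + s * params.levy(x.shape[0], rng)
        z = clip_to_bounds(z, bounds)
        f_x = float(fitness_fn(x)) if agent_fitness is None else float(agent_fitness)
        f_y = float(fitness_fn(y))
        f_z = float(fitness_fn(z))
        if f_y < f_x or f_z < f_x:
            return (y, f_y) if f_y <= f_z else (z, f_z)
        return x, f_x
    raise ValueError(f"unknown HHO mode {mode!r}; expected one of {HHO_MODES}")


def hho_iteration(
    state: OptimizerState,
    bounds: SearchBounds,
    fitness_fn,
    rng,
    params: HHOParams | None = None,
) -> OptimizerState:
    """One HHO sweep: energy draw, mode selection, update, greedy retention.

    Per agent the draw order is: E0 ~ U[-1, 1], escape probability r, then the
    draws of the selected update.
    """
    params = params or HHOParams()
    n = state.population_size
    for i in range(n):
        e0 = rng.uniform(-1.0, 1.0)
        escape_prob = rng.uniform()
        e = escape_energy(e0, state.iteration, state.max_iterations)
        mode = hho_select_mode(e, escape_prob)
        try:
            if mode == "explore":
                candidate = hho_explore(state.positions[i], state, bounds, rng, agent_index=i)
                fitness = float(fitness_fn(candidate))
            else:
                candidate, fitness = hho_besiege(
                    mode, state.positions[i], state, e, bounds, fitness_fn, rng,
                    params=params, agent_fitness=float(state.fitnesses[i]),
                )
                if fitness is None:
                    fitness = float(fitness_fn(candidate))
        except Exception as exc:
            raise RuntimeError(f"objective evaluation failed for agent {i} at t={state.iteration}") from exc
        state.consider(i, candidate, fitness)
    state.iteration += 1
    state.history.append(state.best_fitness)
    return state


class HarrisHawksOptimizer(PopulationOptimizer):
    """HHO as a box-constrained minimizer (``minimize(fn, bounds)``)."""

    phase_label = "HHO"

    def __init__(self, population_size: int = 15, max_iterations: int = 100,
                 seed=None, params: HHOParams | None = None, **kwargs):
        super().__init__(population_size, max_iterations, seed, **kwargs)
        self.params = params or HHOParams()

    def _iterate(self, state, bounds, fn, rng) -> None:
        hho_iteration(state, bounds, fn, rng, self.params)
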