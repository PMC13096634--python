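"""Population state and the shared driver loop for the swarm optimizers.

All optimizers in this package (Aquila, Harris Hawks and the AO->HHO hybrid)
minimize a scalar function over a box.  They share one loop: sample an initial
uniform population, evaluate it, then repeatedly propose a new position per
agent and keep it only if it is not worse (greedy retention).  Greedy
retention plus tracking of the incumbent best gives the elitism contract:
the best-so-far objective is monotonically non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .space import SearchBounds, sample_population

__all__ = ["OptimizerState", "MinimizeResult", "PopulationOptimizer", "check_convergence"]


@dataclass
class OptimizerState:
    """Population snapshot carried between iterations.

    ``iteration`` is the 1-based counter ``t`` of the next iteration to run;
    ``history`` holds the best-so-far objective after initialization and after
    each completed iteration, so it is non-increasing by construction.
    """

    positions: np.ndarray          # (N, D)
    fitnesses: np.ndarray          # (N,)
    best_position: np.ndarray
    best_fitness: float
    iteration: int
    max_iterations: int
    history: list = field(default_factory=list)

    @property
    def population_size(self) -> int:
        return self.positions.shape[0]

    def mean_position(self) -> np.ndarray:
        """Component-wise population mean (the AO ``X_M(t)`` term)."""
        if self.positions.shape[0] == 0:
            raise ValueError("population is empty")
        return self.positions.mean(axis=0)

    def consider(self, index: int, position: np.ndarray, fitness: float) -> bool:
        """Greedy retention: replace agent ``index`` iff not worse; refresh best."""
        accepted = fitness <= self.fitnesses[index]
        if accepted:
            self.positions[index] = position
            self.fitnesses[index] = fitness
        if fitness < self.best_fitness:
            self.best_fitness = float(fitness)
            self.best_position = np.array(position, dtype=float, copy=True)
        return accepted


def check_convergence(history, epsilon: float, patience: int) -> bool:
    """True iff the last ``patience`` successive absolute changes are all < epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    h = np.asarray(list(history), dtype=float)
    if h.size < patience + 1:
        return False
    changes = np.abs(np.diff(h[-(patience + 1):]))
    return bool(np.all(changes < epsilon))


@dataclass
class MinimizeResult:
    """Outcome of one optimizer run."""

    x: np.ndarray
    fun: float
    history: list                  # (iteration, phase, best_objective) triples
    nfev: int
    converged_early: bool
    state: OptimizerState


class _CountingFn:
    def __init__(self, fn: Callable[[np.ndarray], float]):
        self.fn = fn
        self.nfev = 0

    def __call__(self, x: np.ndarray) -> float:
        self.nfev += 1
        return float(self.fn(x))


class PopulationOptimizer:
    """Base driver: init + evaluate + iterate until budget or convergence.

    Subclasses implement ``_iterate(state, bounds, fn, rng)`` (one sweep over
    the population at ``t = state.iteration``, ending with the counter
    incremented and the history appended) and ``_phase(t)`` (label for the
    run history).  Early stopping triggers when the best objective has changed
    by less than ``epsilon`` for ``patience`` consecutive iterations.
    """

    phase_label = "OPT"

    def __init__(
        self,
        population_size: int = 15,
        max_iterations: int = 100,
        seed: Optional[int] = None,
        epsilon: float = 1e-4,
        patience: int = 10,
        early_stopping: bool = False,
    ):
        if population_size < 2:
            raise ValueError("population_size must be >= 2")
        if max_iterations < 2:
            raise ValueError("max_iterations must be >= 2")
        self.population_size = population_size
        self.max_iterations = max_iterations
        self.seed = seed
        self.epsilon = epsilon
        self.patience = patience
        self.early_stopping = early_stopping

    # -- hooks -------------------------------------------------------------
    def _phase(self, t: int) -> str:
        return self.phase_label

    def _iterate(self, state: OptimizerState, bounds: SearchBounds, fn, rng) -> None:
        raise NotImplementedError

    # -- driver ------------------------------------------------------------
    def init_state(self, fn, bounds: SearchBounds, rng) -> OptimizerState:
        positions = sample_population(self.population_size, bounds, rng)
        fitnesses = np.array([fn(x) for x in positions], dtype=float)
        if not np.any(np.isfinite(fitnesses)):
            raise RuntimeError("objective returned no finite value on the initial population")
        best = int(np.argmin(fitnesses))
        state = OptimizerState(
            positions=positions,
            fitnesses=fitnesses,
            best_position=positions[best].copy(),
            best_fitness=float(fitnesses[best]),
            iteration=1,
            max_iterations=self.max_iterations,
        )
        state.history.append(state.best_fitness)
        return state

    def minimize(self, fn: Callable[[np.ndarray], float], bounds: SearchBounds) -> MinimizeResult:
        rng = np.random.default_rng(self.seed)
        counting = _CountingFn(fn)
        state = self.init_state(counting, bounds, rng)
        labeled: list = []
        converged = False
        for t in range(1, self.max_iterations + 1):
            self._iterate(state, bounds, counting, rng)
            labeled.append((t, self._phase(t), state.best_fitness))
            if self.early_stopping and check_convergence(state.history, self.epsilon, self.patience):
                converged = True
                break
        return MinimizeResult(
            x=state.best_position.copy(),
            fun=state.best_fitness,
            history=labeled,
            nfev=counting.nfev,
            converged_early=converged,
            state=state,
        )
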