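"""AO -> HHO hybrid driver and the configuration-level tuning front end.

The hybrid runs Aquila-Optimizer iterations (global exploration) for the
first ``ceil(switch_fraction * I)`` iterations, then hands the full
population and incumbent best to Harris-Hawks iterations (energy-gated local
exploitation) for the remainder — a single hard switch, no re-initialization,
so the best-so-far objective is preserved exactly across the hand-off.  A run
stops early once the best objective has changed by less than ``epsilon`` for
``patience`` consecutive iterations.

``optimize`` wraps the driver for CNN hyperparameter tuning: optimizer-space
vectors are decoded to configurations, and a fitness cache keyed by the
decoded configuration serves duplicates (e.g. categorical plateaus) without
re-training.  ``ablate`` runs AO-only, HHO-only and the hybrid from identical
seeds for paired comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .aquila import AOParams, ao_iteration
from .driver import MinimizeResult, PopulationOptimizer, check_convergence
from .hho import HHOParams, hho_iteration
from .space import CNNConfig, HyperparameterSpace, SearchBounds, decode

__all__ = [
    "HybridConfig",
    "OptimizationResult",
    "HybridAOHHO",
    "optimize",
    "ablate",
    "check_convergence",
]


@dataclass(frozen=True)
class HybridConfig:
    """Run configuration: population size P, iteration budget I, the AO->HHO
    switch fraction, and the convergence test (epsilon, patience)."""

    population_size: int = 15
    max_iterations: int = 40
    switch_fraction: float = 0.5
    epsilon: float = 1e-4
    patience: int = 10
    seed: Optional[int] = None
    early_stopping: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 2:
            raise ValueError("max_iterations must be >= 2")
        if not (0.0 <= self.switch_fraction <= 1.0):
            raise ValueError("switch_fraction must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class OptimizationResult:
    """Best decoded configuration plus the labeled convergence history."""

    best_config: CNNConfig
    best_objective: float
    history: list                  # (iteration, phase, best_objective)
    evaluations_used: int
    converged_early: bool
    best_vector: np.ndarray = field(default=None)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history, columns=["iteration", "phase", "best_objective"])


class HybridAOHHO(PopulationOptimizer):
    """The hybrid minimizer: AO iterations up to the switch point, HHO after.

    With ``switch_fraction=1`` the trajectory is bit-identical to
    :class:`~aohho.aquila.AquilaOptimizer` under the same seed; with
    ``switch_fraction=0`` to :class:`~aohho.hho.HarrisHawksOptimizer`.
    """

    def __init__(
        self,
        population_size: int = 15,
        max_iterations: int = 100,
        seed=None,
        switch_fraction: float = 0.5,
        ao_params: AOParams | None = None,
        hho_params: HHOParams | None = None,
        **kwargs,
    ):
        super().__init__(population_size, max_iterations, seed, **kwargs)
        if not (0.0 <= switch_fraction <= 1.0):
            raise ValueError("switch_fraction must lie in [0, 1]")
        self.switch_fraction = switch_fraction
        self.ao_params = ao_params or AOParams()
        self.hho_params = hho_params or HHOParams()

    @property
    def switch_iteration(self) -> int:
        return math.ceil(self.switch_fraction * self.max_iterations)

    def _phase(self, t: int) -> str:
        return "AO" if t <= self.switch_iteration else "HHO"

    def _iterate(self, state, bounds, fn, rng) -> None:
        if state.iteration <= self.switch_iteration:
            ao_iteration(state, self.ao_params, bounds, fn, rng)
        else:
            hho_iteration(state, bounds, fn, rng, self.hho_params)


class _ConfigCache:
    """Fitness cache keyed by the decoded configuration; counts misses."""

    def __init__(self, fitness_fn: Callable[[CNNConfig], float], space: HyperparameterSpace):
        self.fitness_fn = fitness_fn
        self.space = space
        self.cache: dict = {}
        self.misses = 0
        self.failures = 0

    def __call__(self, u: np.ndarray) -> float:
        config = decode(u, self.space)
        key = tuple(config.as_dict().values())
        if key not in self.cache:
            self.misses += 1
            try:
                self.cache[key] = float(self.fitness_fn(config))
            except Exception:
                self.failures += 1
                raise
        return self.cache[key]


def _make_driver(config: HybridConfig, algorithm: str = "ao-hho") -> PopulationOptimizer:
    kwargs = dict(
        population_size=config.population_size,
        max_iterations=config.max_iterations,
        seed=config.seed,
        epsilon=config.epsilon,
        patience=config.patience,
        early_stopping=config.early_stopping,
    )
    algorithm = algorithm.lower()
    if algorithm == "ao-hho":
        return HybridAOHHO(switch_fraction=config.switch_fraction, **kwargs)
    if algorithm == "ao":
        return HybridAOHHO(switch_fraction=1.0, **kwargs)
    if algorithm == "hho":
        return HybridAOHHO(switch_fraction=0.0, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected 'ao', 'hho' or 'ao-hho'")


def optimize(
    fitness_fn: Callable[[CNNConfig], float],
    space: HyperparameterSpace,
    config: HybridConfig,
    algorithm: str = "ao-hho",
) -> OptimizationResult:
    """Tune a configuration-level objective with the hybrid (or a single arm).

    ``fitness_fn`` maps a :class:`CNNConfig` to a scalar objective to
    minimize.  Duplicate decoded configurations are served from a cache, so
    ``evaluations_used`` counts actual objective evaluations (cache misses).
    """
    cache = _ConfigCache(fitness_fn, space)
    driver = _make_driver(config, algorithm)
    bounds = SearchBounds.unit(space.dimension)
    try:
        result = driver.minimize(cache, bounds)
    except Exception as exc:
        if cache.misses > 0 and cache.misses == cache.failures:
            raise RuntimeError(
                "objective failed on every evaluated candidate; check the fitness function"
            ) from exc
        raise
    return OptimizationResult(
        best_config=decode(result.x, space),
        best_objective=result.fun,
        history=result.history,
        evaluations_used=cache.misses,
        converged_early=result.converged_early,
        best_vector=result.x,
    )


def ablate(
    fitness_fn: Callable[[CNNConfig], float],
    space: HyperparameterSpace,
    config: HybridConfig,
) -> dict[str, OptimizationResult]:
    """Run AO-only, HHO-only and AO-HHO with identical seeds and budgets.

    All three arms share the seed, so their initial populations (and hence
    the pairing needed for paired tests) are identical.
    """
    return {name: optimize(fitness_fn, space, config, algorithm=name)
            for name in ("ao", "hho", "ao-hho")}
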