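"""Shared fixtures: small populations, unit bounds and a scripted RNG.

The scripted RNG lets update equations be checked against line-by-line
transcriptions with frozen random draws: both the implementation and the
transcription consume the same queued numbers in the documented draw order.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from aohho.driver import OptimizerState
from aohho.space import SearchBounds

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")


class ScriptedRng:
    """Replays queued uniforms / normals / integers in call order."""

    def __init__(self, uniforms=(), normals=(), integers=()):
        self._uniforms = list(uniforms)
        self._normals = list(normals)
        self._integers = list(integers)

    def _pop_uniform(self):
        if not self._uniforms:
            raise AssertionError("scripted rng ran out of uniforms")
        return float(self._uniforms.pop(0))

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return low + self._pop_uniform() * (high - low)
        return np.array([low + self._pop_uniform() * (high - low)
                         for _ in range(int(np.prod(size)))]).reshape(size)

    def random(self, size=None):
        return self.uniform(size=size)

    def standard_normal(self, n):
        if len(self._normals) < n:
            raise AssertionError("scripted rng ran out of normals")
        out = np.array([float(self._normals.pop(0)) for _ in range(n)])
        return out

    def integers(self, low, high=None):
        if not self._integers:
            raise AssertionError("scripted rng ran out of integers")
        return int(self._integers.pop(0))


@pytest.fixture
def unit_bounds_2d() -> SearchBounds:
    return SearchBounds.unit(2)


def make_state(positions, fitnesses=None, iteration=1, max_iterations=10) -> OptimizerState:
    positions = np.asarray(positions, dtype=float)
    if fitnesses is None:
        fitnesses = np.array([float(np.sum(p * p)) for p in positions])
    best = int(np.argmin(fitnesses))
    state = OptimizerState(
        positions=positions.copy(),
        fitnesses=np.asarray(fitnesses, dtype=float),
        best_position=positions[best].copy(),
        best_fitness=float(fitnesses[best]),
        iteration=iteration,
        max_iterations=max_iterations,
    )
    state.history.append(state.best_fitness)
    return state


@pytest.fixture
def sphere():
    return lambda x: float(np.sum(np.asarray(x) ** 2))
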