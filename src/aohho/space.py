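"""Mixed continuous/categorical hyperparameter space and its continuous relaxation.

The tuned space couples one continuous hyperparameter (learning rate) with four
categorical ones (batch size, base filter count, dropout rate, optimizer kind).
Population-based metaheuristics such as the Aquila Optimizer and Harris Hawks
Optimization operate on real vectors, so the space is relaxed onto the unit
hypercube ``[0, 1]^5``: the learning-rate coordinate is decoded log-uniformly
over its range and each categorical coordinate by equal-width binning of
``[0, 1]`` into as many bins as there are choices.  ``decode`` and ``encode``
form a bijection on valid configurations (categoricals map back to bin
centers, the learning rate to its log-scale position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SearchBounds",
    "HyperparameterSpace",
    "CNNConfig",
    "decode",
    "encode",
    "clip_to_bounds",
    "sample_population",
]


@dataclass(frozen=True)
class SearchBounds:
    """Box constraints ``[lower, upper]`` for an optimizer-space real vector."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        if lo.ndim != 1 or up.ndim != 1 or lo.shape != up.shape:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not np.all(lo < up):
            raise ValueError("each lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @property
    def dimension(self) -> int:
        return self.lower.shape[0]

    @classmethod
    def unit(cls, dimension: int) -> "SearchBounds":
        """The unit hypercube ``[0, 1]^D`` used for the relaxed space."""
        if dimension < 1:
            raise ValueError("dimension must be >= 1")
        return cls(np.zeros(dimension), np.ones(dimension))


@dataclass(frozen=True)
class HyperparameterSpace:
    """The default CNN hyperparameter search space.

    Defaults: learning rate in [1e-4, 1e-2] (searched on a log scale),
    batch size in {16, 32, 64}, base filters in {32, 64, 128},
    dropout in {0.3, 0.5}, optimizer in {adam, sgd}.
    """

    learning_rate_range: tuple[float, float] = (1e-4, 1e-2)
    batch_choices: tuple[int, ...] = (16, 32, 64)
    filter_choices: tuple[int, ...] = (32, 64, 128)
    dropout_choices: tuple[float, ...] = (0.3, 0.5)
    optimizer_choices: tuple[str, ...] = ("adam", "sgd")

    def __post_init__(self) -> None:
        lo, hi = self.learning_rate_range
        if not (0 < lo < hi):
            raise ValueError("learning_rate_range must satisfy 0 < min < max")
        for name in ("batch_choices", "filter_choices", "dropout_choices", "optimizer_choices"):
            choices = getattr(self, name)
            if len(choices) == 0:
                raise ValueError(f"{name} must be non-empty")
        for name in ("batch_choices", "filter_choices", "dropout_choices"):
            choices = getattr(self, name)
            if list(choices) != sorted(choices):
                raise ValueError(f"{name} must be sorted ascending")

    @property
    def dimension(self) -> int:
        return 5

    @property
    def categorical_choices(self) -> tuple[tuple, ...]:
        return (self.batch_choices, self.filter_choices, self.dropout_choices, self.optimizer_choices)

    @classmethod
    def from_dict(cls, cfg: dict) -> "HyperparameterSpace":
        """Build a space from a config mapping (YAML/JSON block)."""
        kwargs = {}
        if "learning_rate" in cfg:
            kwargs["learning_rate_range"] = tuple(float(v) for v in cfg["learning_rate"])
        if "batch_size" in cfg:
            kwargs["batch_choices"] = tuple(int(v) for v in cfg["batch_size"])
        if "filters" in cfg:
            kwargs["filter_choices"] = tuple(int(v) for v in cfg["filters"])
        if "dropout" in cfg:
            kwargs["dropout_choices"] = tuple(float(v) for v in cfg["dropout"])
        if "optimizer" in cfg:
            kwargs["optimizer_choices"] = tuple(str(v).lower() for v in cfg["optimizer"])
        return cls(**kwargs)


@dataclass(frozen=True)
class CNNConfig:
    """One decoded CNN training configuration."""

    learning_rate: float
    batch_size: int
    base_filters: int
    dropout_rate: float
    optimizer_kind: str

    def validate(self, space: HyperparameterSpace) -> None:
        lo, hi = space.learning_rate_range
        if not (lo <= self.learning_rate <= hi):
            raise ValueError(f"learning_rate {self.learning_rate} outside [{lo}, {hi}]")
        pairs = [
            ("batch_size", self.batch_size, space.batch_choices),
            ("base_filters", self.base_filters, space.filter_choices),
            ("dropout_rate", self.dropout_rate, space.dropout_choices),
            ("optimizer_kind", self.optimizer_kind, space.optimizer_choices),
        ]
        for name, value, choices in pairs:
            if value not in choices:
                raise ValueError(f"{name}={value!r} not among {choices}")

    def as_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "base_filters": self.base_filters,
            "dropout_rate": self.dropout_rate,
            "optimizer_kind": self.optimizer_kind,
        }


def _bin_index(u: float, n_bins: int) -> int:
    # half-open bins; u == 1.0 belongs to the last bin so decode is total on [0, 1]
    return min(int(math.floor(u * n_bins)), n_bins - 1)


def decode(u: np.ndarray, space: HyperparameterSpace) -> CNNConfig:
    """Map a unit-hypercube vector to a CNN configuration.

    Coordinate order: (learning rate, batch size, base filters, dropout,
    optimizer).  The learning rate is decoded log-uniformly; categorical
    coordinates by equal-width binning with the component 1.0 assigned to
    the last bin.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (space.dimension,):
        raise ValueError(f"expected vector of dimension {space.dimension}, got shape {u.shape}")
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("components must lie in [0, 1]; clip to bounds first")
    lo, hi = space.learning_rate_range
    lr = 10.0 ** (math.log10(lo) + u[0] * (math.log10(hi) - math.log10(lo)))
    cats = []
    for coord, choices in zip(u[1:], space.categorical_choices):
        cats.append(choices[_bin_index(float(coord), len(choices))])
    batch, filters, dropout, opt = cats
    return CNNConfig(
        learning_rate=float(lr),
        batch_size=int(batch),
        base_filters=int(filters),
        dropout_rate=float(dropout),
        optimizer_kind=str(opt),
    )


def encode(config: CNNConfig, space: HyperparameterSpace) -> np.ndarray:
    """Inverse of :func:`decode`: categorical values map to their bin centers."""
    config.validate(space)
    lo, hi = space.learning_rate_range
    u0 = (math.log10(config.learning_rate) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
    values = (config.batch_size, config.base_filters, config.dropout_rate, config.optimizer_kind)
    coords = [u0]
    for value, choices in zip(values, space.categorical_choices):
        idx = choices.index(value)
        coords.append((idx + 0.5) / len(choices))
    return np.asarray(coords, dtype=float)


def clip_to_bounds(x: np.ndarray, bounds: SearchBounds) -> np.ndarray:
    """Clamp a vector (or stack of vectors) into the box; idempotent."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != bounds.dimension:
        raise ValueError(f"vector dimension {x.shape[-1]} != bounds dimension {bounds.dimension}")
    return np.clip(x, bounds.lower, bounds.upper)


def sample_population(n: int, bounds: SearchBounds, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. uniform agents inside the box; reproducible from seed.

    At least two agents are required: the mean-position term of the Aquila
    updates and the rabbit/hawk roles in Harris Hawks both need a population.
    """
    if n < 2:
        raise ValueError("population size must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(bounds.lower, bounds.upper, size=(n, bounds.dimension))
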