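"""Lévy-flight step generator (Mantegna scheme), shared by the AO and HHO updates.

A Lévy flight injects occasional long jumps into the search.  Steps are
generated per coordinate as ``s * u * sigma / |v|^(1/beta)`` with
``u, v ~ N(0, 1)`` and

    sigma = Gamma(1 + beta) * sin(pi * beta / 2)
            / (Gamma((1 + beta) / 2) * beta * 2^((beta - 1) / 2))

The ``1/beta`` exponent on ``|v|`` is the canonical Mantegna form, which gives
the heavy-tailed step distribution the algorithms rely on; a
``strict_exponent_beta`` flag exposes the variant with ``|v|^beta`` instead,
under which steps at ``beta = 1.5`` collapse toward zero rather than
heavy-tail (kept for side-by-side comparison only).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gamma as _gamma

__all__ = ["levy_sigma", "levy_flight"]


def levy_sigma(beta: float) -> float:
    """Mantegna scale factor ``sigma`` for Lévy exponent ``beta`` in (0, 2]."""
    if not (0.0 < beta <= 2.0):
        raise ValueError("beta must lie in (0, 2]")
    num = _gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float(num / den)


def levy_flight(
    dim: int,
    rng: np.random.Generator,
    s: float = 0.01,
    beta: float = 1.5,
    strict_exponent_beta: bool = False,
) -> np.ndarray:
    """Draw a ``dim``-vector of Lévy steps.

    Draw order (relevant for scripted-rng tests): first the ``dim`` numerator
    normals ``u``, then the ``dim`` denominator normals ``v``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sigma = levy_sigma(beta)
    u = rng.standard_normal(dim) * sigma
    v = rng.standard_normal(dim)
    exponent = beta if strict_exponent_beta else 1.0 / beta
    return s * u / np.abs(v) ** exponent
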