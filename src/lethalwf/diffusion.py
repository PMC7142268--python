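"""Diffusion-approximation coefficients of the lethal-allele chain.

The chain's density obeys a forward Kolmogorov (diffusion) equation with
drift F(x) — the deterministic force — and infinitesimal variance

    V(x) = [x + F(x)] [1 - (2x + 2F(x))] / (2N).

V(x) is not asymptotic: it equals the chain's one-step variance
identically, since Var[Bin(N, p)]/(2N)^2 = p(1-p)/(4N) with
p = 2x + 2F(x).  For x, u << 1 the coefficients reduce to

    F(x) ~= u (1 - h) - h x,      V(x) ~= (1 - h)(x + u) / (2N),

so at low frequency the allele drifts like a neutral-ish allele in a
population of effective size N / (1 - h).  Only the coefficients are
exposed; the chain itself is exact and cheap, so no PDE solver is
provided.
"""

from __future__ import annotations

import numpy as np

from .deterministic import _force_raw
from .params import PopulationParams, check_frequency

__all__ = [
    "infinitesimal_variance",
    "small_x_coefficients",
    "coefficient_table",
]


def infinitesimal_variance(x: float, params: PopulationParams) -> float:
    """One-generation variance V(x) of the frequency at frequency x.

    Exactly the variance of the binomial update, V(x) = p(1-p)/(4N) with
    p = 2x + 2F(x); non-negative on [0, 1/2] and zero only where p is 0
    or 1.
    """
    x = check_frequency(x)
    if params.is_infinite:
        raise ValueError("infinitesimal variance needs a finite N")
    f = _force_raw(x, params.h, params.u)
    p = 2.0 * (x + f)
    return (x + f) * (1.0 - p) / (2.0 * params.N)


def small_x_coefficients(
    x: float, params: PopulationParams
) -> tuple[float, float]:
    """Leading-order drift and variance for x << 1.

    Returns ``(u (1 - h) - h x, (1 - h)(x + u) / (2N))``.  Assumes h is
    not equal to 1 (a fully dominant lethal never reaches appreciable
    frequency, and the expansion degenerates there).  No cutoff on x is
    enforced; accuracy is the caller's concern.
    """
    x = check_frequency(x)
    h, u = params.h, params.u
    drift = u * (1.0 - h) - h * x
    if params.is_infinite:
        raise ValueError("small-x variance needs a finite N")
    var = (1.0 - h) * (x + u) / (2.0 * params.N)
    return drift, var


def coefficient_table(params: PopulationParams,
                      x_grid=None) -> "np.ndarray":
    """Structured array of (x, F(x), V(x), and their small-x forms)
    over a frequency grid, ready for TSV dumping or plotting."""
    if x_grid is None:
        x_grid = np.linspace(0.0, 0.5, 101)
    x_grid = np.asarray(x_grid, dtype=float)
    rows = np.empty(
        x_grid.size,
        dtype=[("x", float), ("drift", float), ("variance", float),
               ("drift_small_x", float), ("variance_small_x", float)],
    )
    for i, x in enumerate(x_grid):
        f = _force_raw(float(x), params.h, params.u)
        v = infinitesimal_variance(float(x), params)
        ds, vs = small_x_coefficients(float(x), params)
        rows[i] = (x, f, v, ds, vs)
    return rows
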