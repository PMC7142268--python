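"""Deterministic (infinite-population) dynamics of a lethal allele.

One generation maps the adult frequency x of the lethal allele through
gamete mutation (y = u + (1 - u) x), random union into zygotes, and
viability selection with fitnesses (0, 1 - h, 1):

    x' = (1 - h) y / (1 + (1 - 2h) y),

so the per-generation evolutionary force is F(x) = x' - x, a rational
function whose numerator is the quadratic

    (1 - h) u - [h + (2 - 3h) u] x - (1 - 2h)(1 - u) x**2

over the denominator 1 + (1 - 2h) u + (1 - 2h)(1 - u) x.  Setting the
numerator to zero gives the unique stable equilibrium on [0, 1/2],

    x_hat = 2 (1 - h) u / ( h + (2 - 3h) u
                            + sqrt(h**2 (1 + u)**2 + 4 (1 - 2h) u) ),

evaluated here with the cancellation-free branch of the quadratic formula
(the printed form loses ~8 digits when h < 0 and u is small).
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

from .params import (
    DominanceSchedule,
    EquilibriumResult,
    HalfTimeResult,
    PopulationParams,
    check_frequency,
)

__all__ = [
    "relative_fitnesses",
    "deterministic_force",
    "step_infinite",
    "trajectory_infinite",
    "equilibrium_exact",
    "equilibrium_approx",
    "half_time_exact_infinite",
    "half_time_approx_rise",
    "half_time_approx_fall",
]

#: Roundoff tolerance for the structural bound 0 <= x + F(x) <= 1/2.
_BOUND_EPS = 1e-12

#: |F(x_hat)| below this counts as a fixed point.
FIXED_POINT_TOL = 1e-12


def relative_fitnesses(params: PopulationParams) -> tuple[float, float, float]:
    """Relative genotype fitnesses (w_aa, w_aA, w_AA) = (0, 1 - h, 1)."""
    return params.fitnesses()


def _force_raw(x, h: float, u: float):
    """F(x) without domain checks; accepts scalars or ndarrays.

    The single degenerate corner h = 1, u = 1 (every zygote carries the
    lethal genotype, mean fitness zero) is resolved by taking the
    successor frequency to be 0, i.e. F(x) = -x.
    """
    num = (1.0 - h) * u - (h + (2.0 - 3.0 * h) * u) * x \
        - (1.0 - 2.0 * h) * (1.0 - u) * x * x
    den = 1.0 + (1.0 - 2.0 * h) * u + (1.0 - 2.0 * h) * (1.0 - u) * x
    if isinstance(den, np.ndarray):
        zero = den == 0.0
        if zero.any():
            den = np.where(zero, 1.0, den)
            return np.where(zero, -x, num / den)
        return num / den
    if den == 0.0:
        return -x
    return num / den


def deterministic_force(x: float, params: PopulationParams) -> float:
    """Expected per-generation change F(x) of the lethal-allele frequency.

    Positive F pushes the frequency up (mutation pressure, heterozygote
    advantage); negative F reflects purging of the lethal homozygote.
    The successor x + F(x) is guaranteed to stay in [0, 1/2].
    """
    x = check_frequency(x)
    f = _force_raw(x, params.h, params.u)
    succ = x + f
    if not (-_BOUND_EPS <= succ <= 0.5 + _BOUND_EPS):
        raise ArithmeticError(
            f"internal inconsistency: x + F(x) = {succ!r} escapes [0, 1/2] "
            f"by more than {_BOUND_EPS} at x={x}, h={params.h}, u={params.u}"
        )
    return f


def step_infinite(x: float, params: PopulationParams) -> float:
    """One deterministic generation: x' = x + F(x), clamped into [0, 1/2]
    only to absorb roundoff at the boundaries."""
    succ = x + deterministic_force(x, params)
    return min(max(succ, 0.0), 0.5)


def trajectory_infinite(
    x0: float,
    schedule: DominanceSchedule,
    u: float,
    t_max: int,
) -> list[tuple[int, float]]:
    """Iterate the deterministic recursion under a dominance schedule.

    Returns ``[(t, x_t)]`` for t = origin .. t_max, where the transition
    from t to t + 1 uses the schedule's h(t).
    """
    if t_max < schedule.origin:
        raise ValueError("t_max precedes the schedule origin")
    x = check_frequency(x0, name="x0")
    out = [(schedule.origin, x)]
    for t in range(schedule.origin, t_max):
        params = PopulationParams(u=u, h=schedule.h_at(t))
        x = step_infinite(x, params)
        out.append((t + 1, x))
    return out


def equilibrium_exact(params: PopulationParams) -> EquilibriumResult:
    """Exact equilibrium frequency x_hat of the deterministic recursion.

    Solves the quadratic numerator of F(x) = 0 with the numerically stable
    root formula: for b >= 0 the rationalized form 2c / (b + sqrt(disc)),
    for b < 0 (overdominance) the form (-b + sqrt(disc)) / (2a), where
    a = (1 - 2h)(1 - u), b = h + (2 - 3h) u, c = (1 - h) u.  Both branches
    avoid subtracting nearly equal quantities, keeping relative error at
    roundoff level down to u = 1e-12 and beyond.
    """
    h, u = params.h, params.u
    a = (1.0 - 2.0 * h) * (1.0 - u)
    b = h + (2.0 - 3.0 * h) * u
    c = (1.0 - h) * u
    # disc = b*b + 4*a*c, algebraically h^2 (1+u)^2 + 4 (1-2h) u >= 0
    disc = h * h * (1.0 + u) * (1.0 + u) + 4.0 * (1.0 - 2.0 * h) * u
    root = math.sqrt(max(disc, 0.0))
    if a == 0.0:
        # h = 1/2 or u = 1 degenerate to a linear equation b x = c.
        x_hat = 0.0 if c == 0.0 else c / b
    elif b >= 0.0:
        denom = b + root
        x_hat = 0.0 if denom == 0.0 else 2.0 * c / denom
    else:
        x_hat = (-b + root) / (2.0 * a)
    x_hat = min(max(x_hat, 0.0), 0.5)
    return EquilibriumResult(x_hat=x_hat, method="exact")


def equilibrium_approx(
    params: PopulationParams, regime: str
) -> EquilibriumResult:
    """Closed-form equilibrium approximations for limiting regimes.

    Regimes
    -------
    ``small-positive-h``
        u << h << 1:  x_hat ~= (1 - h) u / h.
    ``recessive``
        h = 0:  x_hat = sqrt(u) / (1 + sqrt(u)), exact at h = 0.
    ``overdominant``
        u << |h| << 1, h < 0:  x_hat ~= |h| / (1 + 2|h|).
    ``zero-mutation-limit``
        u -> 0:  0 for h >= 0, |h| / (1 + 2|h|) for h < 0.

    A regime whose inequality is violated produces a warning, not an
    error: the formula is still evaluated as requested.
    """
    import warnings

    h, u = params.h, params.u
    if regime == "small-positive-h":
        if h <= 0.0:
            raise ValueError("small-positive-h regime requires h > 0")
        if not (u < h * 1e-2 and h < 0.1):
            warnings.warn(
                f"small-positive-h approximation assumes u << h << 1 "
                f"(got u={u}, h={h})",
                stacklevel=2,
            )
        x_hat = (1.0 - h) * u / h
    elif regime == "recessive":
        if h != 0.0:
            warnings.warn(
                f"recessive approximation assumes h = 0 (got h={h})",
                stacklevel=2,
            )
        r = math.sqrt(u)
        x_hat = r / (1.0 + r)
    elif regime == "overdominant":
        if h >= 0.0:
            raise ValueError("overdominant regime requires h < 0")
        if not (u < abs(h) * 1e-2 and abs(h) < 0.1):
            warnings.warn(
                f"overdominant approximation assumes u << |h| << 1 "
                f"(got u={u}, h={h})",
                stacklevel=2,
            )
        x_hat = abs(h) / (1.0 + 2.0 * abs(h))
    elif regime == "zero-mutation-limit":
        x_hat = 0.0 if h >= 0.0 else abs(h) / (1.0 + 2.0 * abs(h))
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return EquilibriumResult(x_hat=min(max(x_hat, 0.0), 0.5), method=regime)


def _crossing_halftime(
    trajectory: Iterator[float],
    x_start: float,
    x_final: float,
    *,
    offset: int = 0,
    rule: str = "round",
    t_cap: int = 10_000_000,
) -> HalfTimeResult:
    """Locate the midpoint crossing of a monotone (mean-)frequency path.

    ``trajectory`` yields the value after 1, 2, ... transitions from
    ``x_start``.  With ``rule="round"`` (deterministic recursions, where
    the discrete path shadows the continuous-time solution) the reported
    ``t_half`` is the linearly interpolated crossing time rounded to the
    nearest integer; with ``rule="cross"`` it is the first integer
    generation at which the path has reached or passed the midpoint.
    ``offset`` shifts the generation labels (finite-population bookkeeping
    counts the generation in which the environment changes; see the
    methods note).
    """
    if rule not in ("round", "cross"):
        raise ValueError(f"unknown crossing rule {rule!r}")
    if x_start == x_final:
        raise ValueError(
            "x_start equals x_final: no half-time is defined for a "
            "degenerate jump"
        )
    x_mid = 0.5 * (x_start + x_final)
    rising = x_final > x_start
    prev = x_start
    for t, x in enumerate(trajectory, start=1):
        crossed = x >= x_mid if rising else x <= x_mid
        if crossed:
            t_interp = t - 1 + (x_mid - prev) / (x - prev)
            if rule == "round":
                t_half = int(round(t_interp)) + offset
            else:
                t_half = t + offset
            return HalfTimeResult(
                t_half=t_half,
                x_start=x_start,
                x_final=x_final,
                x_mid=x_mid,
                t_cross=t + offset,
                t_interp=t_interp + offset,
            )
        prev = x
        if t >= t_cap:
            raise RuntimeError(
                f"midpoint not crossed within {t_cap} generations"
            )
    raise RuntimeError("trajectory exhausted before the midpoint crossing")


def half_time_exact_infinite(
    params_pre: PopulationParams, params_post: PopulationParams
) -> HalfTimeResult:
    """Half time to equilibrium after a jump in the dominance coefficient.

    The population sits at the equilibrium of ``params_pre``; at t = 0 the
    dominance coefficient changes to that of ``params_post`` and the
    deterministic recursion is iterated until the frequency has covered
    half the distance to the new equilibrium.  The reported T_1/2 is the
    interpolated crossing time rounded to the nearest generation.
    """
    if params_pre.u != params_post.u:
        raise ValueError("pre- and post-jump parameters must share u")
    x_start = equilibrium_exact(params_pre).x_hat
    x_final = equilibrium_exact(params_post).x_hat

    def walk() -> Iterator[float]:
        x = x_start
        while True:
            x = step_infinite(x, params_post)
            yield x

    return _crossing_halftime(walk(), x_start, x_final)


def half_time_approx_rise(h_star: float, u: float) -> float:
    """Closed-form T_1/2 for the onset of overdominance (h: 0 -> h* < 0).

    T_1/2 ~= ln( [|h*| / (1 + 2|h*|)] / sqrt(u) ) / ln(1 + |h*|),
    valid for u << |h*| << 1: the frequency grows roughly geometrically
    with ratio 1 + |h*| from its mutation-selection value ~ sqrt(u)
    toward the overdominant equilibrium |h*| / (1 + 2|h*|).
    """
    if h_star >= 0.0:
        raise ValueError("the rise approximation requires h_star < 0")
    if not (0.0 < u < abs(h_star)):
        raise ValueError("the rise approximation requires 0 < u < |h_star|")
    ah = abs(h_star)
    return math.log(ah / (1.0 + 2.0 * ah) / math.sqrt(u)) / math.log(1.0 + ah)


def half_time_approx_fall(h_star: float, u: float) -> float:
    """Closed-form T_1/2 for the loss of overdominance (h: h* < 0 -> 0).

    T_1/2 ~= ln(1 + 2 sqrt(u)/|h*| - 2 u/h***2) / (2 sqrt(u)),
    valid for u << h***2: relaxation from the overdominant equilibrium
    back to the recessive mutation-selection balance ~ sqrt(u).
    """
    if h_star >= 0.0:
        raise ValueError("the fall approximation requires h_star < 0")
    if not (0.0 < u < h_star * h_star):
        raise ValueError("the fall approximation requires 0 < u < h_star**2")
    ah = abs(h_star)
    r = math.sqrt(u)
    return math.log(1.0 + 2.0 * r / ah - 2.0 * u / (ah * ah)) / (2.0 * r)
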