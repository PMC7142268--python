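"""Parameter containers and validation for the lethal-allele model.

The model describes a biallelic locus where the disease-causing allele *a*
is lethal when homozygous.  Genotype fitnesses are

    w_aa = 0,    w_aA = 1 - h,    w_AA = 1,

with dominance coefficient h <= 1 (h = 0: fully recessive; 0 < h < 1:
partially recessive; h < 0: overdominant, heterozygote advantage).  One-way
mutation A -> a occurs with probability u per allele copy per generation.

Because the lethal allele only survives in heterozygote adults, its adult
frequency can never exceed one half; every frequency handled by this
package lives on [0, 1/2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "INFINITE",
    "PopulationParams",
    "DominanceSchedule",
    "EquilibriumResult",
    "HalfTimeResult",
    "check_frequency",
]

#: Sentinel for an effectively infinite (deterministic) population.
INFINITE = math.inf

#: Upper bound on the adult frequency of the lethal allele.
MAX_FREQ = 0.5


def check_frequency(x: float, *, name: str = "x") -> float:
    """Validate an adult allele frequency, which must lie in [0, 1/2].

    The bound is structural: a lethal homozygote means every surviving copy
    of the allele sits in a heterozygote, so at most half of all adult
    allele copies can be the lethal one.
    """
    x = float(x)
    if not (0.0 <= x <= MAX_FREQ):
        raise ValueError(
            f"{name}={x!r} outside [0, 0.5]; adult frequency of a lethal "
            "allele cannot exceed one half"
        )
    return x


def _as_size(N) -> float | int:
    """Normalize a population size: positive int, or INFINITE."""
    if N is None:
        return INFINITE
    if isinstance(N, str):
        if N.lower() in {"inf", "infinite", "infinity"}:
            return INFINITE
        try:
            N = int(N)
        except ValueError as exc:
            raise ValueError(f"unrecognized population size {N!r}") from exc
    if isinstance(N, float):
        if math.isinf(N):
            return INFINITE
        if N != int(N):
            raise ValueError(f"population size must be an integer, got {N!r}")
        N = int(N)
    if isinstance(N, bool) or not isinstance(N, int):
        raise TypeError(f"population size must be an int or 'inf', got {N!r}")
    if N < 1:
        raise ValueError(f"population size must be >= 1, got {N}")
    return N


@dataclass(frozen=True)
class PopulationParams:
    """Parameters (u, h, N) of the lethal-allele model.

    Parameters
    ----------
    u
        Per-allele, per-generation probability of the one-way mutation
        A -> a.  Must lie in [0, 1].
    h
        Dominance coefficient; heterozygote fitness is 1 - h, so any
        h <= 1 is admissible (h < 0 gives heterozygote advantage).
    N
        Adult census size (positive integer), or :data:`INFINITE` /
        ``"inf"`` / ``None`` for the deterministic infinite-population
        limit.
    s
        Selection coefficient against the aa homozygote.  The model is
        derived specifically for a lethal genotype, so s is fixed at 1;
        any other value is rejected.
    """

    u: float
    h: float
    N: float | int = INFINITE
    s: float = field(default=1.0)

    def __post_init__(self):
        u = float(self.u)
        h = float(self.h)
        if not (0.0 <= u <= 1.0):
            raise ValueError(f"mutation rate u={u!r} outside [0, 1]")
        if not (h <= 1.0):
            raise ValueError(
                f"dominance coefficient h={h!r} > 1 would make the "
                "heterozygote fitness 1 - h negative"
            )
        if math.isnan(h):
            raise ValueError("dominance coefficient h must not be NaN")
        if float(self.s) != 1.0:
            raise ValueError(
                "the model describes a lethal homozygote; s is fixed at 1"
            )
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "N", _as_size(self.N))
        object.__setattr__(self, "s", 1.0)

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.N)

    def with_h(self, h: float) -> "PopulationParams":
        """Copy of these parameters with a different dominance coefficient."""
        return replace(self, h=h)

    def fitnesses(self) -> tuple[float, float, float]:
        """Relative genotype fitnesses (w_aa, w_aA, w_AA) = (0, 1-h, 1)."""
        return (0.0, 1.0 - self.h, 1.0)


@dataclass(frozen=True)
class DominanceSchedule:
    """Piecewise-constant dominance coefficient h(t).

    ``epochs`` is an ordered sequence of ``(t_start, h)`` pairs; each epoch
    applies from its ``t_start`` (a generation index) up to, but not
    including, the next epoch's start.  The value h(t) governs the
    transition from generation t to generation t + 1, so a jump "at t = 0"
    means the very first transition already uses the new coefficient.
    """

    epochs: tuple[tuple[int, float], ...]

    def __post_init__(self):
        eps = tuple((int(t), float(h)) for t, h in self.epochs)
        if not eps:
            raise ValueError("schedule needs at least one epoch")
        starts = [t for t, _ in eps]
        if starts != sorted(set(starts)):
            raise ValueError("epoch start times must be strictly increasing")
        for _, h in eps:
            if h > 1.0:
                raise ValueError(f"epoch dominance coefficient h={h} > 1")
        object.__setattr__(self, "epochs", eps)

    @classmethod
    def constant(cls, h: float) -> "DominanceSchedule":
        return cls(epochs=((0, h),))

    @classmethod
    def jump(cls, h_star: float, t_f: int | None = None,
             h_before: float = 0.0) -> "DominanceSchedule":
        """Schedule for the environmental-change scenario: h = ``h_star``
        from t = 0, optionally reverting to ``h_before`` at t = ``t_f``."""
        eps = [(0, float(h_star))]
        if t_f is not None:
            eps.append((int(t_f), float(h_before)))
        return cls(epochs=tuple(eps))

    @property
    def origin(self) -> int:
        return self.epochs[0][0]

    def h_at(self, t: int) -> float:
        """Dominance coefficient governing the transition t -> t + 1."""
        if t < self.origin:
            raise ValueError(
                f"t={t} precedes the schedule origin {self.origin}"
            )
        h = self.epochs[0][1]
        for t_start, h_epoch in self.epochs:
            if t >= t_start:
                h = h_epoch
            else:
                break
        return h

    def values(self, t_max: int) -> list[float]:
        """h(t) for t = origin .. t_max - 1 (one value per transition)."""
        return [self.h_at(t) for t in range(self.origin, t_max)]


@dataclass(frozen=True)
class EquilibriumResult:
    """An equilibrium frequency and the method that produced it."""

    x_hat: float
    method: str

    _METHODS = frozenset(
        {"exact", "small-positive-h", "recessive", "overdominant",
         "zero-mutation-limit"}
    )

    def __post_init__(self):
        if self.method not in self._METHODS:
            raise ValueError(f"unknown equilibrium method {self.method!r}")
        object.__setattr__(
            self, "x_hat", check_frequency(self.x_hat, name="x_hat")
        )

    def __float__(self) -> float:
        return self.x_hat


@dataclass(frozen=True)
class HalfTimeResult:
    """Half time to equilibrium.

    ``t_half`` is the reported integer number of generations for the
    (mean) frequency to cover half the distance from ``x_start`` to
    ``x_final``; ``t_cross`` is the first integer generation at which the
    discrete trajectory has reached or passed the midpoint, and
    ``t_interp`` the linearly interpolated continuous crossing time.
    """

    t_half: int
    x_start: float
    x_final: float
    x_mid: float
    t_cross: int
    t_interp: float

    def __post_init__(self):
        check_frequency(self.x_start, name="x_start")
        check_frequency(self.x_final, name="x_final")
        check_frequency(self.x_mid, name="x_mid")
        expected_mid = 0.5 * (self.x_start + self.x_final)
        if self.x_mid != expected_mid:
            raise ValueError("x_mid must equal (x_start + x_final)/2 exactly")
        if self.t_half < 0:
            raise ValueError("t_half must be non-negative")
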