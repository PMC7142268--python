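"""Orchestrated experiments: dominance-jump transients and summary tables.

The central scenario is an environmental change that discontinuously
alters the heterozygote's fitness: a lethal allele sits at its fully
recessive (h = 0) mutation-selection balance, at t = 0 the heterozygote
becomes slightly advantageous (h = h* < 0), and after t_f generations the
advantage is lost again.  Even a ~1% fitness edge drives the allele
frequency up by orders of magnitude, and the subsequent decay back to
mutation-selection balance takes hundreds of generations — a candidate
explanation for lethal disease alleles observed far above their
mutation-limited expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import chain, deterministic
from .params import DominanceSchedule, PopulationParams

__all__ = ["ScenarioResult", "run_jump_scenario", "stationary_table",
           "half_time_table"]


@dataclass
class ScenarioResult:
    """Per-generation summary of a scenario run plus provenance."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        m = self.frame["mean_x"].to_numpy()
        if m.size and (m.min() < -1e-12 or m.max() > 0.5 + 1e-12):
            raise ValueError("mean frequencies escape [0, 1/2]")


def run_jump_scenario(
    u: float,
    N,
    h_star: float,
    t_f: int | None = 2000,
    t_max: int = 4000,
    h_baseline: float = 0.0,
) -> ScenarioResult:
    """Run the dominance-jump scenario for an infinite or finite population.

    The population starts at the ``h_baseline`` equilibrium (infinite N)
    or stationary distribution (finite N); the dominance coefficient is
    ``h_star`` for transitions t = 0 .. t_f - 1 and reverts to
    ``h_baseline`` afterwards (``t_f=None`` never reverts).  Returns
    per-generation mean frequency, its log10, and (finite N) variance.
    """
    if t_f is not None and not (0 < t_f <= t_max):
        raise ValueError("need 0 < t_f <= t_max")
    schedule = DominanceSchedule.jump(h_star, t_f, h_before=h_baseline)
    params_pre = PopulationParams(u=u, h=h_baseline, N=N)
    meta = {
        "u": u, "N": params_pre.N, "h_star": h_star, "t_f": t_f,
        "t_max": t_max, "h_baseline": h_baseline,
    }
    if params_pre.is_infinite:
        x0 = deterministic.equilibrium_exact(params_pre).x_hat
        traj = deterministic.trajectory_infinite(x0, schedule, u, t_max)
        frame = pd.DataFrame(traj, columns=["t", "mean_x"])
        meta["solver"] = "deterministic-recursion"
    else:
        N_int = int(params_pre.N)
        pi0 = chain.stationary_distribution(params_pre)
        rec = chain.propagate_distribution(pi0, schedule, u, N_int, t_max)
        frame = pd.DataFrame(
            {"t": rec["t"], "mean_x": rec["mean_x"], "var_x": rec["var_x"]}
        )
        meta["solver"] = "kernel-propagation"
    with np.errstate(divide="ignore"):
        frame["log10_mean_x"] = np.log10(frame["mean_x"].to_numpy())
    return ScenarioResult(frame=frame, meta=meta)


def stationary_table(
    u_list: Sequence[float],
    N_list: Sequence,
    h_list: Sequence[float],
) -> pd.DataFrame:
    """Stationary/equilibrium mean frequencies over a parameter grid.

    One row per (u, N, h): the stationary mean of the finite-N chain, or
    the deterministic equilibrium for infinite N, reported as
    log10(E_stat[X]) and the ratio E_stat[X]/u, together with N*h (the
    composite that controls how strongly overdominance beats drift).
    """
    rows = []
    for u in u_list:
        for N in N_list:
            for h in h_list:
                params = PopulationParams(u=u, h=h, N=N)
                if params.is_infinite:
                    mean = deterministic.equilibrium_exact(params).x_hat
                    Nh = math.nan
                else:
                    mean = chain.stationary_mean(params)
                    Nh = params.N * h
                rows.append({
                    "u": u,
                    "N": params.N,
                    "h": h,
                    "N_x_h": Nh,
                    "log10_mean": math.log10(mean) if mean > 0 else -math.inf,
                    "mean_over_u": mean / u if u > 0 else math.nan,
                })
    return pd.DataFrame(rows)


def half_time_table(
    u_list: Sequence[float],
    N_list: Sequence,
    jumps: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Half times to equilibrium/stationarity over a parameter grid.

    ``jumps`` lists (h_pre, h_post) pairs; infinite-N rows use the
    deterministic recursion, finite rows the propagated chain mean.
    """
    rows = []
    for u in u_list:
        for N in N_list:
            for h_pre, h_post in jumps:
                pre = PopulationParams(u=u, h=h_pre, N=N)
                post = PopulationParams(u=u, h=h_post, N=N)
                if pre.is_infinite:
                    res = deterministic.half_time_exact_infinite(pre, post)
                else:
                    res = chain.half_time_finite(pre, post)
                rows.append({
                    "u": u, "N": pre.N, "h_pre": h_pre, "h_post": h_post,
                    "t_half": res.t_half,
                    "x_start": res.x_start, "x_final": res.x_final,
                })
    return pd.DataFrame(rows)
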