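"""Configuration parsing, TSV/CSV/MTX writers, and deterministic fixtures.

Outputs are plain text: tab-separated tables with ``#``-prefixed metadata
lines (tool version, configuration, seed) so any run can be regenerated
from its own header.  Floats are written with ``repr`` round-trip
precision.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import DominanceSchedule, PopulationParams

__all__ = ["RunConfig", "parse_config", "serialize_config", "write_table",
           "read_table", "write_matrix_market", "make_fixtures"]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "u", "h", "schedule", "N", "x0", "t_max", "seed", "out",
    "solver_cap", "format",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    ``h`` and ``schedule`` are mutually exclusive; ``x0`` is either a
    frequency or the string ``"equilibrium"`` (start from the equilibrium
    or stationary state of the first epoch's parameters).
    """

    u: float
    schedule: DominanceSchedule
    N: float | int
    t_max: int
    x0: float | str = "equilibrium"
    seed: int | None = None
    out: str | None = None
    solver_cap: int = 10_000
    format: str = "tsv"

    def __post_init__(self):
        validated = PopulationParams(
            u=self.u, h=self.schedule.epochs[0][1], N=self.N
        )
        object.__setattr__(self, "N", validated.N)
        object.__setattr__(self, "u", validated.u)
        if self.t_max < 0:
            raise ValueError("t_max must be non-negative")
        if isinstance(self.x0, str) and self.x0 != "equilibrium":
            raise ValueError(f"x0 must be a frequency or 'equilibrium', "
                             f"got {self.x0!r}")
        if self.format not in ("tsv", "csv"):
            raise ValueError(f"unknown output format {self.format!r}")


def parse_config(text: str) -> RunConfig:
    """Parse a YAML/JSON config document into a validated RunConfig.

    Unknown keys are rejected with a listing; invalid values raise with a
    field-level message.
    """
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError("config must be a mapping of keys to values")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; "
            f"known keys: {sorted(_KNOWN_KEYS)}"
        )
    if "h" in data and "schedule" in data:
        raise ValueError("give either 'h' or 'schedule', not both")
    if "h" in data:
        schedule = DominanceSchedule.constant(float(data["h"]))
    elif "schedule" in data:
        eps = data["schedule"]
        try:
            schedule = DominanceSchedule(
                epochs=tuple((int(e["t_start"]), float(e["h"])) for e in eps)
            )
        except (TypeError, KeyError) as exc:
            raise ValueError(
                "schedule must be a list of {t_start, h} mappings"
            ) from exc
    else:
        raise ValueError("config needs 'h' or 'schedule'")
    try:
        u = float(data["u"])
        t_max = int(data["t_max"])
    except KeyError as exc:
        raise ValueError(f"config missing required key {exc.args[0]!r}") from exc
    kwargs = {}
    for key in ("x0", "seed", "out", "solver_cap", "format"):
        if key in data:
            kwargs[key] = data[key]
    if "x0" in kwargs and not isinstance(kwargs["x0"], str):
        kwargs["x0"] = float(kwargs["x0"])
    return RunConfig(u=u, schedule=schedule, N=data.get("N", "inf"),
                     t_max=t_max, **kwargs)


def serialize_config(config: RunConfig) -> str:
    """Serialize a RunConfig to YAML; parse(serialize(c)) == c."""
    data = {
        "u": config.u,
        "schedule": [{"t_start": t, "h": h} for t, h in config.schedule.epochs],
        "N": "inf" if np.isinf(config.N) else int(config.N),
        "t_max": config.t_max,
        "x0": config.x0,
        "solver_cap": config.solver_cap,
        "format": config.format,
    }
    if config.seed is not None:
        data["seed"] = config.seed
    if config.out is not None:
        data["out"] = config.out
    return yaml.safe_dump(data, sort_keys=True)


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_table(
    rows,
    path,
    *,
    columns: Sequence[str] | None = None,
    metadata: Mapping | None = None,
    fmt: str = "tsv",
) -> None:
    """Write rows (DataFrame, dict-of-arrays, or list of dicts) as TSV/CSV.

    The file starts with ``#``-prefixed metadata lines (always including
    the tool version), then a header line, then the data with
    full-precision floats and POSIX newlines.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown table format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        frame = pd.DataFrame(rows)
    if columns is not None:
        frame = frame.loc[:, list(columns)]
    meta = {"lethalwf_version": __version__}
    if metadata:
        meta.update(metadata)
    path = Path(path)
    try:
        with open(path, "w", newline="\n") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
            fh.write(sep.join(map(str, frame.columns)) + "\n")
            for row in frame.itertuples(index=False):
                fh.write(sep.join(_fmt(v) for v in row) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing table to {path}: {exc}") from exc


def read_table(path, fmt: str = "tsv") -> tuple[pd.DataFrame, dict]:
    """Read a table written by :func:`write_table`; returns (frame, meta)."""
    sep = "\t" if fmt == "tsv" else ","
    meta = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                meta[key.strip()] = json.loads(value.strip())
            else:
                lines.append(line)
    frame = pd.read_csv(_io.StringIO("".join(lines)), sep=sep)
    return frame, meta


def write_matrix_market(W: np.ndarray, path) -> None:
    """Export a transition kernel in Matrix Market coordinate format."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(str(path), sparse.coo_matrix(W))


def make_fixtures(seed: int = 0) -> dict:
    """Deterministic bundle of small reference inputs for testing.

    Contains brute-force stationary vectors for tiny chains (N = 1, 2, 3),
    the closed-form recessive no-mutation trajectory x_t = x0/(1 + t x0),
    and the (u, N, h) grids of the stationary and half-time summary
    tables.  The same seed yields a byte-identical bundle.
    """
    rng = np.random.default_rng(seed)
    tiny = {}
    for N in (1, 2, 3):
        u = float(np.round(rng.uniform(0.01, 0.2), 6))
        params = PopulationParams(u=u, h=0.0, N=N)
        from .chain import build_transition_matrix

        W = build_transition_matrix(params)
        # brute-force stationary vector: eigenvector of eigenvalue 1
        vals, vecs = np.linalg.eig(W)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        tiny[N] = {"u": u, "W": W, "pi": pi}
    x0 = 0.5
    closed_form = [(t, x0 / (1.0 + t * x0)) for t in range(51)]
    return {
        "seed": seed,
        "tiny_chains": tiny,
        "recessive_no_mutation_trajectory": closed_form,
        "stationary_grid": {
            "u": [1e-8, 1e-5],
            "N": [500, 1000, 2000, "inf"],
            "h": [-0.01, -0.001, 0.0, 0.001, 0.01],
        },
        "half_time_grid": {
            "u": [1e-8, 1e-5],
            "N": [500, 1000, 2000, "inf"],
            "jumps": [(0.0, -0.01), (-0.01, 0.0)],
        },
    }
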