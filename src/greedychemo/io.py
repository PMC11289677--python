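"""Configuration files, trajectory CSV round-tripping and run manifests.

Config format: a single TOML document with ``[model]``, ``[simulation]``
and ``[output]`` tables.  Unknown keys are rejected so that typos fail
loudly.  Trajectory CSVs carry floats at 17 significant digits, which
round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .model import ModelParams
from .particle_sim import SimConfig
from .run_sim import RunEvent, Trajectory

__all__ = [
    "ConfigError",
    "load_config",
    "write_trajectories",
    "read_trajectories",
    "RunManifest",
    "write_manifest",
]

_MODEL_KEYS = {"a", "v", "alpha", "D"}
_SIM_KEYS = {"dt", "rc", "burn_in_policy", "burn_in_tol", "max_time",
             "particle_cap", "r0", "n_trials", "seed"}
_OUTPUT_KEYS = {"out_dir", "prefix"}

_CSV_COLUMNS = ["trial", "event_index", "t_start", "rs_start", "phi", "dt",
                "drs", "outcome"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def load_config(path: str | Path) -> tuple[ModelParams, SimConfig, dict]:
    """Parse a TOML config into (ModelParams, SimConfig, extras).

    ``extras`` carries the simulation keys that are not numerical
    controls of the particle stepper (r0, n_trials, seed) plus the
    ``[output]`` table.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    unknown_tables = set(doc) - {"model", "simulation", "output"}
    if unknown_tables:
        raise ConfigError(f"unknown config tables: {sorted(unknown_tables)}")
    model = doc.get("model", {})
    sim = doc.get("simulation", {})
    output = doc.get("output", {})
    for name, table, allowed in (("model", model, _MODEL_KEYS),
                                 ("simulation", sim, _SIM_KEYS),
                                 ("output", output, _OUTPUT_KEYS)):
        bad = set(table) - allowed
        if bad:
            raise ConfigError(f"unknown keys in [{name}]: {sorted(bad)}")
    missing = _MODEL_KEYS - set(model)
    if missing:
        raise ConfigError(f"missing keys in [model]: {sorted(missing)}")
    try:
        params = ModelParams(a=float(model["a"]), v=float(model["v"]),
                             alpha=float(model["alpha"]), D=float(model["D"]))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    sim_extras = {k: sim[k] for k in ("r0", "n_trials", "seed") if k in sim}
    cfg_kwargs = {k: sim[k] for k in sim if k not in sim_extras}
    if "dt" not in cfg_kwargs:
        cfg_kwargs["dt"] = params.a**2 / (200.0 * params.D)
    if "rc" not in cfg_kwargs:
        r0 = float(sim_extras.get("r0", 2.0 * params.a))
        cfg_kwargs["rc"] = 10.0 * max(params.a, r0, params.rh)
    cfg = SimConfig(**cfg_kwargs)
    if cfg.dt <= 0 or cfg.rc <= 0:
        raise ConfigError("dt and rc must be positive")
    return params, cfg, {**sim_extras, "output": output}


def write_trajectories(trajectories: Sequence[Trajectory], path: str | Path) -> None:
    """Write an ensemble to CSV (one row per run event, 17 sig digits)."""
    rows = []
    for i, tr in enumerate(trajectories):
        for j, ev in enumerate(tr.events):
            rows.append((i, j, ev.t_start, ev.rs_start, ev.phi, ev.dt, ev.drs,
                         ev.terminated))
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectories(path: str | Path, params: ModelParams | None = None,
                      r0: float | None = None) -> list[Trajectory]:
    """Inverse of :func:`write_trajectories`.

    The CSV does not embed physical parameters; pass ``params`` to
    reattach them (needed for exact within-run evaluation).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed trajectory CSV {path}: {exc}") from exc
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV {path} lacks columns {sorted(missing)}")
    out: list[Trajectory] = []
    for trial, grp in df.groupby("trial", sort=True):
        grp = grp.sort_values("event_index")
        first = grp.iloc[0]
        start = float(first["rs_start"]) if r0 is None else r0
        traj = Trajectory(seed=int(trial), params=params, r0=start)
        for _, row in grp.iterrows():
            traj.events.append(RunEvent(
                t_start=float(row["t_start"]), rs_start=float(row["rs_start"]),
                phi=float(row["phi"]), dt=float(row["dt"]), drs=float(row["drs"]),
                terminated=str(row["outcome"]),
            ))
        last = traj.events[-1]
        traj.outcome = last.terminated if last.terminated != "none" else "max_time"
        traj.total_time = last.t_start + last.dt
        out.append(traj)
    return out


@dataclass
class RunManifest:
    """Everything needed to regenerate an output file."""

    params: dict
    sim_config: dict
    seed: int
    code_version: str
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def make_manifest(params: ModelParams, cfg: SimConfig | None, seed: int,
                  outputs: Sequence[str | Path] = ()) -> RunManifest:
    from . import __version__

    sim_config = asdict(cfg) if cfg is not None else {}
    sim_config = {k: ("inf" if v == float("inf") else v) for k, v in sim_config.items()}
    return RunManifest(
        params=asdict(params),
        sim_config=sim_config,
        seed=seed,
        code_version=__version__,
        outputs={str(p): sha256_of(p) for p in outputs},
    )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, default=float)
        fh.write("\n")
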