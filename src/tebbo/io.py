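"""Configuration files, tree archives and run directories.

Configs are YAML with a flat, schema-validated layout (unknown keys are a
hard error — no silent ignore). Trees are archived as JSON keyed by branch
id; round-tripping is exact on ids and flags and reproduces coordinates,
widths and volumes to full double precision. Every run directory receives a
copy of the resolved configuration, the package version and all seeds, so a
run is reproducible from its directory alone.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .params import GrowthParameters
from .spatial import (
    Branch,
    OrganoidTree,
    PerturbationSchedule,
    SimulationConfig,
    SimulationRun,
)
from .synth import ObservationNoiseModel

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "save_tree",
    "load_tree",
    "save_run",
]

logger = logging.getLogger("tebbo")


class ConfigError(ValueError):
    """Configuration file could not be parsed or validated."""


class _ParamsSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    v0: float = 80.0
    kb: float = 0.55
    kd0: float = 1.5
    w0: float = 60.0
    v_cell: float = 1000.0
    l_init: float = 5.0
    w_min: float = 0.0
    dim: int = 3


class _SimSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dtheta: float = 0.5
    theta_b: float = 0.6
    dt: float = 0.01
    duration: float = 9.0
    seed: int = 0
    couple_branching_to_division: bool = True
    self_avoidance_distance: float | None = None
    dilution_locality: float = 0.3
    record_nodes: bool = True
    snapshot_times: list[float] | None = None
    tip_track_interval: float | None = None


class _NoiseSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width_cv: float = 0.1
    growth_rate_cv: float = 0.1
    count_cv: float = 0.1
    track_jitter_sd: float = 2.0
    seed: int | None = None


class _EventSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time: float
    overrides: dict[str, float]


class _RunSchema(BaseModel):
    model_config = ConfigDict(extra="forbid")
    params: _ParamsSchema = Field(default_factory=_ParamsSchema)
    sim: _SimSchema = Field(default_factory=_SimSchema)
    noise: _NoiseSchema = Field(default_factory=_NoiseSchema)
    schedule: list[_EventSchema] = Field(default_factory=list)
    output_dir: str = "tebbo_out"
    log_level: str = "INFO"


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (all defaults applied)."""

    params: GrowthParameters
    sim: SimulationConfig
    noise: ObservationNoiseModel
    schedule: PerturbationSchedule
    output_dir: Path
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "sim": {
                "dtheta": self.sim.dtheta,
                "theta_b": self.sim.theta_b,
                "dt": self.sim.dt,
                "duration": self.sim.duration,
                "seed": self.sim.seed,
                "couple_branching_to_division": self.sim.couple_branching_to_division,
                "self_avoidance_distance": self.sim.self_avoidance_distance,
                "dilution_locality": self.sim.dilution_locality,
                "record_nodes": self.sim.record_nodes,
                "snapshot_times": (
                    list(self.sim.snapshot_times) if self.sim.snapshot_times else None
                ),
                "tip_track_interval": self.sim.tip_track_interval,
            },
            "noise": dataclasses.asdict(self.noise),
            "schedule": [{"time": t, "overrides": ov} for t, ov in self.schedule.events],
            "output_dir": str(self.output_dir),
            "log_level": self.log_level,
        }


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Missing optional fields fall back to defaults (logged); unknown or
    misspelled keys raise :class:`ConfigError` naming the offending field.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        schema = _RunSchema.model_validate(raw)
    except ValidationError as e:
        locs = ", ".join(".".join(str(p) for p in err["loc"]) or "<root>" for err in e.errors())
        raise ConfigError(f"{path}: invalid configuration at: {locs}\n{e}") from e

    for section in ("params", "sim", "noise"):
        if section not in raw:
            logger.info("config %s: section %r missing, defaults applied", path, section)

    params = GrowthParameters(**schema.params.model_dump())
    schedule = PerturbationSchedule(
        events=tuple((e.time, e.overrides) for e in schema.schedule)
    )
    sim_kwargs = schema.sim.model_dump()
    if sim_kwargs["snapshot_times"] is not None:
        sim_kwargs["snapshot_times"] = tuple(sim_kwargs["snapshot_times"])
    sim = SimulationConfig(
        params=params,
        schedule=schedule if schedule.events else None,
        **sim_kwargs,
    )
    noise = ObservationNoiseModel(**schema.noise.model_dump())
    return RunConfig(
        params=params,
        sim=sim,
        noise=noise,
        schedule=schedule,
        output_dir=Path(schema.output_dir),
        log_level=schema.log_level,
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# tree archives
# ---------------------------------------------------------------------------


def save_tree(tree: OrganoidTree, path: str | Path) -> None:
    """Write one tree as a JSON archive (branches keyed by id)."""
    doc = {
        "time": tree.time,
        "rng_seed": tree.rng_seed,
        "branches": {
            str(b.id): {
                "parent_id": b.parent_id,
                "nodes": b.nodes.tolist(),
                "length": b.length,
                "width": b.width,
                "volume": b.volume,
                "birth_time": b.birth_time,
                "terminal": b.terminal,
                "broken": b.broken,
            }
            for b in tree.branches.values()
        },
    }
    Path(path).write_text(json.dumps(doc))


def load_tree(path: str | Path) -> OrganoidTree:
    doc = json.loads(Path(path).read_text())
    branches = {}
    for key, b in doc["branches"].items():
        bid = int(key)
        branches[bid] = Branch(
            id=bid,
            parent_id=b["parent_id"],
            nodes=np.asarray(b["nodes"], dtype=float),
            length=b["length"],
            width=b["width"],
            volume=b["volume"],
            birth_time=b["birth_time"],
            terminal=b["terminal"],
            broken=b["broken"],
        )
    return OrganoidTree(branches=branches, time=doc["time"], rng_seed=doc["rng_seed"])


def save_run(run: SimulationRun, directory: str | Path, run_config: RunConfig | None = None) -> None:
    """Archive a simulation run: one tree JSON per snapshot, an index CSV,
    and (when given) the resolved configuration plus package version."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for tree in run.trees:
        save_tree(tree, directory / f"tree_t{tree.time:07.3f}.json")
    run.index_table().to_csv(directory / "index.csv", index=False)
    meta = {"package_version": __version__, "seed": run.config.seed}
    (directory / "run.json").write_text(json.dumps(meta, indent=2))
    if run_config is not None:
        save_config(run_config, directory / "config.yaml")
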