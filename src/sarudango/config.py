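"""Pipeline configuration: YAML in, fully validated dataclass out.

An empty file (or no file) yields the standard experiment: group sizes
70–400, temperatures 1–10, joining thresholds 1–8, the per-size leaving
grids, 100 replicates, step cap 20,000.  Unknown keys and out-of-domain
values are rejected with the offending key named — a sweep this expensive
should never run on a silently misread config.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .sweep import SweepGrid, default_leave_thresholds

ALL_STAGES = ("sweep", "metrics", "glm", "comparison")
DEFAULT_GROUP_SIZES = (70, 100, 130, 160, 300, 400)


@dataclass(frozen=True)
class PipelineConfig:
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    temperatures: tuple[int, ...] = tuple(range(1, 11))
    join_thresholds: tuple[int, ...] = tuple(range(1, 9))
    leave_thresholds: Optional[tuple[int, ...]] = None  # None = per-size default
    replicates: int = 100
    base_seed: int = 0
    step_cap: int = 20_000
    candidate_policy: str = "random_neighbor"
    leave_mode: str = "per_member"
    nucleation_size: str = "lone_pool"
    join_selectivity: str = "nucleation_only"
    output_dir: str = "sarudango_out"
    stages: tuple[str, ...] = ALL_STAGES
    worker_count: int = 1
    glm_group_sizes: tuple[int, ...] = (70, 100, 130, 160)

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for g in self.grids():
            pass  # SweepGrid / SimParams validation runs in grids()

    def grids(self) -> list[SweepGrid]:
        """One sweep grid per configured group size."""
        out = []
        for n in self.group_sizes:
            leave = (self.leave_thresholds
                     if self.leave_thresholds is not None
                     else tuple(default_leave_thresholds(n)))
            out.append(
                SweepGrid(
                    group_size=n,
                    temperatures=self.temperatures,
                    join_thresholds=self.join_thresholds,
                    leave_thresholds=tuple(leave),
                    replicates=self.replicates,
                    base_seed=self.base_seed + 1_000_000 * n,
                    step_cap=self.step_cap,
                    candidate_policy=self.candidate_policy,
                    leave_mode=self.leave_mode,
                    nucleation_size=self.nucleation_size,
                    join_selectivity=self.join_selectivity,
                )
            )
        return out

    def sim_overrides(self) -> dict:
        return {
            "candidate_policy": self.candidate_policy,
            "leave_mode": self.leave_mode,
            "nucleation_size": self.nucleation_size,
            "join_selectivity": self.join_selectivity,
        }


_TUPLE_KEYS = {"group_sizes", "temperatures", "join_thresholds",
               "leave_thresholds", "stages", "glm_group_sizes"}


def load_config(path: Optional[str | Path] = None, **overrides) -> PipelineConfig:
    """Read a YAML config file, apply keyword overrides, validate everything."""
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping, "
                             f"got {type(loaded).__name__}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_KEYS & set(data):
        if data[key] is not None:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)
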