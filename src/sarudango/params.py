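"""Parameter vector for a single simulation run.

A run is fully specified by a :class:`SimParams` instance plus an integer
seed.  The temperature axis is the model's abstract 1–10 scale (1 = coldest
conditions under which huddling is observed, 10 = warm enough that huddling
is rare); it is not degrees Celsius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class SimParams:
    """Parameters of one huddling simulation.

    Attributes
    ----------
    group_size
        Number of agents, equal to the maximum attainable cluster size.
    temperature
        Ambient temperature on the model's integer 1–10 scale.
    join_threshold
        Divisor J in the join probability; larger J makes agents more
        selective about joining a huddle.
    candidate_policy
        How a lone agent picks what to try to join among everything in
        sensing range: ``"random_neighbor"`` draws one in-range agent
        uniformly (the candidate is that agent's cluster, or the agent
        itself as a nascent pair), ``"largest"`` deterministically targets
        the largest in-range cluster (ties to the lowest cluster id), falling
        back to the lowest-id lone agent.
    leave_threshold
        Divisor L in the leave probability; larger L makes agents more
        committed to staying.
    grid_width, grid_height
        Extent of the toroidal world, in patches.
    sensing_radius
        Radius (patch units) within which an agent perceives others.
    step_cap
        Maximum number of ticks before a run is cut off.
    """

    group_size: int
    temperature: int
    join_threshold: int
    leave_threshold: int
    grid_width: int = 16
    grid_height: int = 16
    sensing_radius: float = 2.0
    step_cap: int = 20_000
    candidate_policy: str = "random_neighbor"
    leave_mode: str = "per_member"
    nucleation_size: str = "lone_pool"
    join_selectivity: str = "nucleation_only"

    def __post_init__(self) -> None:
        if self.group_size < 2:
            raise ValueError(f"group_size must be >= 2, got {self.group_size}")
        if not 1 <= self.temperature <= 10:
            raise ValueError(
                f"temperature must be an integer in [1, 10], got {self.temperature}"
            )
        if self.join_threshold < 1:
            raise ValueError(
                f"join_threshold must be >= 1, got {self.join_threshold}"
            )
        if self.leave_threshold < 10:
            raise ValueError(
                f"leave_threshold must be >= 10, got {self.leave_threshold}"
            )
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.sensing_radius <= 0:
            raise ValueError(
                f"sensing_radius must be > 0, got {self.sensing_radius}"
            )
        # step_cap = 0 is permitted as a degenerate run that records its
        # initial (cluster-free) state and stops.
        if self.step_cap < 0:
            raise ValueError(f"step_cap must be >= 0, got {self.step_cap}")
        if self.candidate_policy not in ("random_neighbor", "largest"):
            raise ValueError(
                f"unknown candidate_policy {self.candidate_policy!r}"
            )
        if self.leave_mode not in ("size_scaled", "per_member", "timer"):
            raise ValueError(f"unknown leave_mode {self.leave_mode!r}")
        if self.nucleation_size not in ("lone_pool", "single"):
            raise ValueError(
                f"unknown nucleation_size {self.nucleation_size!r}"
            )
        if self.join_selectivity not in ("nucleation_only", "all_joins"):
            raise ValueError(
                f"unknown join_selectivity {self.join_selectivity!r}"
            )

    def replace(self, **changes) -> "SimParams":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return SimParams(**kwargs)
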