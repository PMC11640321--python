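"""Single-run execution: tick until everyone huddles or the cap is hit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._engine import _run_impl
from .params import SimParams
from .world import (_LEAVE_CODE, _NUC_CODE, _POLICY_CODE, _SEL_CODE,
                    WorldState, cluster_sizes, init_world)


@dataclass(frozen=True)
class RunRecord:
    """Outcome of one simulation run.

    ``n_clusters`` counts huddles of size >= 2 at termination;
    ``mean_cluster_size`` is ``None`` when no cluster survived
    (``no_cluster`` true).  ``termination`` is ``"all_joined"`` when every
    agent ended up huddled, ``"step_cap"`` when the tick budget ran out.
    """

    params: SimParams
    seed: int
    n_clusters: int
    cluster_sizes: tuple[int, ...]
    mean_cluster_size: Optional[float]
    no_cluster: bool
    termination: str
    steps_elapsed: int


def _record(world: WorldState, all_joined: bool, steps: int) -> RunRecord:
    sizes = tuple(sorted(cluster_sizes(world, validate=False), reverse=True))
    n = len(sizes)
    return RunRecord(
        params=world.params,
        seed=world.seed,
        n_clusters=n,
        cluster_sizes=sizes,
        mean_cluster_size=(sum(sizes) / n) if n else None,
        no_cluster=(n == 0),
        termination="all_joined" if all_joined else "step_cap",
        steps_elapsed=steps,
    )


def run_simulation(params: SimParams, seed: int) -> RunRecord:
    """Execute one run to termination; identical ``(params, seed)`` gives an
    identical record."""
    world = init_world(params, seed)
    p = params
    all_joined, steps = _run_impl(
        world.pos_x, world.pos_y, world.heading, world.slot,
        world.huddle_time, world.slot_used, world.slot_cid, world.slot_size,
        world.slot_ax, world.slot_ay, world.free_stack, world.meta,
        float(p.grid_width), float(p.grid_height), float(p.sensing_radius),
        float(p.temperature), float(p.join_threshold),
        float(p.leave_threshold), _POLICY_CODE[p.candidate_policy],
        _LEAVE_CODE[p.leave_mode], _NUC_CODE[p.nucleation_size],
        _SEL_CODE[p.join_selectivity], p.step_cap, world.rng,
    )
    return _record(world, bool(all_joined), int(steps))


def finish_run(world: WorldState, steps_done: int) -> RunRecord:
    """Summarise an externally ticked world into a :class:`RunRecord`."""
    return _record(world, world.n_lone == 0, steps_done)
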