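"""World state and the individual behavioural operations.

The world lives in flat numpy arrays (see :mod:`sarudango._engine`); this
module provides the object API over those arrays plus a pure-python
implementation of every per-agent operation — movement, sensing, joining,
leaving, cluster re-spacing.  :func:`tick_reference` composes them into one
shuffled pass that consumes the *identical* random-number stream as the
compiled kernel, which lets the test-suite assert bit-exact agreement
between the two paths.

Production runs go through :mod:`sarudango.run`, which drives the compiled
kernel; the operations here are the readable specification of what that
kernel does and are what unit tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._engine import (TWO_PI, _circle_point, _step_forward, _tick_impl,
                      _tor_d2)
from .params import SimParams

_POLICY_CODE = {"random_neighbor": 0, "largest": 1}
_LEAVE_CODE = {"per_member": 0, "size_scaled": 1, "timer": 2}
_NUC_CODE = {"single": 0, "lone_pool": 1}
_SEL_CODE = {"all_joins": 0, "nucleation_only": 1}


@dataclass(frozen=True)
class AgentState:
    """Read-only snapshot of one agent."""

    agent_id: int
    position: tuple[float, float]
    heading: float
    cluster_id: int  # -1 when not huddled
    huddle_time: int


@dataclass(frozen=True)
class Candidate:
    """Outcome of a sensing pass: the thing a lone agent may try to join.

    ``kind`` is ``"cluster"`` (an existing huddle; ``cluster_id`` and ``size``
    are set) or ``"lone"`` (a prospective partner; ``partner_id`` set,
    size 1).
    """

    kind: str
    size: int
    cluster_id: int = -1
    partner_id: int = -1


class WorldState:
    """Mutable simulation world: agents, cluster registry, tick counter, RNG.

    Clusters live in a slot-based registry (capacity = group size, since every
    cluster holds at least two members).  Slots are recycled through a free
    stack; the public *cluster id* is a monotone counter so identifiers are
    never reused.
    """

    def __init__(self, params: SimParams, seed: int):
        self.params = params
        self.seed = seed
        n = params.group_size
        self.rng = np.random.default_rng(seed)
        self.pos_x = np.empty(n)
        self.pos_y = np.empty(n)
        self.heading = np.empty(n)
        # agents start lone, uniformly scattered on the torus
        for i in range(n):
            self.pos_x[i] = self.rng.random() * params.grid_width
            self.pos_y[i] = self.rng.random() * params.grid_height
            self.heading[i] = self.rng.random() * TWO_PI
        self.slot = np.full(n, -1, np.int64)
        self.huddle_time = np.zeros(n, np.int64)
        self.slot_used = np.zeros(n, np.bool_)
        self.slot_cid = np.zeros(n, np.int64)
        self.slot_size = np.zeros(n, np.int64)
        self.slot_ax = np.zeros(n)
        self.slot_ay = np.zeros(n)
        self.free_stack = np.arange(n - 1, -1, -1, dtype=np.int64)
        # meta = [next_cluster_id, tick, free_slot_count]
        self.meta = np.array([0, 0, n], dtype=np.int64)

    # -- bookkeeping views ------------------------------------------------

    @property
    def tick_count(self) -> int:
        return int(self.meta[1])

    @property
    def n_lone(self) -> int:
        return int(np.count_nonzero(self.slot < 0))

    def agent(self, agent_id: int) -> AgentState:
        s = int(self.slot[agent_id])
        return AgentState(
            agent_id=agent_id,
            position=(float(self.pos_x[agent_id]), float(self.pos_y[agent_id])),
            heading=float(self.heading[agent_id]),
            cluster_id=int(self.slot_cid[s]) if s >= 0 else -1,
            huddle_time=int(self.huddle_time[agent_id]),
        )

    @property
    def agents(self) -> list[AgentState]:
        return [self.agent(i) for i in range(self.params.group_size)]

    @property
    def clusters(self) -> dict[int, dict]:
        """Cluster table: cluster_id -> {'members': tuple, 'anchor': (x, y)}."""
        out: dict[int, dict] = {}
        for s in range(self.params.group_size):
            if self.slot_used[s]:
                members = tuple(int(a) for a in np.flatnonzero(self.slot == s))
                out[int(self.slot_cid[s])] = {
                    "members": members,
                    "anchor": (float(self.slot_ax[s]), float(self.slot_ay[s])),
                }
        return out

    def toroidal_distance(self, a: int, b: int) -> float:
        p = self.params
        return float(
            np.sqrt(
                _tor_d2(self.pos_x[a], self.pos_y[a], self.pos_x[b],
                        self.pos_y[b], float(p.grid_width), float(p.grid_height))
            )
        )


def init_world(params: SimParams, seed: int) -> WorldState:
    """Fresh world: every agent lone (cluster id -1, huddle time 0), positions
    and headings uniform on the torus, empty cluster registry, tick 0.

    The same ``(params, seed)`` always yields a bit-identical world.
    """
    return WorldState(params, seed)


def cluster_sizes(world: WorldState, validate: bool = True) -> list[int]:
    """Sizes of all registered clusters (each necessarily >= 2).

    With ``validate=True`` the registry is cross-checked against a brute-force
    group-by of the agents' slots; any mismatch raises ``RuntimeError``.
    """
    sizes = []
    for s in range(world.params.group_size):
        if world.slot_used[s]:
            sizes.append(int(world.slot_size[s]))
            if validate:
                actual = int(np.count_nonzero(world.slot == s))
                if actual != world.slot_size[s]:
                    raise RuntimeError(
                        f"registry corruption: slot {s} records size "
                        f"{world.slot_size[s]} but {actual} agents carry it"
                    )
    if validate:
        n_clustered = int(np.count_nonzero(world.slot >= 0))
        if n_clustered != sum(sizes):
            raise RuntimeError("registry corruption: orphaned cluster slots")
    return sizes


# -- per-agent operations (python reference path) -------------------------


def move_lone_agent(world: WorldState, agent_id: int) -> None:
    """Resample the agent's heading uniformly and advance one patch unit,
    wrapping on the torus.  Only lone agents move."""
    if world.slot[agent_id] >= 0:
        raise ValueError(f"agent {agent_id} is huddled and cannot move")
    p = world.params
    h = world.rng.random() * TWO_PI
    world.heading[agent_id] = h
    world.pos_x[agent_id], world.pos_y[agent_id] = _step_forward(
        world.pos_x[agent_id], world.pos_y[agent_id], h,
        float(p.grid_width), float(p.grid_height),
    )


def neighbours_in_range(world: WorldState, agent_id: int) -> list[int]:
    """Ids of all other agents within the toroidal sensing radius, ascending."""
    p = world.params
    W, H = float(p.grid_width), float(p.grid_height)
    r2 = p.sensing_radius**2
    xi, yi = world.pos_x[agent_id], world.pos_y[agent_id]
    return [
        j
        for j in range(p.group_size)
        if j != agent_id
        and _tor_d2(xi, yi, world.pos_x[j], world.pos_y[j], W, H) <= r2
    ]


def find_candidate_cluster(world: WorldState, agent_id: int) -> Optional[Candidate]:
    """Sense within the toroidal sensing radius and pick what to try to join.

    Under the default ``random_neighbor`` policy one in-range agent is drawn
    uniformly (consuming a draw from the world's stream when any neighbour
    exists): a clustered pick proposes its cluster, a lone pick proposes a
    nascent pair.  Under ``largest``, the largest cluster represented by any
    in-range member wins (ties broken by lowest cluster id), with only lone
    agents in range the lowest-id one becomes a size-1 candidate.  ``None``
    when nobody is in range.
    """
    if world.slot[agent_id] >= 0:
        raise ValueError(f"agent {agent_id} is already huddled")
    nbrs = neighbours_in_range(world, agent_id)
    if not nbrs:
        return None
    if world.params.candidate_policy == "random_neighbor":
        j = nbrs[int(world.rng.random() * len(nbrs))]
        sj = int(world.slot[j])
        if sj >= 0:
            return Candidate(kind="cluster", size=int(world.slot_size[sj]),
                             cluster_id=int(world.slot_cid[sj]))
        return Candidate(kind="lone", size=1, partner_id=j)
    best_slot, best_size, best_cid = -1, 0, 2**62
    best_lone = -1
    for j in nbrs:
        sj = int(world.slot[j])
        if sj >= 0:
            sz = int(world.slot_size[sj])
            cid = int(world.slot_cid[sj])
            if sz > best_size or (sz == best_size and cid < best_cid):
                best_slot, best_size, best_cid = sj, sz, cid
        elif best_lone < 0:
            best_lone = j
    if best_slot >= 0:
        return Candidate(kind="cluster", size=best_size, cluster_id=best_cid)
    return Candidate(kind="lone", size=1, partner_id=best_lone)


def _slot_of_cid(world: WorldState, cid: int) -> int:
    for s in range(world.params.group_size):
        if world.slot_used[s] and world.slot_cid[s] == cid:
            return s
    raise KeyError(f"no active cluster with id {cid}")


def update_cluster_positions(world: WorldState, cluster_id: int) -> None:
    """Space the cluster's members evenly on a circle around its anchor.

    The circle radius is ``min(1, sensing_radius / 2)`` so every member stays
    well inside sensing range of the anchor; members are placed in ascending
    agent-id order, making the layout deterministic.
    """
    s = _slot_of_cid(world, cluster_id)
    p = world.params
    m = int(world.slot_size[s])
    rc = min(1.0, p.sensing_radius / 2.0)
    t = 0
    for a in range(p.group_size):
        if world.slot[a] == s:
            world.pos_x[a], world.pos_y[a] = _circle_point(
                float(world.slot_ax[s]), float(world.slot_ay[s]), rc, t, m,
                float(p.grid_width), float(p.grid_height),
            )
            t += 1


def attempt_join(world: WorldState, agent_id: int, candidate: Candidate,
                 u: Optional[float] = None) -> bool:
    """One Bernoulli join decision against ``p_join`` for the candidate.

    On success the agent (and, for a lone-partner candidate, the partner)
    is enrolled — a fresh cluster id is allocated when nucleating, with the
    joiner's position as anchor — and members are re-spaced.  Returns whether
    the join happened.  ``u`` overrides the uniform draw for testing; by
    default it is taken from the world's own stream.
    """
    if world.slot[agent_id] >= 0:
        raise ValueError(f"agent {agent_id} is already huddled")
    p = world.params
    if u is None:
        u = world.rng.random()
    n_cmax = p.group_size
    if candidate.kind == "cluster":
        # an established huddle pulls by size and temperature; the
        # selectivity divisor applies here only under 'all_joins'
        prob = (candidate.size / n_cmax) * (1.0 / p.temperature)
        if p.join_selectivity == "all_joins":
            prob = prob * (1.0 / p.join_threshold)
    else:
        if p.nucleation_size == "lone_pool":
            # both founders consent: the selectivity divisor applies twice
            n_eff = int(np.count_nonzero(world.slot < 0))
            prob = ((n_eff / n_cmax) * (1.0 / p.temperature)
                    * (1.0 / p.join_threshold) * (1.0 / p.join_threshold))
        else:
            prob = ((1 / n_cmax) * (1.0 / p.temperature)
                    * (1.0 / p.join_threshold))
    if not u < prob:
        return False
    if candidate.kind == "cluster":
        s = _slot_of_cid(world, candidate.cluster_id)
        world.slot[agent_id] = s
        world.huddle_time[agent_id] = 0
        world.slot_size[s] += 1
    else:
        world.meta[2] -= 1
        s = int(world.free_stack[world.meta[2]])
        world.slot_used[s] = True
        world.slot_cid[s] = world.meta[0]
        world.meta[0] += 1
        world.slot_size[s] = 2
        world.slot_ax[s] = world.pos_x[agent_id]
        world.slot_ay[s] = world.pos_y[agent_id]
        world.slot[agent_id] = s
        world.slot[candidate.partner_id] = s
        world.huddle_time[agent_id] = 0
        world.huddle_time[candidate.partner_id] = 0
    update_cluster_positions(world, int(world.slot_cid[s]))
    return True


def attempt_leave(world: WorldState, agent_id: int,
                  u: Optional[float] = None) -> bool:
    """One Bernoulli leave decision against ``p_leave`` for the agent's cluster.

    A leaver keeps its current position and resumes the random walk next
    tick.  A cluster reduced to a single member is dissolved and the remnant
    released.  On staying, the agent's huddle time increments.  Returns
    whether the agent left.
    """
    s = int(world.slot[agent_id])
    if s < 0:
        raise ValueError(f"agent {agent_id} is not huddled")
    p = world.params
    if u is None:
        u = world.rng.random()
    n_cmax = p.group_size
    sz = int(world.slot_size[s])
    prob = ((n_cmax - sz) / n_cmax) * (1.0 / p.leave_threshold)
    if p.leave_mode == "size_scaled":
        prob = prob / sz
    elif p.leave_mode == "timer" and world.huddle_time[agent_id] < p.leave_threshold:
        prob = -1.0
    if not u < prob:
        world.huddle_time[agent_id] += 1
        return False
    world.slot[agent_id] = -1
    world.huddle_time[agent_id] = 0
    world.slot_size[s] -= 1
    if world.slot_size[s] == 1:
        remnant = int(np.flatnonzero(world.slot == s)[0])
        world.slot[remnant] = -1
        world.huddle_time[remnant] = 0
        world.slot_used[s] = False
        world.slot_size[s] = 0
        world.free_stack[world.meta[2]] = s
        world.meta[2] += 1
    else:
        update_cluster_positions(world, int(world.slot_cid[s]))
    return True


def tick_reference(world: WorldState) -> int:
    """Pure-python tick: one shuffled pass, each agent acting on the world as
    it stands mid-pass.  Draw-for-draw identical to the compiled kernel.

    Returns the number of lone agents after the pass.
    """
    n = world.params.group_size
    order = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(world.rng.random() * (i + 1))
        order[i], order[j] = order[j], order[i]
    for k in range(n):
        i = int(order[k])
        if world.slot[i] < 0:
            move_lone_agent(world, i)
            cand = find_candidate_cluster(world, i)
            u = world.rng.random()  # one decision draw, candidate or not
            if cand is not None:
                attempt_join(world, i, cand, u=u)
        else:
            attempt_leave(world, i)
    world.meta[1] += 1
    return world.n_lone


def tick(world: WorldState) -> int:
    """Advance the world one tick using the compiled kernel.

    Returns the number of lone agents after the pass.  Trajectories are
    bit-identical to :func:`tick_reference`.
    """
    p = world.params
    n = p.group_size
    scratch = (np.empty(n, np.int64), np.empty(n, np.int64),
               np.empty(n, np.float64))
    return int(
        _tick_impl(
            world.pos_x, world.pos_y, world.heading, world.slot,
            world.huddle_time, world.slot_used, world.slot_cid,
            world.slot_size, world.slot_ax, world.slot_ay, world.free_stack,
            world.meta, float(p.grid_width), float(p.grid_height),
            float(p.sensing_radius), float(p.temperature),
            float(p.join_threshold), float(p.leave_threshold),
            _POLICY_CODE[p.candidate_policy], _LEAVE_CODE[p.leave_mode],
            _NUC_CODE[p.nucleation_size], _SEL_CODE[p.join_selectivity],
            world.rng, *scratch,
        )
    )
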