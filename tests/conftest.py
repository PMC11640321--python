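"""Shared fixtures: small worlds and cached miniature sweeps.

The miniature sweep used by several statistics tests is generated once per
session; its grid is intentionally tiny so the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sarudango.params import SimParams
from sarudango.sweep import SweepGrid, execute_sweep
from sarudango.world import init_world


@pytest.fixture
def small_params() -> SimParams:
    return SimParams(group_size=30, temperature=2, join_threshold=1,
                     leave_threshold=10)


@pytest.fixture
def small_world(small_params):
    return init_world(small_params, seed=7)


def make_world(n=20, t=2, j=1, lv=10, seed=3, **kw):
    return init_world(SimParams(n, t, j, lv, **kw), seed)


def place_cluster(world, member_ids, x=5.0, y=5.0):
    """Manually install a cluster into a fresh world (test scaffolding)."""
    s = int(world.free_stack[world.meta[2] - 1])
    world.meta[2] -= 1
    cid = int(world.meta[0])
    world.meta[0] += 1
    world.slot_used[s] = True
    world.slot_cid[s] = cid
    world.slot_size[s] = len(member_ids)
    world.slot_ax[s] = x
    world.slot_ay[s] = y
    for t_, a in enumerate(member_ids):
        world.slot[a] = s
        ang = 2 * np.pi * t_ / len(member_ids)
        world.pos_x[a] = (x + np.cos(ang)) % world.params.grid_width
        world.pos_y[a] = (y + np.sin(ang)) % world.params.grid_height
    return cid


@pytest.fixture(scope="session")
def mini_sweep_table() -> pd.DataFrame:
    """A tiny but real sweep: N=20, T x J x L = 3x2x2, 2 replicates."""
    grid = SweepGrid(
        group_size=20,
        temperatures=(1, 5, 10),
        join_thresholds=(1, 4),
        leave_thresholds=(10, 20),
        replicates=2,
        base_seed=99,
        step_cap=2000,
    )
    return execute_sweep(grid)
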