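"""Factorial parameter sweep with replicates and reproducible seeding.

The default grids mirror the simulation experiment the model was designed
for: temperatures 1–10, joining thresholds 1–8, 100 replicates, and a
leaving-threshold axis that is dense (step 10, up to 70) for a group of 70
and coarse (step 40, capped at 170) for the other group sizes — 56,000 runs
for the N = 70 grid.

Every run owns a seed derived deterministically from the grid's base seed
and the run's position in the enumeration, so results are independent of
execution order and worker count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .params import SimParams
from .run import RunRecord, run_simulation

logger = logging.getLogger(__name__)

#: canonical column order of a sweep result table
SWEEP_COLUMNS = [
    "group_size", "temperature", "join_threshold", "leave_threshold",
    "replicate", "seed", "n_clusters", "mean_cluster_size", "no_cluster",
    "termination", "steps_elapsed", "cluster_sizes",
]

_STANDARD_GROUP_SIZES = (70, 100, 130, 160, 300, 400)


def default_leave_thresholds(group_size: int) -> list[int]:
    """The leaving-threshold axis for one group size.

    Step 10 from 10 to 70 for a group of 70; otherwise step 40 from 10,
    truncated at ``min(group_size, 170)``.
    """
    if group_size == 70:
        return list(range(10, 71, 10))
    top = min(group_size, 170)
    return list(range(10, top + 1, 40))


@dataclass(frozen=True)
class SweepGrid:
    """Factorial design: one group size crossed with T, J and L axes."""

    group_size: int
    temperatures: tuple[int, ...]
    join_thresholds: tuple[int, ...]
    leave_thresholds: tuple[int, ...]
    replicates: int
    base_seed: int = 0
    step_cap: int = 20_000
    candidate_policy: str = "random_neighbor"
    leave_mode: str = "per_member"
    nucleation_size: str = "lone_pool"
    join_selectivity: str = "nucleation_only"

    def __post_init__(self) -> None:
        if not (self.temperatures and self.join_thresholds and self.leave_thresholds):
            raise ValueError("all sweep axes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        # validate every cell against the simulator's parameter domains
        for t in self.temperatures:
            for j in self.join_thresholds:
                for lv in self.leave_thresholds:
                    self._params(t, j, lv)

    def _params(self, t: int, j: int, lv: int) -> SimParams:
        return SimParams(
            self.group_size, t, j, lv, step_cap=self.step_cap,
            candidate_policy=self.candidate_policy,
            leave_mode=self.leave_mode,
            nucleation_size=self.nucleation_size,
            join_selectivity=self.join_selectivity,
        )


def default_grid(group_size: int, replicates: int = 100, base_seed: int = 0,
                 **overrides) -> SweepGrid:
    """The standard sweep design for one group size (56,000 runs at N = 70)."""
    if group_size not in _STANDARD_GROUP_SIZES:
        logger.warning(
            "group size %d is not one of the standard sizes %s",
            group_size, _STANDARD_GROUP_SIZES,
        )
    kwargs = dict(
        group_size=group_size,
        temperatures=tuple(range(1, 11)),
        join_thresholds=tuple(range(1, 9)),
        leave_thresholds=tuple(default_leave_thresholds(group_size)),
        replicates=replicates,
        base_seed=base_seed,
    )
    kwargs.update(overrides)
    return SweepGrid(**kwargs)


def count_runs(grid: SweepGrid) -> int:
    """Total number of runs the grid enumerates."""
    return (len(grid.temperatures) * len(grid.join_thresholds)
            * len(grid.leave_thresholds) * grid.replicates)


def enumerate_runs(grid: SweepGrid) -> Iterator[tuple[SimParams, int, int]]:
    """Yield ``(params, replicate, seed)`` in deterministic lexicographic
    order (temperature, join threshold, leave threshold, replicate); the
    seed is ``base_seed + ordinal``."""
    ordinal = 0
    for t in grid.temperatures:
        for j in grid.join_thresholds:
            for lv in grid.leave_thresholds:
                params = grid._params(t, j, lv)
                for rep in range(grid.replicates):
                    yield params, rep, grid.base_seed + ordinal
                    ordinal += 1


def record_to_row(rec: RunRecord, replicate: int) -> dict:
    return {
        "group_size": rec.params.group_size,
        "temperature": rec.params.temperature,
        "join_threshold": rec.params.join_threshold,
        "leave_threshold": rec.params.leave_threshold,
        "replicate": replicate,
        "seed": rec.seed,
        "n_clusters": rec.n_clusters,
        "mean_cluster_size": rec.mean_cluster_size,
        "no_cluster": int(rec.no_cluster),
        "termination": rec.termination,
        "steps_elapsed": rec.steps_elapsed,
        "cluster_sizes": ";".join(str(s) for s in rec.cluster_sizes),
    }


def execute_sweep(grid: SweepGrid, worker_count: int = 1,
                  log_every: int = 500) -> pd.DataFrame:
    """Run every cell x replicate of the grid; returns the result table.

    Seeds are bound to run specifications, not to workers, so the table is
    identical for any ``worker_count``.  The compiled tick kernel releases
    the GIL, hence threads parallelise cleanly.
    """
    if worker_count < 1:
        raise ValueError("worker_count must be >= 1")
    specs = list(enumerate_runs(grid))
    total = len(specs)
    logger.info("sweep N=%d: %d runs on %d worker(s)",
                grid.group_size, total, worker_count)

    def _one(idx: int, params: SimParams, rep: int, seed: int) -> dict:
        try:
            rec = run_simulation(params, seed)
        except Exception as exc:
            raise RuntimeError(
                f"sweep run {idx} failed: params={params}, seed={seed}"
            ) from exc
        if log_every and (idx + 1) % log_every == 0:
            logger.info("sweep N=%d: run %d/%d done (seed %d)",
                        grid.group_size, idx + 1, total, seed)
        return record_to_row(rec, rep)

    if worker_count == 1:
        rows = [_one(i, *spec) for i, spec in enumerate(specs)]
    else:
        rows = Parallel(n_jobs=worker_count, prefer="threads")(
            delayed(_one)(i, *spec) for i, spec in enumerate(specs)
        )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    if len(table) != count_runs(grid):
        raise RuntimeError("sweep dropped runs: "
                           f"{len(table)} rows != {count_runs(grid)} expected")
    return table


def run_sweeps(grids: list[SweepGrid], worker_count: int = 1) -> pd.DataFrame:
    """Execute several grids (e.g. one per group size) into one table."""
    return pd.concat(
        [execute_sweep(g, worker_count=worker_count) for g in grids],
        ignore_index=True,
    )


def write_sweep_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_sweep_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"cluster_sizes": "string"})
    table["cluster_sizes"] = table["cluster_sizes"].fillna("")
    return table[SWEEP_COLUMNS]


def pooled_cluster_sizes(table: pd.DataFrame) -> np.ndarray:
    """All individual cluster sizes across the table's runs, pooled."""
    sizes: list[int] = []
    for cell in table["cluster_sizes"]:
        if isinstance(cell, str) and cell:
            sizes.extend(int(x) for x in cell.split(";"))
    return np.asarray(sizes, dtype=np.int64)
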