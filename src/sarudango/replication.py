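"""Scaled-down replication of the published simulation experiment.

The original experiment is hours of CPU (full grids with 100 replicates per
cell, 256,000 runs).  This module defines the package's canonical reduced
version of it: the same temperature (1–10), joining-threshold (1–8) and
leaving-threshold grids over group sizes 70–160 with a single replicate per
cell, plus a thinned grid for the large 300/400 groups used only for the
cluster-size realism diagnostic.  All headline quantities — the no-cluster
fraction, the GLM coefficients, the large-cluster proportions and the
site-line rankings — are computed from these tables.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .comparison import builtin_site_lines, fit_all_lines, rank_against_site
from .metrics import extra_large_proportion, no_cluster_fraction
from .stats import GlmDesign, fit_nb_glm
from .sweep import SweepGrid, default_grid, execute_sweep, pooled_cluster_sizes

logger = logging.getLogger(__name__)

CORE_GROUP_SIZES = (70, 100, 130, 160)

#: group sizes and thinned axes for the cluster-size realism diagnostic;
#: one matched grid per size so the over-137 shares are comparable
REALISM_GROUP_SIZES = (160, 300, 400)
REALISM_TEMPERATURES = (1, 5, 9)
REALISM_JOIN_THRESHOLDS = (2, 5, 8)
REALISM_LEAVE_THRESHOLDS = (10, 90, 170)


def core_grids(base_seed: int, replicates: int = 1) -> list[SweepGrid]:
    """Default grids for the four group sizes the statistics are run on."""
    return [
        default_grid(n, replicates=replicates,
                     base_seed=base_seed + 1_000_000 * n)
        for n in CORE_GROUP_SIZES
    ]


def realism_grids(base_seed: int, replicates: int = 1) -> list[SweepGrid]:
    """Matched thinned grids for N = 160, 300, 400 (realism diagnostic)."""
    return [
        SweepGrid(
            group_size=n,
            temperatures=REALISM_TEMPERATURES,
            join_thresholds=REALISM_JOIN_THRESHOLDS,
            leave_thresholds=REALISM_LEAVE_THRESHOLDS,
            replicates=replicates,
            base_seed=base_seed + 2_000_000 + 1_000 * n,
        )
        for n in REALISM_GROUP_SIZES
    ]


def run_core_sweep(base_seed: int, replicates: int = 1,
                   worker_count: int = 1) -> pd.DataFrame:
    tables = []
    for grid in core_grids(base_seed, replicates):
        tables.append(execute_sweep(grid, worker_count=worker_count))
        logger.info("core sweep: finished N=%d", grid.group_size)
    return pd.concat(tables, ignore_index=True)


def run_realism_sweep(base_seed: int, replicates: int = 1,
                      worker_count: int = 1) -> pd.DataFrame:
    tables = [execute_sweep(g, worker_count=worker_count)
              for g in realism_grids(base_seed, replicates)]
    return pd.concat(tables, ignore_index=True)


def over_size_fraction(table: pd.DataFrame, group_size: int,
                       threshold: int = 137) -> float:
    """Fraction of pooled clusters above ``threshold`` for one group size."""
    pooled = pooled_cluster_sizes(table[table["group_size"] == group_size])
    if pooled.size == 0:
        return 0.0
    return float(np.mean(pooled > threshold))


def combination_pool(table: pd.DataFrame, group_size: int,
                     join_threshold: int) -> np.ndarray:
    return pooled_cluster_sizes(
        table[(table["group_size"] == group_size)
              & (table["join_threshold"] == join_threshold)]
    )


def headline_metrics(core: pd.DataFrame,
                     realism: pd.DataFrame | None = None) -> dict[str, dict]:
    """Every quantity the reduced replication reports, with problem sizes.

    Percentages are on a 0–100 scale.  Keys are stable; each value is
    ``{"value": float, "n": int}`` where ``n`` is the number of simulation
    runs (or pooled clusters) behind the number.
    """
    out: dict[str, dict] = {}

    def put(key: str, value: float, n: int) -> None:
        out[key] = {"value": float(value), "n": int(n)}

    # printed site equations, reconstructed from their anchors
    for name, line in builtin_site_lines().items():
        put(f"{name}_slope", round(line.slope, 2), 2)
        put(f"{name}_intercept", round(line.intercept, 2), 2)

    # sweep design arithmetic
    from .sweep import count_runs

    put("n70_default_grid_runs", count_runs(default_grid(70)), 1)

    # no-cluster fraction over the four statistical group sizes
    put("no_cluster_pct", 100.0 * no_cluster_fraction(core), len(core))

    # joining-threshold coefficients of the two count GLMs
    fit_counts = fit_nb_glm(core, GlmDesign("n_clusters"))
    put("glm_n_clusters_join_coef",
        fit_counts.coefficient("join_threshold"), fit_counts.n_obs)
    fit_size = fit_nb_glm(core, GlmDesign("individuals_per_cluster"))
    put("glm_per_cluster_join_coef",
        fit_size.coefficient("join_threshold"), fit_size.n_obs)

    # cluster-size realism for the combinations singled out in the field
    pool_160_6 = combination_pool(core, 160, 6)
    put("pct_over51_n160_j6", 100.0 * extra_large_proportion(pool_160_6),
        pool_160_6.size)
    pool_70_4 = combination_pool(core, 70, 4)
    put("pct_over51_n70_j4", 100.0 * extra_large_proportion(pool_70_4),
        pool_70_4.size)
    pool_100_2 = combination_pool(core, 100, 2)
    put("n_over100_n100_j2",
        int(np.sum(pool_100_2 > 100)) if pool_100_2.size else 0,
        pool_100_2.size)

    # best-matching combinations per site line
    fits = fit_all_lines(core)
    for name, site in builtin_site_lines().items():
        ranked = rank_against_site(fits, site)
        put(f"best_{name}_group_size", ranked.iloc[0]["group_size"],
            len(ranked))
        put(f"best_{name}_join_threshold", ranked.iloc[0]["join_threshold"],
            len(ranked))

    # over-137 exclusion diagnostic: matched thinned grids per group size
    if realism is not None:
        for n in REALISM_GROUP_SIZES:
            put(f"pct_over137_n{n}", 100.0 * over_size_fraction(realism, n),
                int((realism["group_size"] == n).sum()))
    return out
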