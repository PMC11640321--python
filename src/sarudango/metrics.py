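"""Summary statistics over sweep output.

Cluster-size categories follow the field convention for this system:
"large" huddles have 20–51 members, "extra-large" more than 51, and 137 is
the largest huddle ever recorded in the wild, making the fraction of
simulated clusters above it a useful realism diagnostic.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .sweep import pooled_cluster_sizes

LARGE_RANGE = (20, 51)      # closed interval
EXTRA_LARGE_MIN = 51        # strictly greater than
OBSERVED_MAX = 137          # strictly greater than

SUMMARY_COLUMNS = [
    "n_runs", "mean_of_mean_cluster_size", "mean_n_clusters",
    "prop_no_cluster", "prop_large", "prop_extra_large",
    "prop_over_observed_max",
]


def no_cluster_fraction(table: pd.DataFrame) -> float:
    """Fraction of runs that ended without a single surviving cluster."""
    if len(table) == 0:
        raise ValueError("empty sweep table")
    return float(table["no_cluster"].mean())


def extra_large_proportion(sizes: Iterable[int],
                           threshold: int = EXTRA_LARGE_MIN) -> float:
    """Fraction of pooled clusters strictly larger than ``threshold``."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    arr = np.asarray(list(sizes), dtype=np.int64)
    if arr.size == 0:
        warnings.warn("no clusters pooled; proportion reported as 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean(arr > threshold))


def large_proportion(sizes: Iterable[int],
                     low: int = LARGE_RANGE[0], high: int = LARGE_RANGE[1]) -> float:
    """Fraction of pooled clusters with between ``low`` and ``high`` members
    (closed interval)."""
    arr = np.asarray(list(sizes), dtype=np.int64)
    if arr.size == 0:
        warnings.warn("no clusters pooled; proportion reported as 0",
                      stacklevel=2)
        return 0.0
    return float(np.mean((arr >= low) & (arr <= high)))


def combination_summaries(table: pd.DataFrame,
                          keys: Sequence[str] = ("group_size", "join_threshold"),
                          ) -> pd.DataFrame:
    """One summary row per distinct key combination.

    Mean cluster size is averaged over runs that produced at least one
    cluster; size-category proportions pool every individual cluster of the
    group's runs.
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    allowed = {"group_size", "join_threshold", "leave_threshold", "temperature"}
    bad = set(keys) - allowed
    if bad:
        raise KeyError(f"unknown grouping keys: {sorted(bad)}")
    rows = []
    for key_vals, grp in table.groupby(list(keys), sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        pooled = pooled_cluster_sizes(grp)
        clustered = grp.loc[grp["no_cluster"] == 0, "mean_cluster_size"]
        row = dict(zip(keys, key_vals))
        row["n_runs"] = len(grp)
        row["mean_of_mean_cluster_size"] = (
            float(clustered.mean()) if len(clustered) else np.nan
        )
        row["mean_n_clusters"] = float(grp["n_clusters"].mean())
        row["prop_no_cluster"] = float(grp["no_cluster"].mean())
        if pooled.size:
            row["prop_large"] = float(np.mean(
                (pooled >= LARGE_RANGE[0]) & (pooled <= LARGE_RANGE[1])))
            row["prop_extra_large"] = float(np.mean(pooled > EXTRA_LARGE_MIN))
            row["prop_over_observed_max"] = float(np.mean(pooled > OBSERVED_MAX))
        else:
            row["prop_large"] = 0.0
            row["prop_extra_large"] = 0.0
            row["prop_over_observed_max"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=[*keys, *SUMMARY_COLUMNS])
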