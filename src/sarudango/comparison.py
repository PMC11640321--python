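"""Ranking simulated temperature–cluster-size lines against field sites.

Four field sites provide published anchor values for how mean huddle size
changes over the model's 1–10 temperature scale: Arashiyama (3 individuals
per cluster at temperature 1, none at 10), Katsuyama (a constant 2.2),
Takasakiyama (4.8 down to 2.8) and Shodoshima (30 down to 20 — the island
famous for its giant "monkey dumpling" huddles).  Each site therefore has a
straight line y = a·T + b.  Each simulated (group size, joining threshold)
combination gets its own least-squares line of per-run mean cluster size on
temperature, and combinations are ranked by how closely slope and intercept
match a site's line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata


@dataclass(frozen=True)
class SiteLine:
    """Empirical line for one site, built from two printed anchor points."""

    site: str
    anchor_low: tuple[float, float]   # (temperature, individuals per cluster)
    anchor_high: tuple[float, float]

    @property
    def slope(self) -> float:
        return line_from_anchors(self.anchor_low, self.anchor_high)[0]

    @property
    def intercept(self) -> float:
        return line_from_anchors(self.anchor_low, self.anchor_high)[1]


@dataclass(frozen=True)
class FitLine:
    """OLS line for one simulated (group size, join threshold) combination."""

    group_size: int
    join_threshold: int
    slope: float
    intercept: float
    n_points: int


def line_from_anchors(anchor_low: tuple[float, float],
                      anchor_high: tuple[float, float]) -> tuple[float, float]:
    """Slope and intercept of the line through two (temperature, y) anchors."""
    (t0, y0), (t1, y1) = anchor_low, anchor_high
    if t0 == t1:
        raise ValueError("anchor temperatures must differ")
    slope = (y1 - y0) / (t1 - t0)
    return slope, y0 - slope * t0


def builtin_site_lines() -> dict[str, SiteLine]:
    """The four field-site lines, anchored at temperatures 1 and 10."""
    return {
        "arashiyama": SiteLine("arashiyama", (1.0, 3.0), (10.0, 0.0)),
        "katsuyama": SiteLine("katsuyama", (1.0, 2.2), (10.0, 2.2)),
        "takasakiyama": SiteLine("takasakiyama", (1.0, 4.8), (10.0, 2.8)),
        "shodoshima": SiteLine("shodoshima", (1.0, 30.0), (10.0, 20.0)),
    }


def fit_temperature_line(table: pd.DataFrame, group_size: int,
                         join_threshold: int) -> FitLine:
    """OLS of per-run mean cluster size on temperature for one combination.

    Pools all leave thresholds and replicates; runs without clusters carry
    no response and are excluded.  Needs at least two distinct temperatures.
    """
    sub = table[
        (table["group_size"] == group_size)
        & (table["join_threshold"] == join_threshold)
        & (table["no_cluster"] == 0)
    ]
    temps = sub["temperature"].to_numpy(dtype=float)
    if len(np.unique(temps)) < 2:
        raise ValueError(
            f"combination (N={group_size}, J={join_threshold}) covers "
            f"{len(np.unique(temps))} temperature(s); need >= 2"
        )
    y = sub["mean_cluster_size"].to_numpy(dtype=float)
    X = sm.add_constant(temps)
    res = sm.OLS(y, X).fit()
    return FitLine(
        group_size=group_size,
        join_threshold=join_threshold,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        n_points=len(sub),
    )


def fit_all_lines(table: pd.DataFrame) -> list[FitLine]:
    """One temperature line per (group size, join threshold) in the table.

    Combinations with insufficient temperature coverage are skipped.
    """
    fits = []
    combos = (
        table[["group_size", "join_threshold"]]
        .drop_duplicates()
        .sort_values(["group_size", "join_threshold"])
    )
    for n, j in combos.itertuples(index=False):
        try:
            fits.append(fit_temperature_line(table, int(n), int(j)))
        except ValueError:
            continue
    return fits


def rank_against_site(fits: list[FitLine], site: SiteLine) -> pd.DataFrame:
    """Rank fitted lines by agreement with one site's line.

    Absolute slope and intercept differences are ranked separately
    (ascending, ties get average ranks) and combined as their mean; the
    result is sorted by that mean rank.
    """
    if not fits:
        raise ValueError("no fitted lines to rank")
    rows = pd.DataFrame(
        {
            "group_size": [f.group_size for f in fits],
            "join_threshold": [f.join_threshold for f in fits],
            "abs_diff_intercept": [abs(f.intercept - site.intercept) for f in fits],
            "abs_diff_slope": [abs(f.slope - site.slope) for f in fits],
        }
    )
    rows["rank_intercept"] = rankdata(rows["abs_diff_intercept"], method="average")
    rows["rank_slope"] = rankdata(rows["abs_diff_slope"], method="average")
    rows["mean_rank"] = (rows["rank_intercept"] + rows["rank_slope"]) / 2.0
    rows.insert(0, "site", site.site)
    return (
        rows.sort_values(["mean_rank", "group_size", "join_threshold"])
        .reset_index(drop=True)
    )


def rank_all_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Fit all combination lines once, rank them against every site."""
    fits = fit_all_lines(table)
    return pd.concat(
        [rank_against_site(fits, s) for s in builtin_site_lines().values()],
        ignore_index=True,
    )


def site_lines_frame() -> pd.DataFrame:
    """Site lines as a table (for CSV export and audit)."""
    rows = []
    for s in builtin_site_lines().values():
        rows.append(
            {
                "site": s.site,
                "t_low": s.anchor_low[0], "y_low": s.anchor_low[1],
                "t_high": s.anchor_high[0], "y_high": s.anchor_high[1],
                "slope": s.slope, "intercept": s.intercept,
            }
        )
    return pd.DataFrame(rows)
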