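"""End-to-end pipeline: sweep -> metrics -> GLM -> empirical comparison.

Every stage reads and writes plain CSV in the configured output directory
and the whole run is summarised in ``manifest.json`` (file name -> sha256),
so two runs with the same config and base seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .comparison import fit_all_lines, rank_against_site, builtin_site_lines, site_lines_frame
from .config import PipelineConfig
from .metrics import combination_summaries
from .stats import (GlmDesign, coefficient_summary, compute_vif, fit_nb_glm,
                    prepare_glm_table, stepwise_select)
from .sweep import read_sweep_csv, run_sweeps, write_sweep_csv

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(
            f"stage '{stage}' needs {path.name}, which does not exist in "
            f"{path.parent} — run the sweep stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the artefact manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sweep_path = out / "sweep.csv"

    if "sweep" in config.stages:
        logger.info("stage sweep: %d grid(s), base seed %d",
                    len(config.group_sizes), config.base_seed)
        table = run_sweeps(config.grids(), worker_count=config.worker_count)
        write_sweep_csv(table, sweep_path)
        written.append(sweep_path)

    if "metrics" in config.stages:
        table = read_sweep_csv(_require(sweep_path, "metrics"))
        summ = combination_summaries(table, ("group_size", "join_threshold"))
        p = out / "combination_summaries.csv"
        summ.to_csv(p, index=False)
        written.append(p)

    if "glm" in config.stages:
        table = read_sweep_csv(_require(sweep_path, "glm"))
        for response in ("n_clusters", "individuals_per_cluster"):
            design = GlmDesign(response=response,
                               group_sizes=config.glm_group_sizes)
            try:
                fit = fit_nb_glm(table, design)
            except Exception as exc:  # surface which model failed
                raise StageError(f"stage 'glm' failed for response "
                                 f"{response!r}: {exc}") from exc
            coef = coefficient_summary(fit)
            p = out / f"glm_{response}.csv"
            coef.to_csv(p, index_label="term")
            written.append(p)
            logger.info("GLM %s: theta=%.3g AIC=%.1f", response,
                        fit.theta if fit.theta is not None else float("nan"),
                        fit.aic)
            trace, _ = stepwise_select(table, design, criterion="AIC")
            p = out / f"glm_stepwise_{response}.csv"
            trace.to_csv(p, index=False)
            written.append(p)
        vif = compute_vif(prepare_glm_table(
            table, GlmDesign(response="n_clusters",
                             group_sizes=config.glm_group_sizes)))
        p = out / "vif.csv"
        vif.to_csv(p, header=True, index_label="predictor")
        written.append(p)

    if "comparison" in config.stages:
        table = read_sweep_csv(_require(sweep_path, "comparison"))
        glm_sizes = set(config.glm_group_sizes)
        sub = table[table["group_size"].isin(glm_sizes)]
        fits = fit_all_lines(sub)
        lines = pd.DataFrame(
            [
                {
                    "group_size": f.group_size, "join_threshold": f.join_threshold,
                    "slope": f.slope, "intercept": f.intercept,
                    "n_points": f.n_points,
                }
                for f in fits
            ]
        )
        p = out / "fitted_lines.csv"
        lines.to_csv(p, index=False)
        written.append(p)
        ranks = pd.concat(
            [rank_against_site(fits, s) for s in builtin_site_lines().values()],
            ignore_index=True,
        )
        p = out / "site_rankings.csv"
        ranks.to_csv(p, index=False)
        written.append(p)
        p = out / "site_lines.csv"
        site_lines_frame().to_csv(p, index=False)
        written.append(p)

    manifest = {p.name: _sha256(p) for p in written}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %d artefact(s) in %s", len(written), out)
    return manifest
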