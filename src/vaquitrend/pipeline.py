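"""End-to-end analysis pipeline: prepare -> fit -> diagnose -> trend -> project.

One entry point (:func:`run_all`) chains the stages, writes every tabular
output as headered CSV with a JSON metadata sidecar (seed, configuration,
data fingerprint), and returns the in-memory results.  Each stage is also
runnable on its own from the library or the CLI, reading the serialized
intermediates of the previous stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .diagnostics import diagnostic_report
from .geostat import MCMCConfig, PosteriorDraws, PriorSpec, fit
from .projection import (TrajectorySet, abundance_table, apply_minimum_counts,
                         lognormal_from_moments, project, updated_trend_table)
from .synthetic import SyntheticTruth, scenario_study_like, simulate_dataset
from .trend import compute_B, compute_lambda, trend_table

log = logging.getLogger("vaquitrend")


@dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML."""

    output_dir: str = "vaquitrend_run"
    seed: int = 0
    # data source: either file paths or a synthetic scenario
    detections_path: str | None = None
    effort_path: str | None = None
    sites_path: str | None = None
    column_map: dict | None = None
    synthetic: bool = True
    core_window: tuple = aio.DEFAULT_CORE_WINDOW
    # model
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    # projection
    abundance_mean: float = 66.0
    abundance_sd: float = 33.0
    projection_start_year: int = 2015
    minimum_counts: dict = field(default_factory=lambda: {2017: 7, 2018: 6})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "priors" in raw:
            raw["priors"] = PriorSpec(**raw["priors"])
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "core_window" in raw:
            raw["core_window"] = tuple(raw["core_window"])
        if "minimum_counts" in raw:
            raw["minimum_counts"] = {int(k): int(v)
                                     for k, v in raw["minimum_counts"].items()}
        return cls(**raw)


def prepare(config: RunConfig):
    """Load (or simulate) daily records and annualize them."""
    if config.synthetic:
        truth = scenario_study_like(seed=config.seed)
        dataset, real = simulate_dataset(truth)[:2]
        return dataset, {"source": "synthetic", "truth_seed": truth.seed,
                         "lambda_true": [float(x) for x in real.lambda_true]}
    grid = aio.load_site_grid(config.sites_path, config.column_map)
    records = aio.load_daily_records(config.detections_path, config.effort_path,
                                     config.column_map, grid=grid)
    dataset = aio.annualize(records, config.core_window, grid=grid)
    return dataset, {"source": "files", "n_records": int(len(records))}


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline, writing all outputs under ``config.output_dir``.

    Produces: annual summaries, posterior draws, a diagnostics report, the
    trend table (before and after the minimum-count update), abundance
    summaries for the projected years, and a JSON log of seeds and
    configuration.  Raises at the failing stage with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        meta["stages"][name] = "ok"

    try:
        stage("prepare")
        dataset, prep_meta = prepare(config)
        meta["prepare"] = prep_meta
        dataset.summaries.to_csv(out / "annual_summaries.csv", index=False)
        dataset.grid.to_frame().to_csv(out / "sites.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'prepare' failed: {exc}") from exc

    try:
        stage("fit")
        mcmc = MCMCConfig(**{**asdict(config.mcmc), "seed": config.seed})
        draws = fit(dataset, config.priors, mcmc)
        draws.write_csv(out / "posterior_draws.csv", out / "posterior_meta.json")
        meta["fit"] = {"n_draws": draws.n_draws,
                       "rho_accept_rate": draws.rho_accept_rate,
                       "warnings": draws.warnings}
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc

    try:
        stage("diagnose")
        report = diagnostic_report(draws, dataset, seed=config.seed)
        report["parameters"].to_csv(out / "diagnostics.csv", index=False)
        report["bayes_p"].to_csv(out / "bayes_p_values.csv", index=False)
        meta["diagnose"] = {"converged": report["converged"],
                            "fraction_extreme_p": report["fraction_extreme_p"]}
    except Exception as exc:
        raise RuntimeError(f"stage 'diagnose' failed: {exc}") from exc

    try:
        stage("trend")
        table = trend_table(draws)
        table.to_csv(out / "trend_table.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'trend' failed: {exc}") from exc

    try:
        stage("project")
        b = compute_B(draws)
        years = draws.years
        start = config.projection_start_year
        if start not in years:
            raise ValueError(f"projection start year {start} not fitted")
        streams = {
            (t1, t2): compute_lambda(b, years, t1, t2).draws
            for t1, t2 in zip(years[years.index(start):-1],
                              years[years.index(start) + 1:])
        }
        prior = lognormal_from_moments(config.abundance_mean, config.abundance_sd)
        trajectories = project(prior, streams, seed=config.seed)
        updated = apply_minimum_counts(trajectories, config.minimum_counts)
        abundance_pre = abundance_table(trajectories, retained_only=False)
        abundance_post = abundance_table(updated, retained_only=True)
        abundance_pre.assign(update="before").to_csv(
            out / "abundance_before_update.csv", index=False)
        abundance_post.assign(update="after").to_csv(
            out / "abundance_after_update.csv", index=False)
        updated.table.to_csv(out / "trajectories.csv", index=False)
        table_after = updated_trend_table(draws, updated)
        table_after.to_csv(out / "trend_table_after_update.csv", index=False)
        meta["project"] = {"n_trajectories": trajectories.n_trajectories,
                           "n_retained": updated.n_retained}
    except Exception as exc:
        raise RuntimeError(f"stage 'project' failed: {exc}") from exc

    with open(out / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)

    return {
        "dataset": dataset,
        "draws": draws,
        "diagnostics": report,
        "trend_table": table,
        "trend_table_after_update": table_after,
        "trajectories": updated,
        "abundance_before": abundance_pre,
        "abundance_after": abundance_post,
        "meta": meta,
    }
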