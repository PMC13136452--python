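"""End-to-end pipeline: simulate-or-ingest → score → aggregate →
demographics → trends, with every intermediate written to disk.

Outputs are deterministic under a fixed seed: no timestamps, sorted JSON
keys, full-precision CSV — two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .demographics import build_summary, round_for_display
from .exposure import aggregate_city
from .io import (PipelineConfig, read_grid_csv, read_holc, read_tracts,
                 write_geojson, write_grid_csv)
from .redlining_score import score_city, score_summary
from .synthetic_city import SyntheticTruth, generate_city
from .trends import build_trend_table

log = logging.getLogger(__name__)


def _trend_json(result: dict) -> dict:
    fit = result["fit"]
    return {
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "covariance": [[float(x) for x in row] for row in fit.cov.to_numpy()],
        "sigma2_tract": fit.sigma2_u,
        "sigma2_resid": fit.sigma2_e,
        "n_obs": fit.n_obs,
        "n_tracts": fit.n_tracts,
        "method": fit.method,
        "reference": fit.reference,
        "year_origin": fit.year_origin,
        "overall_level_p": {str(y): p for y, p in result["overall_level_p"].items()},
        "overall_slope_p": result["overall_slope_p"],
        "bonferroni_m": result["bonferroni_m"],
        "contrasts": {
            f"{mode}" + (f"_{y}" if y is not None else ""):
                [dataclasses.asdict(c) for c in crs]
            for (mode, y), crs in result["contrasts"].items()},
    }


def run_report(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    When input paths are absent from the config, the synthetic-city
    generator supplies the corresponding stage's inputs.  Returns a dict
    with the in-memory results (scores, panel, summary, trends, log).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logbook: dict = {"holcair_version": __version__,
                     "config": config.to_log_dict(), "stages": {}}

    synthetic = config.tracts_path is None
    if synthetic:
        truth = SyntheticTruth(seed=config.seed)
        city = generate_city(nx=config.nx, ny=config.ny, cell_m=config.cell_m,
                             years=tuple(config.years), truth=truth,
                             grid_cell_m=config.grid_cell_m,
                             pollutant=config.pollutant, seed=config.seed)
        tracts, graded, grid = city.tracts, city.graded_areas, city.pollution
        write_geojson(tracts.assign(geometry=tracts.geometry), out / "tracts.geojson")
        write_geojson(graded, out / "holc_areas.geojson")
        write_grid_csv(grid, out / "grid_values.csv", out / "grid_cells.csv")
        truth_dict = dataclasses.asdict(truth)
        (out / "truth.json").write_text(json.dumps(truth_dict, sort_keys=True,
                                                   default=float))
    else:
        if config.holc_path is None or config.grid_values_path is None:
            raise ValueError("real-data runs need tracts, HOLC and grid paths")
        tracts = read_tracts(config.tracts_path, config.id_field, config.area_field)
        graded = read_holc(config.holc_path, config.grade_field)
        grid = read_grid_csv(config.grid_values_path, config.grid_cells_path,
                             config.pollutant)

    scores = score_city(tracts, graded, config.sliver_m2)
    summary = score_summary(scores)
    scores.to_csv(out / "scores.csv", index=False)
    (out / "score_summary.json").write_text(
        json.dumps(summary.to_dict(orient="records"), sort_keys=True))
    logbook["stages"]["score"] = {"n_tracts_in": len(tracts),
                                  "n_tracts_selected": len(scores)}

    panel = aggregate_city(tracts[tracts.tract_id.isin(scores.tract_id)], grid,
                           screen=config.screen,
                           threshold=config.screen_threshold,
                           min_run_days=config.screen_min_run_days,
                           manual_list=config.manual_exclusions,
                           min_coverage=config.min_coverage,
                           min_day_frac=config.min_day_frac)
    panel.to_csv(out / "panel.csv", index=False)
    agg_log = {"n_rows": len(panel),
               "n_missing_means": int(panel["mean"].isna().sum())}
    if "screen_report" in panel.attrs:
        rep = panel.attrs["screen_report"]
        rep.to_csv(out / "exclusions.csv", index=False)
        agg_log["excluded_by_year"] = {str(r.year): int(r.n_removed)
                                       for r in rep.itertuples(index=False)}
    logbook["stages"]["aggregate"] = agg_log

    if synthetic:
        census, svi = city.census, city.svi
        census.to_csv(out / "census.csv", index=False)
        svi.to_csv(out / "svi.csv", index=False)
    else:
        census = pd.read_csv(config.census_path) if config.census_path else None
        svi = pd.read_csv(config.svi_path) if config.svi_path else None
    if census is not None and svi is not None:
        demo = build_summary(census, svi, scores)
        demo.to_csv(out / "demographics.csv", index=False)
        round_for_display(demo).to_csv(out / "demographics_display.csv", index=False)
        logbook["stages"]["demographics"] = {"n_cells": len(demo)}

    trend = build_trend_table(panel.dropna(subset=["mean"]), scores,
                              years=list(config.report_years),
                              reference=config.reference,
                              alpha=config.alpha, gate=config.gate_contrasts,
                              year_origin=config.year_origin)
    trend["table"].to_csv(out / "trend_table.csv", index=False)
    (out / "trend_fit.json").write_text(json.dumps(_trend_json(trend),
                                                   sort_keys=True))
    logbook["stages"]["trends"] = {"n_obs": trend["fit"].n_obs,
                                   "method": trend["fit"].method}

    # per-category annual mean series (basis for a trends-over-time figure)
    series = (panel.merge(scores[["tract_id", "category"]], on="tract_id")
              .groupby(["category", "year"], as_index=False)["mean"].mean()
              .rename(columns={"mean": "category_mean"}))
    series.to_csv(out / "category_year_means.csv", index=False)

    (out / "report_log.json").write_text(json.dumps(logbook, sort_keys=True,
                                                    default=str))
    return {"scores": scores, "summary": summary, "panel": panel,
            "trend": trend, "log": logbook}
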