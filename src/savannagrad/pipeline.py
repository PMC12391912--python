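"""Chained execution of the census-analysis stages with one global seed.

Stages: ``simulate -> impute -> aggregate -> diversity -> biomass -> fit ->
stabsel -> predict-gradient``.  One global seed deterministically derives a
per-stage seed, so a stage can be re-run in isolation and still match the full
pipeline.  Every run writes a machine-readable manifest (stage order, row
counts, seeds, package version).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import savannagrad
from savannagrad import censusio
from savannagrad.aggregate import aggregate_grid
from savannagrad.boost import BoostModel, boost_fit, build_base_learners, cv_tune
from savannagrad.families import family_from_name
from savannagrad.gradients import (
    conditioning_record,
    default_distance_grid,
    gradient_curve,
)
from savannagrad.kriging import impute_grid
from savannagrad.metrics import SpeciesAttributes, block_biomass, diversity_profile
from savannagrad.stabsel import stabsel
from savannagrad.synthetic import ScenarioConfig, simulate_landscape, write_truth

log = logging.getLogger(__name__)

STAGES = ("simulate", "impute", "aggregate", "diversity", "biomass",
          "fit", "stabsel", "predict-gradient")


class PipelineConfigError(ValueError):
    """Invalid stage list or missing stage inputs."""


def stage_seed(global_seed, stage):
    """Deterministic per-stage seed below 2**31."""
    h = np.random.SeedSequence([int(global_seed), STAGES.index(stage)])
    return int(h.generate_state(1)[0] % (2**31))


def metrics_table(blocks, colmap):
    """Diversity profile + biomass per (block, year) row of a block table."""
    attrs = SpeciesAttributes.default()
    species = [s for s in colmap.species]
    rows = []
    for _, rec in blocks.iterrows():
        counts = rec[species].to_numpy(dtype=float)
        prof = diversity_profile(counts)
        bio = block_biomass({s: float(rec[s]) for s in species}, attrs)
        rows.append({
            colmap.block_id: rec[colmap.block_id],
            colmap.year: rec[colmap.year],
            **prof.as_dict(),
            "biomass_kg": bio.total_kg,
            "biomass_migratory_kg": bio.migratory_kg,
            "biomass_nonmigratory_kg": bio.nonmigratory_kg,
        })
    out = pd.DataFrame(rows)
    return blocks.merge(out, on=[colmap.block_id, colmap.year])


def default_model_predictors(colmap):
    metric = [colmap.dist_boundary] + list(colmap.covariates)
    binary = list(colmap.flags)
    return metric, binary


def fit_response_model(
    blocks,
    response,
    family,
    colmap,
    grouping=("year",),
    metric_predictors=None,
    binary_predictors=None,
    n_iter=300,
    step=0.1,
    use_cv=False,
    cv_max_iter=200,
    n_resamples=10,
    seed=0,
):
    """Build learners and fit (optionally CV-tuned) one response model."""
    if isinstance(family, str):
        family = family_from_name(family)
    metric, binary = default_model_predictors(colmap)
    metric = list(metric_predictors or metric)
    binary = list(binary_predictors or binary)
    grouping = [colmap.year if g == "year" else g for g in grouping]
    data = blocks.dropna(subset=[response]).reset_index(drop=True)
    specs = build_base_learners(
        data, family, metric_predictors=metric, binary_predictors=binary,
        grouping=grouping,
    )
    if use_cv:
        cv = cv_tune(
            data, response, family, specs, max_iter=cv_max_iter, step=step,
            n_resamples=n_resamples, stratify=grouping, seed=seed,
        )
        n_iter = max(cv.mstop, 1)
    model = boost_fit(data, response, family, specs, n_iter=n_iter, step=step)
    return model, data


def run_pipeline(config, out_dir, seed=0):
    """Run the configured stages and write all artifacts plus a manifest.

    ``config`` is a dict (usually parsed from YAML) with a ``stages`` list and
    optional per-stage parameter blocks.  Stage order must follow the
    canonical order and later stages require their upstream products.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    order = [STAGES.index(s) for s in stages if s in STAGES]
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineConfigError(f"unknown stage(s): {unknown}")
    if order != sorted(order):
        raise PipelineConfigError(f"stages out of order: {stages}")

    manifest = {"version": savannagrad.__version__, "seed": int(seed), "stages": []}
    t_all = time.time()
    grid = blocks = model_info = None
    colmap = censusio.ColumnMap.default()

    for stage in stages:
        t0 = time.time()
        info = {"stage": stage, "seed": stage_seed(seed, stage)}
        params = config.get(stage.replace("-", "_"), {}) or {}
        if stage == "simulate":
            sc = ScenarioConfig(**{**params, "seed": stage_seed(seed, stage)})
            grid = simulate_landscape(sc)
            colmap = grid.colmap
            censusio.write_subblock_csv(grid, out / "subblocks.csv")
            write_truth(sc, grid).to_csv(out / "truth.csv", index=False)
            info["rows"] = len(grid)
        elif stage == "impute":
            if grid is None:
                grid = censusio.read_subblock_csv(config["inputs"]["subblocks"], colmap)
            grid = impute_grid(grid, columns=params.get("columns"),
                               seed=stage_seed(seed, stage),
                               max_neighbors=params.get("max_neighbors", 32))
            censusio.write_subblock_csv(grid, out / "subblocks_imputed.csv")
            info["rows"] = len(grid)
        elif stage == "aggregate":
            if grid is None:
                raise PipelineConfigError("aggregate requires a simulated or loaded grid")
            blocks = aggregate_grid(grid)
            censusio.write_block_csv(blocks, out / "blocks.csv", colmap)
            info["rows"] = len(blocks)
        elif stage in ("diversity", "biomass"):
            if blocks is None:
                raise PipelineConfigError(f"{stage} requires aggregated blocks")
            if "d0" not in blocks.columns:
                blocks = metrics_table(blocks, colmap)
                censusio.write_block_csv(blocks, out / "block_metrics.csv", colmap)
            info["rows"] = len(blocks)
        elif stage == "fit":
            if blocks is None or "d0" not in blocks.columns:
                raise PipelineConfigError("fit requires block metrics")
            response = params.get("response", "richness_raw")
            famname = params.get("family", "nb")
            shift = params.get("shift", 0.0)
            family = family_from_name(famname, shift=shift)
            model, data = fit_response_model(
                blocks, response, family, colmap,
                grouping=params.get("grouping", ("year",)),
                metric_predictors=params.get("metric_predictors"),
                binary_predictors=params.get("binary_predictors"),
                n_iter=params.get("n_iter", 300),
                step=params.get("step", 0.1),
                use_cv=params.get("use_cv", False),
                cv_max_iter=params.get("cv_max_iter", 200),
                n_resamples=params.get("n_resamples", 10),
                seed=stage_seed(seed, stage),
            )
            (out / "model.json").write_text(json.dumps(model.to_dict()))
            pd.DataFrame({"iteration": range(len(model.risks)),
                          "train_nll": model.risks}).to_csv(out / "risk_curve.csv", index=False)
            model_info = {"model": model, "data": data, "response": response}
            info["mstop"] = model.mstop
        elif stage == "stabsel":
            if model_info is None:
                raise PipelineConfigError("stabsel requires a fitted model stage")
            family = model_info["model"].family
            data = model_info["data"]
            metric, binary = default_model_predictors(colmap)
            specs = build_base_learners(
                data, family,
                metric_predictors=params.get("metric_predictors", metric),
                binary_predictors=params.get("binary_predictors", binary),
                grouping=[colmap.year],
            )
            res = stabsel(
                data, model_info["response"], family, specs,
                b=params.get("b", 50), q_sel=params.get("q_sel", 6),
                pi_thr=params.get("pi_thr", 0.7),
                seed=stage_seed(seed, stage),
                max_iter=params.get("max_iter", 500),
            )
            res.frequencies.to_csv(out / "selection_frequencies.csv", index=False)
            (out / "stable_set.txt").write_text(
                "\n".join(res.stable_set) + f"\nPFER bound: {res.pfer_bound:.3f}\n"
            )
            info["stable_set_size"] = len(res.stable_set)
        elif stage == "predict-gradient":
            if model_info is None:
                raise PipelineConfigError("predict-gradient requires a fitted model")
            data = model_info["data"]
            metric, binary = default_model_predictors(colmap)
            cond = conditioning_record(data, metric, binary, colmap.dist_boundary)
            dgrid = default_distance_grid(data, colmap.dist_boundary,
                                          params.get("step_km", 0.5))
            obs_range = (data[colmap.dist_boundary].min(), data[colmap.dist_boundary].max())
            curves = []
            for year in sorted(data[colmap.year].unique()):
                curve = gradient_curve(
                    model_info["model"], dgrid, cond, colmap.dist_boundary,
                    extra={colmap.year: year}, observed_range=obs_range,
                )
                frame = curve.to_frame()
                frame["year"] = year
                curves.append(frame)
                info[f"peak_km_{year}"] = curve.peak_distance
            pd.concat(curves, ignore_index=True).to_csv(out / "gradient_curves.csv", index=False)
        info["elapsed_s"] = round(time.time() - t0, 3)
        manifest["stages"].append(info)

    manifest["elapsed_s"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
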