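"""End-to-end orchestration of the winter-distribution analysis.

Stage order follows the filtering ladder and modelling workflow: simulate
(optional, synthetic studies) -> proof/standardise -> season & daytime ->
life-history classification -> behavioural state -> thinning -> train/test
split -> covariate engineering & screening -> background sampling ->
regularization tuning -> final fit -> projection -> evaluation ->
comparison.  Every stage writes its outputs plus a manifest (parameters,
seed, row counts) under its own subdirectory, and a completed stage is
reused on resume rather than recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare as cmp
from . import covariates as cov
from . import evalsuite as ev
from . import io
from . import lifehistory as lh
from . import maxent as mx
from . import synthio
from . import telemetry as tm
from .grid import Raster

RECOVERY_CATEGORIES = {
    "climate_weather": 1,
    "vegetation_landcover": 1,
    "developed": 1,
    "topography": 1,
    "wind_uplift": 1,
}

STAGE_SEED_OFFSET = {
    "simulate": 11,
    "filter": 23,
    "thin": 31,
    "split": 37,
    "covars": 41,
    "model": 53,
}


@dataclass
class PipelineConfig:
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    filters: tm.FilterParams = field(default_factory=tm.FilterParams)
    extents: tuple = cov.EXTENT_LADDER_M
    statistics: tuple = ("mean", "sd")
    n_random_screen: int = 10_000
    vif_threshold: float = 4.0
    n_background: int = 100_000
    buffer_km: float = 20.0
    reg_candidates: tuple = mx.DEFAULT_REG_CANDIDATES
    tune_k: int = 10
    tune_holdout: float = 0.25
    feature_config: mx.FeatureConfig = field(default_factory=mx.FeatureConfig)
    prune_min_pct: float = 1.0
    seed: int = 0


def _stage_rng(config: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, STAGE_SEED_OFFSET[stage]])
    )


def run_recovery(
    seed: int,
    n_presence: int = 1000,
    nrows: int = 150,
    ncols: int = 150,
    resolution: float = 1000.0,
    n_background: int = 5000,
    beta: float = 1.2,
    informative: str = "wind_uplift_1",
    extents: tuple = (1000.0, 2000.0),
    reg_multiplier: float = 1.0,
) -> dict:
    """Parameter-recovery study on a known log-linear truth surface.

    One informative covariate among four noise covariates; presence points
    are drawn from the truth intensity (the point-process view of the
    telemetry data after filtering and thinning), split 75/25, screened,
    fitted, and projected.  Returns the Spearman correlation of the fitted
    surface with the truth, the holdout (squared) Boyce index, percent
    contributions, and whether the informative covariate's base variable
    ranks first.
    """
    from scipy import stats

    sim = synthio.SimConfig(
        nrows=nrows,
        ncols=ncols,
        resolution=resolution,
        n_per_category=dict(RECOVERY_CATEGORIES),
        n_ecoregions=0,
        true_betas={informative: beta},
        seed=seed,
    )
    stack = synthio.generate_covariate_stack(sim)
    truth = synthio.true_intensity(stack, sim.true_betas)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    px, py = synthio.sample_presence_points(truth, n_presence, rng)
    n_train = int(round(0.75 * n_presence))
    perm = rng.permutation(n_presence)
    tr, te = perm[:n_train], perm[n_train:]
    train_xy = (px[tr], py[tr])
    test_xy = (px[te], py[te])

    candidates = cov.build_candidates(stack, extents, ("mean", "sd"))
    selected = cov.select_best_scale(candidates, train_xy, n_random=5000, rng=rng)
    bx, by, modeled = mx.sample_background(
        train_xy, stack.grid, buffer_km=20.0, n=n_background, rng=rng
    )
    surviving, _ = cov.vif_filter(selected, (bx, by), rng=rng)
    names = surviving.names
    X_p = surviving.sample(names, *train_xy)
    X_b = surviving.sample(names, bx, by)
    fc = mx.FeatureConfig(product=False, threshold=False, hinge=False)
    model = mx.fit(X_p, X_b, names, set(), reg_multiplier, fc)
    surface = mx.project(model, surviving, names)
    ok = surface.valid_mask & truth.valid_mask
    rho = float(stats.spearmanr(surface.data[ok], truth.data[ok]).statistic)
    table = ev.evaluate_surface(surface, test_xy)
    contrib = model.percent_contribution()
    by_base = {}
    for n, pct in contrib.items():
        base = surviving.meta(n).base
        by_base[base] = by_base.get(base, 0.0) + pct
    top_base = max(by_base, key=by_base.get)
    return {
        "spearman_rho": rho,
        "holdout_boyce": table.boyce,
        "holdout_r2": table.r2,
        "contributions": by_base,
        "informative_first": top_base == informative,
        "n_presence": n_presence,
        "eval_table": table,
        "surface": surface,
        "truth": truth,
    }


def run_pipeline(config: PipelineConfig, out_dir, resume: bool = True) -> dict:
    """Run all stages; returns a dict of headline results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crs = config.sim.crs
    results: dict = {}

    # ---- simulate -------------------------------------------------------
    sim_dir = out / "simulate"
    if resume and (sim_dir / "telemetry.csv").exists():
        stack = io.read_stack(sim_dir / "stack")
        truth_surface = io.read_raster(sim_dir / "truth_intensity.asc")
        fixes, _ = io.read_telemetry(sim_dir / "telemetry.csv", crs=crs)
        meta = pd.read_csv(sim_dir / "meta.csv", parse_dates=["tag_date"])
        truth_labels = pd.read_csv(sim_dir / "truth_individuals.csv")
    else:
        stack, truth, fixes, meta = synthio.simulate(config.sim)
        truth_surface = truth.intensity
        truth_labels = truth.individuals
        sim_dir.mkdir(exist_ok=True)
        io.write_stack(stack, sim_dir / "stack")
        io.write_raster(truth_surface, sim_dir / "truth_intensity.asc")
        io.write_telemetry(
            fixes[["deployment_id", "timestamp", "lon", "lat", "fix_type", "argos_class"]],
            sim_dir / "telemetry.csv",
        )
        meta.to_csv(sim_dir / "meta.csv", index=False)
        truth.individuals.to_csv(sim_dir / "truth_individuals.csv", index=False)
        truth.fix_labels.to_csv(sim_dir / "truth_fix_labels.csv", index=False)
        io.write_manifest(sim_dir, "simulate", {"seed": config.sim.seed},
                          {"fixes": len(fixes), "deployments": len(meta)})
        fixes, _ = io.read_telemetry(sim_dir / "telemetry.csv", crs=crs)
    grid = stack.grid
    study_mask = np.ones(grid.shape, dtype=bool)
    import shapely.geometry as sg

    study_area = sg.box(*grid.extent)

    # ---- filter: steps 1-2 ---------------------------------------------
    f1, r_cls = tm.argos_class_filter(fixes)
    f2, r_spk = tm.spike_filter(f1, config.filters.spike_rules)
    f3, r_vel = tm.velocity_filter(f2, config.filters.vmax)
    f4, r_hr = tm.hourly_subsample(f3)
    winter, summer, r_season = tm.season_daytime_filter(f4, config.filters.daytime_margin_h)
    removal_log = pd.concat([r_cls, r_spk, r_vel, r_hr, r_season])
    flt_dir = out / "filter"
    flt_dir.mkdir(exist_ok=True)
    removal_log_counts = removal_log["removal_reason"].value_counts().to_dict()
    io.write_manifest(flt_dir, "filter", {"vmax": config.filters.vmax},
                      {"in": len(fixes), "winter": len(winter), "summer": len(summer),
                       **removal_log_counts})

    # ---- classify: step 3 ----------------------------------------------
    labels, retained = lh.classify_all(winter, summer, meta, study_area, crs)
    cls_dir = out / "classify"
    cls_dir.mkdir(exist_ok=True)
    labels.to_csv(cls_dir / "labels.csv", index=False)
    results["labels"] = labels

    # ---- behavior + thinning + split: steps 4-6 -------------------------
    sedentary, r_beh = tm.behavioral_filter(retained, config.filters)
    thinned, _ = tm.thin_two_per_day(
        sedentary, _stage_rng(config, "thin"), config.filters.thin_min_separation_h
    )
    train, test = tm.train_test_split(
        thinned, config.filters.train_frac, _stage_rng(config, "split")
    )
    io.write_telemetry(train.drop(columns=[c for c in train.columns if c.endswith("_min")]),
                       flt_dir / "train.csv")
    io.write_telemetry(test.drop(columns=[c for c in test.columns if c.endswith("_min")]),
                       flt_dir / "test.csv")
    results["n_train"] = len(train)
    results["n_test"] = len(test)

    # ---- covariates -----------------------------------------------------
    train_xy = (train["x"].to_numpy(), train["y"].to_numpy())
    test_xy = (test["x"].to_numpy(), test["y"].to_numpy())
    rng_cov = _stage_rng(config, "covars")
    candidates = cov.build_candidates(stack, config.extents, config.statistics)
    selected = cov.select_best_scale(
        candidates, train_xy, n_random=config.n_random_screen, rng=rng_cov,
        area_mask=study_mask,
    )
    bx0, by0, modeled_mask = mx.sample_background(
        train_xy, grid, config.buffer_km, min(config.n_background, 20_000), rng_cov,
        area_mask=study_mask,
    )
    surviving, vif_history = cov.vif_filter(selected, (bx0, by0), config.vif_threshold,
                                            rng=rng_cov)
    cov_dir = out / "covars"
    cov_dir.mkdir(exist_ok=True)
    vif_history.to_csv(cov_dir / "vif_history.csv", index=False)
    getattr(selected, "selection_report", pd.DataFrame()).to_csv(
        cov_dir / "scale_selection.csv", index=False
    )

    # ---- model ----------------------------------------------------------
    rng_model = _stage_rng(config, "model")
    bx, by, modeled_mask = mx.sample_background(
        train_xy, grid, config.buffer_km, config.n_background, rng_model,
        area_mask=study_mask,
    )
    names = surviving.names
    categorical = {n for n in names if surviving.meta(n).categorical}
    X_bg = surviving.sample(names, bx, by)
    ok_bg = np.all(np.isfinite(X_bg), axis=1)
    X_bg = X_bg[ok_bg]

    def covariate_matrix(xy):
        M = surviving.sample(names, xy[0], xy[1])
        return M[np.all(np.isfinite(M), axis=1)]

    def eval_reg(fit_xy, hold_xy, reg):
        model = mx.fit(covariate_matrix(fit_xy), X_bg, names, categorical, reg,
                       config.feature_config)
        surf = mx.project(model, surviving, names, area_mask=modeled_mask)
        t = ev.evaluate_surface(surf, hold_xy)
        return t.r2 if np.isfinite(t.r2) else -1.0

    best_reg, tune_table = mx.tune_regularization(
        train_xy, eval_reg, config.reg_candidates, k=config.tune_k,
        holdout=config.tune_holdout, rng=rng_model,
    )
    results["reg_multiplier"] = best_reg
    results["tune_table"] = tune_table

    def fit_names(subset_names):
        sub = [names.index(n) for n in subset_names]
        return mx.fit(
            covariate_matrix(train_xy)[:, sub], X_bg[:, sub], subset_names,
            categorical & set(subset_names), best_reg, config.feature_config,
        )

    final_names, model, rounds = mx.prune_by_contribution(
        fit_names, names, config.prune_min_pct
    )
    results["final_covariates"] = final_names
    results["contributions"] = model.percent_contribution()
    mdl_dir = out / "model"
    mdl_dir.mkdir(exist_ok=True)
    (mdl_dir / "model.json").write_text(json.dumps(
        {
            "reg_multiplier": best_reg,
            "covariates": final_names,
            "contributions": results["contributions"],
            "n_features": len(model.feature_set.features),
            "coefficients": dict(zip(model.feature_set.names, model.lam.tolist())),
        },
        indent=2,
    ))

    # ---- project --------------------------------------------------------
    surface = mx.project(model, surviving, final_names, area_mask=study_mask,
                         clip_mask=study_mask)
    io.write_raster(surface, mdl_dir / "surface.asc")
    results["surface"] = surface

    # ---- evaluate -------------------------------------------------------
    table = ev.evaluate_surface(surface, test_xy)
    results["eval"] = table
    group_tables = {}
    for grp, gdf in test.groupby("group"):
        group_tables[grp] = ev.evaluate_surface(
            surface, (gdf["x"].to_numpy(), gdf["y"].to_numpy())
        )
    results["group_eval"] = group_tables
    eval_dir = out / "evaluate"
    eval_dir.mkdir(exist_ok=True)
    table.table.to_csv(eval_dir / "bins_overall.csv", index=False)
    (eval_dir / "summary.json").write_text(json.dumps(
        {
            "r2": table.r2,
            "boyce": table.boyce,
            "aaf_magnitude": table.aaf_magnitude,
            "per_group": {g: {"r2": t.r2, "boyce": t.boyce} for g, t in group_tables.items()},
        },
        indent=2,
    ))

    # ---- compare against the truth surface ------------------------------
    truth_scaled = truth_surface.data / np.nanmax(truth_surface.data)
    truth_r = Raster(grid, truth_scaled)
    results["truth_spearman"] = cmp.surface_correlation(surface, truth_r)
    results["overlap_top10"] = cmp.top_quantile_overlap(surface, truth_r, 0.10)
    if "ecoregion" in stack.names:
        mgmt = cmp.management_summary(surface, stack["ecoregion"].astype(int))
        mgmt.to_csv(out / "management_summary.csv", index=False)
        results["management"] = mgmt
    results["truth_labels"] = truth_labels
    return results
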