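"""End-to-end orchestration: simulate a campaign, clean it, fit seasonal
models, and run the two headline simulation experiments (parameter recovery
and SES-inequality recovery).

Seasonal stratification mirrors the measured contrast: separate models are
fitted for the harmattan and non-harmattan subsets of the campaign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_city as sc
from . import measurements as ms
from . import features as ft
from . import lur
from . import evaluation as ev
from . import exposure as xp


@dataclass
class Campaign:
    """Everything one simulated campaign produces."""

    seed: int
    scene: sc.CityScene
    calendar: sc.SeasonCalendar
    met: pd.DataFrame
    design: sc.SamplingDesign
    registry: ft.PredictorRegistry
    matrix: ft.PredictorMatrix  # standardized on the simulation population
    truth_pm25: sc.GroundTruth
    truth_bc: sc.GroundTruth
    raw_table: pd.DataFrame
    clean_table: pd.DataFrame


def run_campaign(
    seed: int = 0,
    scene_config: sc.SceneConfig | None = None,
    sampling_config: sc.SamplingConfig | None = None,
    met_config: sc.MetConfig | None = None,
    registry: ft.PredictorRegistry | None = None,
    truth_pm25: sc.GroundTruth | None = None,
    truth_bc: sc.GroundTruth | None = None,
    qc_sim: sc.QCSimConfig | None = None,
    qc: ms.QCConfig | None = None,
) -> Campaign:
    """Simulate a full campaign and run the measurement QC pipeline on it."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    calendar = sc.DEFAULT_CALENDAR
    scene = sc.generate_city(scene_config, seed=int(seeds[0]))
    met = sc.generate_meteorology(calendar, met_config, seed=int(seeds[1]))
    design = sc.design_sampling(scene, sampling_config, seed=int(seeds[2]))
    registry = registry or ft.default_registry()
    matrix = ft.assemble_design(scene, design, met, registry)
    matrix, _ = ft.prune_degenerate(matrix)
    matrix = ft.standardize_columns(matrix)
    truth_pm25 = truth_pm25 or sc.default_truth_pm25()
    truth_bc = truth_bc or sc.default_truth_bc()
    raw = sc.simulate_measurement_table(
        matrix.data, design, met, truth_pm25, truth_bc,
        seed=int(seeds[3]), qc=qc_sim, calendar=calendar,
    )
    clean = ms.apply_qc_pipeline(raw, qc)
    return Campaign(
        seed=seed, scene=scene, calendar=calendar, met=met, design=design,
        registry=registry, matrix=matrix, truth_pm25=truth_pm25,
        truth_bc=truth_bc, raw_table=raw, clean_table=clean,
    )


def seasonal_data(
    campaign: Campaign, response: str = "pm25", season: str | None = "non_harmattan"
) -> dict:
    """Merged analysis table for one pollutant and season.

    Returns data (predictor columns), y on the modelling scale (log for
    PM2.5), measured concentrations, and site/week id vectors.
    """
    keys = ["site_id", "week_index"]
    merged = campaign.clean_table.merge(campaign.matrix.data, on=keys, how="inner")
    if season is not None:
        merged = merged[merged["season"] == season]
    if response == "pm25":
        merged = merged[merged["pm25"].notna() & (merged["pm25"] > 0)]
        y_model = np.log(merged["pm25"].to_numpy(dtype=float))
        measured = merged["pm25"].to_numpy(dtype=float)
        resp_name = "log_pm25"
    elif response == "bc":
        merged = merged[merged["bc_absorbance"].notna()]
        y_model = merged["bc_absorbance"].to_numpy(dtype=float)
        measured = y_model.copy()
        resp_name = "bc"
    else:
        raise ValueError("response must be 'pm25' or 'bc'")
    merged = merged.reset_index(drop=True)
    return {
        "data": merged,
        "y_model": y_model,
        "measured": measured,
        "site_ids": merged["site_id"].to_numpy(),
        "week_ids": merged["week_index"].to_numpy(),
        "response": resp_name,
        "season": season,
    }


def fit_seasonal_lur(
    campaign: Campaign,
    response: str = "pm25",
    season: str = "non_harmattan",
    cfg: lur.SelectionConfig | None = None,
    spatial_only: bool = False,
    exclude_extra: set[str] | None = None,
) -> tuple[lur.FittedLUR, lur.SelectionTrace]:
    """Two-stage selection + REML fit on one season's data."""
    d = seasonal_data(campaign, response, season)
    sub = campaign.matrix.copy()
    sub.data = d["data"]
    exclude = set(exclude_extra or ())
    if spatial_only:
        exclude |= {e.name for e in campaign.registry.temporal()}
    exclude = exclude or None
    fit, trace = lur.select_lur(
        sub, d["y_model"], d["site_ids"], d["week_ids"], cfg=cfg, exclude=exclude,
        response=d["response"], season=season,
    )
    return fit, trace


# ---------------------------------------------------------------------------
# Experiment 1: parameter recovery of the generating fixed effects
# ---------------------------------------------------------------------------


def recovery_replicate(seed: int, cfg: lur.SelectionConfig | None = None) -> dict:
    """One recovery replicate on the default 10-fixed / 136-rotating design.

    Simulates the campaign from the default generating truth, runs the full
    selection on the non-harmattan subset over the spatial candidate
    inventory, and reports whether the selected variable set equals the true
    support and whether each recovered coefficient's 95 % CI covers truth.
    """
    camp = run_campaign(seed=seed)
    truth = camp.truth_pm25
    fit, trace = fit_seasonal_lur(
        camp, "pm25", "non_harmattan", cfg, spatial_only=True,
        exclude_extra={"dist_major_road", "inv_dist_major_road"},
    )
    true_cols = set(truth.beta)
    true_bases = {camp.matrix.column_meta[c].base for c in true_cols}
    selected_cols = list(fit.term_names)
    selected_bases = {camp.matrix.column_meta[c].base for c in selected_cols}
    support_ok = selected_bases == true_bases

    coverage = []
    for col, beta in truth.beta.items():
        base = camp.matrix.column_meta[col].base
        match = [c for c in selected_cols if camp.matrix.column_meta[c].base == base]
        if not match:
            continue
        c = match[0]
        lo, hi = fit.conf_int.loc[c, "lo"], fit.conf_int.loc[c, "hi"]
        coverage.append({"term": col, "selected_as": c, "beta_true": beta,
                         "beta_hat": float(fit.params[c]),
                         "covered": bool(lo <= beta <= hi)})
    return {
        "seed": seed,
        "support_recovered": support_ok,
        "selected": sorted(selected_bases),
        "true_support": sorted(true_bases),
        "coverage": coverage,
        "fit": fit,
        "trace": trace,
    }


def recovery_experiment(n_replicates: int = 20, base_seed: int = 0,
                        cfg: lur.SelectionConfig | None = None) -> dict:
    """Support-recovery rate and pooled CI coverage over seeded replicates."""
    reps = [recovery_replicate(base_seed + i, cfg) for i in range(n_replicates)]
    support_rate = float(np.mean([r["support_recovered"] for r in reps]))
    cov = [c["covered"] for r in reps for c in r["coverage"]]
    coverage_rate = float(np.mean(cov)) if cov else float("nan")
    return {
        "replicates": reps,
        "support_rate": support_rate,
        "coverage_rate": coverage_rate,
        "n_coverage_checks": len(cov),
    }


# ---------------------------------------------------------------------------
# Experiment 2: SES-inequality recovery
# ---------------------------------------------------------------------------


def inequality_replicate(seed: int, cellsize: float = 100.0) -> dict:
    """One inequality replicate on a compact scene.

    Simulates a campaign on a 6 km scene, fits the non-harmattan PM2.5 mixed
    model on the true support, predicts the non-harmattan 100 m surface,
    overlays synthetic enumeration areas whose SES is negatively coupled to
    the exposure field, and runs the quintile ANOVA.
    """
    scene_cfg = sc.SceneConfig(extent=(0.0, 0.0, 6000.0, 6000.0), n_local_roads=40)
    truth = sc.default_truth_pm25()
    needed_bases = {"ndvi", "population_density", "major_road_length",
                    "secondary_road_length"}
    registry = ft.default_registry().subset(
        needed_bases | {e.name for e in ft.default_registry().temporal()}
    )
    camp = run_campaign(seed=seed, scene_config=scene_cfg, registry=registry)
    d = seasonal_data(camp, "pm25", "non_harmattan")
    terms = list(camp.truth_pm25.beta)
    fit = lur.fit_lmm(
        d["y_model"], d["data"][terms], d["site_ids"], d["week_ids"],
        response="log_pm25", season="non_harmattan",
        standardization=camp.matrix.standardization,
    )
    template, feats = xp.compute_grid_features(camp.scene, fit, camp.registry, cellsize)
    met_season = camp.met[camp.met["season"] == "non_harmattan"]
    surf = xp.predict_surface(fit, template, feats, camp.met, camp.registry,
                              weeks=list(met_season["week_index"]))
    mean_grid = xp.Grid(surf.weekly.mean(axis=0), template.x0, template.y0,
                        template.cellsize)
    eas = sc.generate_enumeration_areas(camp.scene, seed=seed + 7)
    eas = xp.ea_mean(mean_grid, eas, value_col="mean_pm25")
    eas["quintile"] = xp.ses_quintiles(eas)
    tests = xp.inequality_tests(eas, value_col="mean_pm25")
    means = eas.groupby("quintile")["mean_pm25"].mean()
    return {
        "seed": seed,
        "q1_mean": float(means.loc[1]),
        "q5_mean": float(means.loc[5]),
        "anova_p": tests["anova_p"],
        "anova_f": tests["anova_f"],
        "eas": eas,
        "tests": tests,
    }


def inequality_experiment(n_replicates: int = 20, base_seed: int = 0) -> dict:
    reps = [inequality_replicate(base_seed + i) for i in range(n_replicates)]
    ok = [r["q1_mean"] > r["q5_mean"] and r["anova_p"] < 0.05 for r in reps]
    return {"replicates": reps, "success_rate": float(np.mean(ok))}
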