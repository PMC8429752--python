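"""End-to-end orchestration: simulate → degree-days → fit → map → meta.

Each stage writes its outputs as plain-text artifacts under the run
directory and the manifest records the config hash, seed, package
version and per-stage record counts, so a run is reproducible and
auditable from its artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import InvalidInputError
from . import io as cio
from .range_mapper import (
    annual_ltdd_grid,
    classify_overwintering,
    expansion_series,
    marginal_belt_trend,
    overwinter_area,
    survival_grid,
    warming_scenario,
)
from .resistance_meta import (
    annotate_sites,
    compute_effect_sizes,
    level_frequencies,
    mixed_model_anova,
    predict_resistance_map,
    publication_bias,
    quantile_model,
    weighted_mean_rr,
)
from .survival_models import FittedSurvivalModel, compare_models, validate_field
from .synthetic_data import (
    TruthParams,
    make_regimes,
    simulate_climate_grid,
    simulate_field_experiment,
    simulate_host_mask,
    simulate_resistance_records,
    simulate_survival_experiment,
)

log = logging.getLogger("coldrange")


def run_pipeline(config: RunConfig, truth: TruthParams = TruthParams()) -> dict:
    """Run the full synthetic-data analysis; returns the manifest dict."""
    out = cio.ensure_dir(config.out_dir)
    counts: dict[str, int] = {}
    seed = int(config.seed)
    thermal = config.thermal

    # --- stage 1: simulate inputs -------------------------------------
    regimes = make_regimes(config.n_lab_regimes, seed=seed)
    lab_obs = simulate_survival_experiment(regimes, truth, seed=seed)
    field_obs = simulate_field_experiment(truth, n_sites=config.n_field_sites, seed=seed)
    cio.write_site_series(regimes, out / "lab_regimes.csv")
    cio.write_observations(lab_obs, out / "lab_observations.csv")
    cio.write_observations(field_obs, out / "field_observations.csv")
    counts["lab_observations"] = len(lab_obs)
    counts["field_observations"] = len(field_obs)
    log.info("simulated %d lab and %d field observations", len(lab_obs), len(field_obs))

    # --- stage 2: fit and select the survival model -------------------
    ranking = compare_models(lab_obs, seed=seed)
    pd.DataFrame([
        {"predictor": m.spec.predictor, "form": m.spec.form, "aic": m.aic,
         "r2": m.r2, "rss": m.residual_ss, "n": m.n_obs, **m.coefficients}
        for m in ranking
    ]).to_csv(out / "model_ranking.csv", index=False)
    selected = ranking[0]
    (out / "selected_model.json").write_text(selected.to_json())
    validation = validate_field(selected, field_obs)
    (out / "field_validation.json").write_text(json.dumps({
        "slope": validation.slope, "intercept": validation.intercept,
        "r2": validation.r2, "n": validation.n, "bias": validation.bias,
    }, indent=2))
    counts["models_fitted"] = len(ranking)
    log.info("selected %s-%s (AIC %.1f, R2 %.3f); field R2 %.3f",
             selected.spec.predictor, selected.spec.form, selected.aic,
             selected.r2, validation.r2)

    # --- stage 3: gridded range mapping -------------------------------
    grid = simulate_climate_grid(
        n_lat=config.grid_n_lat, n_lon=config.grid_n_lon,
        year_start=config.grid_year_start, year_end=config.grid_year_end,
        truth=truth, seed=seed,
    )
    host = simulate_host_mask(grid, seed=seed)
    cio.write_grid(grid, out / "climate_grid.csv")
    cio.write_host_mask(host, grid, out / "host_mask.csv")
    baseline_year = config.grid_year_start
    final_year = config.grid_year_end

    expansion = expansion_series(grid, selected, host, baseline_year, thermal)
    expansion.to_csv(out / "expansion_series.csv", index=False)
    try:
        trend = marginal_belt_trend(grid, selected, host, baseline_year, thermal)
        trend_out = {k: v for k, v in trend.items() if k not in ("belt_mean_ltdd", "years")}
    except InvalidInputError:
        # a coarse grid may legitimately have no marginal cell in the baseline year
        trend_out = {"empty_belt": True}
        log.warning("no marginal-belt cells in baseline year %d", baseline_year)
    (out / "marginal_belt_trend.json").write_text(json.dumps(trend_out, indent=2))

    recent_years = list(range(final_year - 4, final_year + 1))
    recent_ltdd = [annual_ltdd_grid(grid, y, thermal) for y in recent_years]
    surv_now = survival_grid(recent_ltdd, selected)
    ow_now = classify_overwintering(surv_now, host, lats=grid.lats, lons=grid.lons,
                                    permanent_cutoff=config.permanent_cutoff,
                                    marginal_cutoff=config.marginal_cutoff,
                                    host_cutoff=config.host_cutoff)
    ow_now.to_frame().to_csv(out / "overwinter_map.csv", index=False)

    scen_rows = []
    for delta in (0.0,) + tuple(config.scenario_deltas):
        warmed = warming_scenario(grid, delta) if delta else grid
        s = survival_grid([annual_ltdd_grid(warmed, y, thermal) for y in recent_years],
                          selected)
        m = classify_overwintering(s, host, lats=grid.lats, lons=grid.lons,
                                   permanent_cutoff=config.permanent_cutoff,
                                   marginal_cutoff=config.marginal_cutoff,
                                   host_cutoff=config.host_cutoff)
        n5, a5 = overwinter_area(m, config.permanent_cutoff)
        n1, a1 = overwinter_area(m, config.marginal_cutoff)
        scen_rows.append({"delta_t": delta, "cells_ge5": n5, "area_ge5_km2": a5,
                          "cells_ge1": n1, "area_ge1_km2": a1})
    scenarios = pd.DataFrame(scen_rows)
    base5 = scenarios.loc[scenarios["delta_t"] == 0.0, "area_ge5_km2"].iloc[0]
    scenarios["expansion_ge5_km2"] = scenarios["area_ge5_km2"] - base5
    scenarios.to_csv(out / "warming_scenarios.csv", index=False)
    counts["grid_cells"] = int(np.prod(grid.shape))
    counts["scenario_rows"] = len(scenarios)

    # --- stage 4: resistance meta-analysis ----------------------------
    records = simulate_resistance_records(
        config.n_resistance_records, truth, grid, survival_model=selected,
        config=thermal, seed=seed,
    )
    cio.write_records(records, out / "resistance_records.csv")
    effects = compute_effect_sizes(records)
    annotated = annotate_sites(effects, grid, selected, thermal)
    annotated.to_csv(out / "effect_sizes.csv", index=False)
    counts["resistance_records"] = len(records)
    counts["records_annotated"] = len(annotated)
    counts["records_dropped_coverage"] = annotated.attrs.get("n_dropped_coverage", 0)
    counts["records_imputed_v"] = int(annotated["imputed_v"].sum())
    log.info("meta: %d records, %d imputed variances, %d dropped for coverage",
             len(annotated), counts["records_imputed_v"],
             counts["records_dropped_coverage"])

    wmeans = weighted_mean_rr(annotated)
    wmeans.rename("weighted_mean_rr").to_csv(out / "weighted_mean_rr.csv")
    level_frequencies(annotated).to_csv(out / "level_frequencies.csv")
    anova = mixed_model_anova(annotated)
    anova["table"].to_csv(out / "mixed_model_anova.csv", index=False)
    qm = quantile_model(annotated, tau=config.quantile_tau)
    (out / "quantile_model.json").write_text(json.dumps(qm, indent=2))
    final_ltdd = annual_ltdd_grid(grid, final_year, thermal)
    rmap = predict_resistance_map(qm, final_ltdd, host, grid.lats, grid.lons,
                                  host_cutoff=config.host_cutoff)
    rmap.to_csv(out / "resistance_map.csv", index=False)
    bias = publication_bias(annotated)
    (out / "publication_bias.json").write_text(json.dumps({
        "kendall_tau": bias["kendall_tau"], "p": bias["p"],
        "n": len(bias["funnel"]),
    }, indent=2))

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seed": seed,
        "counts": counts,
        "selected_model": {"predictor": selected.spec.predictor,
                           "form": selected.spec.form,
                           "coefficients": selected.coefficients},
        "field_validation_r2": validation.r2,
        "artifacts": sorted({p.name for p in out.iterdir() if p.is_file()}
                            | {"manifest.json"}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
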