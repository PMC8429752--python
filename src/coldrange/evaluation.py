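"""Self-checks of the analysis chain on synthetic ground truth.

Each function runs one study-scale simulation experiment and returns the
measured quantities (oracle discrepancies, parameter-recovery coverage,
error rates, recovered slopes).  The pytest acceptance suite asserts on
these results and the acceptance script reports them; both therefore
execute exactly the same computations.

All randomness is derived from a single integer seed via SeedSequence
spawning, so results are reproducible and the independent replicates are
genuinely independent streams.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import coldrange as cr
from .range_mapper import annual_ltdd_grid
from .synthetic_data import GridTruth, MetaTruth, SurvivalTruth, TruthParams


def _child_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), tag])
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


# ---------------------------------------------------------------- LTDD oracles

def ltdd_oracle_check(seed: int, n_series: int = 1000, n_days: int = 365) -> dict:
    """Site- and grid-level LTDD versus a scalar per-day loop.

    ``n_series`` random daily series are evaluated one by one through the
    site path and, packed as cells of one grid, through the vectorised
    grid path; both are compared with a pure-python loop oracle.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    dates = pd.date_range("2001-01-01", periods=n_days, freq="D")
    temps = rng.uniform(-25.0, 30.0, size=(n_series, n_days))

    def loop_oracle(row):
        total = 0.0
        for t in row:
            if t < 11.0:
                total += 11.0 - t
        return total

    max_site = 0.0
    for k in range(n_series):
        s = cr.DailyTemperatureSeries(f"s{k}", -10.0, 0.0, dates, temps[k])
        got = cr.ltdd(s, (dates[0], dates[-1]))
        max_site = max(max_site, abs(got - loop_oracle(temps[k])))

    # same series as cells of a southern-hemisphere grid, calendar-year window
    n_lat = 25
    n_lon = n_series // n_lat
    grid = cr.ClimateGrid(
        lats=np.linspace(-60, -10, n_lat), lons=np.arange(n_lon, dtype=float),
        dates=dates, tmean=temps[: n_lat * n_lon].reshape(n_lat, n_lon, n_days),
    )
    got_grid = annual_ltdd_grid(grid, 2001)
    oracle_grid = np.array([loop_oracle(temps[k]) for k in range(n_lat * n_lon)])
    max_grid = float(np.abs(got_grid.ravel() - oracle_grid).max())
    return {"max_site_diff": float(max_site), "max_grid_diff": max_grid,
            "n_series": n_series}


def closed_form_check(seed: int, n_cases: int = 200) -> dict:
    """Constant-series closed form, additivity and warming monotonicity."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 102]))
    max_closed = 0.0
    max_additivity = 0.0
    monotone_violations = 0
    for _ in range(n_cases):
        d = int(rng.integers(5, 200))
        t = float(rng.uniform(-20.0, 10.9))
        dates = pd.date_range("2002-01-01", periods=d, freq="D")
        s = cr.DailyTemperatureSeries("c", 0.0, 0.0, dates, np.full(d, t))
        got = cr.ltdd(s, (dates[0], dates[-1]))
        max_closed = max(max_closed, abs(got - d * (11.0 - t)))

        temps = rng.uniform(-20.0, 25.0, size=d)
        s2 = cr.DailyTemperatureSeries("r", 0.0, 0.0, dates, temps)
        whole = cr.ltdd(s2, (dates[0], dates[-1]))
        cut = int(rng.integers(1, d))
        parts = (cr.ltdd(s2, (dates[0], dates[cut - 1]))
                 + cr.ltdd(s2, (dates[cut], dates[-1])))
        max_additivity = max(max_additivity, abs(whole - parts))

        delta = float(rng.uniform(0.0, 5.0))
        s3 = cr.DailyTemperatureSeries("w", 0.0, 0.0, dates, temps + delta)
        if cr.ltdd(s3, (dates[0], dates[-1])) > whole + 1e-9:
            monotone_violations += 1
    return {"max_closed_form_err": float(max_closed),
            "max_additivity_err": float(max_additivity),
            "monotonicity_violations": monotone_violations,
            "n_cases": n_cases}


# ------------------------------------------------- survival model recovery

def survival_recovery(seed: int, n_reps: int = 100) -> dict:
    """Parameter recovery and model selection at the chamber design scale.

    Per replicate: 10 regimes x 11 sampling points x two stages (55 and
    65 individuals) = 220 binomial observations from S = a exp(b LTDD);
    the exponential-LTDD fit's 95% Wald intervals are checked against
    the truth and the nine-model AIC ranking is recorded.
    """
    truth = TruthParams()
    regimes = cr.make_regimes(10, seed=seed)
    a_true, b_true = truth.survival.a, truth.survival.b
    cover_a = cover_b = cover_joint = rank1 = 0
    a_hats, b_hats, r2s = [], [], []
    for rep_seed in _child_seeds(seed, n_reps, 103):
        obs = cr.simulate_survival_experiment(regimes, truth, seed=rep_seed)
        fit = cr.fit_survival_model(obs, cr.ModelSpec("LTDD", "exponential"),
                                    seed=rep_seed)
        a_hat, b_hat = fit.coefficients["a"], fit.coefficients["b"]
        se_a, se_b = fit.coef_se["a"], fit.coef_se["b"]
        in_a = abs(a_hat - a_true) <= 1.96 * se_a
        in_b = abs(b_hat - b_true) <= 1.96 * se_b
        cover_a += in_a
        cover_b += in_b
        cover_joint += in_a and in_b
        a_hats.append(a_hat)
        b_hats.append(b_hat)
        r2s.append(fit.r2)
        ranking = cr.compare_models(obs, seed=rep_seed)
        best = ranking[0].spec
        rank1 += (best.predictor, best.form) == ("LTDD", "exponential")
    return {
        "n_reps": n_reps,
        "coverage_a_pct": 100.0 * cover_a / n_reps,
        "coverage_b_pct": 100.0 * cover_b / n_reps,
        "coverage_joint_pct": 100.0 * cover_joint / n_reps,
        "exp_ltdd_rank1_pct": 100.0 * rank1 / n_reps,
        "mean_a": float(np.mean(a_hats)),
        "mean_b": float(np.mean(b_hats)),
        "mean_lab_r2": float(np.mean(r2s)),
    }


def field_validation_check(seed: int) -> dict:
    """Lab-fitted model against independent synthetic field observations.

    The exponential-LTDD model fitted to one chamber experiment predicts
    binomial field data generated from its own law at the field design
    (12 sites, 4 monthly samples, 30 individuals per cage); OLS of
    observed on predicted summarises predictive skill.
    """
    truth = TruthParams()
    regimes = cr.make_regimes(10, seed=seed)
    lab = cr.simulate_survival_experiment(regimes, truth, seed=seed + 1)
    model = cr.fit_survival_model(lab, cr.ModelSpec("LTDD", "exponential"), seed=0)
    fitted_truth = TruthParams(survival=SurvivalTruth(
        a=min(model.coefficients["a"], 1.0), b=min(model.coefficients["b"], 0.0)))
    field = cr.simulate_field_experiment(fitted_truth, n_sites=12, seed=seed + 2)
    res = cr.validate_field(model, field)
    return {
        "slope": res.slope,
        "slope_ci_lo": res.slope - 1.96 * res.slope_stderr,
        "slope_ci_hi": res.slope + 1.96 * res.slope_stderr,
        "r2": res.r2,
        "bias": res.bias,
        "n": res.n,
        "lab_r2": model.r2,
    }


# ----------------------------------------------------- effect-size chain

def effect_chain_check(seed: int, n_records: int = 500) -> dict:
    """Hand-composed effect-size chain and variance convergence."""
    truth = TruthParams()
    grid = cr.simulate_climate_grid(6, 4, 2000, 2008, truth=truth, seed=seed)
    recs = cr.simulate_resistance_records(n_records, truth, grid=grid,
                                          missing_ci_frac=0.0, seed=seed)
    max_err = 0.0
    vs = []
    for r in recs:
        se_f = cr.se_from_ci(r.ci_field)
        se_s = cr.se_from_ci(r.ci_susceptible)
        v_hand = (se_f**2 / (r.n_field * r.lc50_field**2)
                  + se_s**2 / (r.n_susceptible * r.lc50_susceptible**2))
        e = cr.effect_size(r, cr.pooled_variance(r))
        max_err = max(max_err,
                      abs(e.v - v_hand),
                      abs(e.w - 1.0 / np.sqrt(v_hand)),
                      abs(e.wlog_rr - np.log(r.rr) / np.sqrt(v_hand)))
        vs.append(e.v)
    expected_mean_v = truth.meta.measurement_v * float(np.exp(0.3**2 / 2))
    return {"max_chain_err": float(max_err),
            "mean_pooled_v": float(np.mean(vs)),
            "expected_mean_v": expected_mean_v,
            "n_records": n_records}


# -------------------------------------------------------- meta-analysis

def _recovery_truth() -> TruthParams:
    """Ground truth for fold-change recovery: the overwintering contrast
    is the only systematic effect so the group ratio is identifiable."""
    return TruthParams(meta=MetaTruth(etdd_slope=0.0, pesticide_sd=0.0,
                                      site_year_sd=0.4, residual_sd=0.8))


def fold_change_recovery(seed: int, n_reps: int = 6, n_records: int = 400) -> dict:
    """Weighted-mean RR ratio permanent/transient versus the injected fold."""
    truth = _recovery_truth()
    true_log_fold = truth.meta.ow_log_effect["permanent"] - truth.meta.ow_log_effect["transient"]
    grid = cr.simulate_climate_grid(8, 5, 2000, 2010, truth=truth, seed=seed)
    model = cr.FittedSurvivalModel(cr.ModelSpec("LTDD", "exponential"),
                                   {"a": 0.9, "b": -0.005}, 1.0, 0.0, 220, 0.0)
    log_folds = []
    for rep_seed in _child_seeds(seed, n_reps, 104):
        recs = cr.simulate_resistance_records(n_records, truth, grid=grid,
                                              survival_model=model, seed=rep_seed)
        ann = cr.annotate_sites(cr.compute_effect_sizes(recs), grid, model)
        means = cr.weighted_mean_rr(ann)
        if {"permanent", "transient"} <= set(means.index):
            log_folds.append(float(np.log(means["permanent"] / means["transient"])))
    log_folds = np.asarray(log_folds)
    return {
        "n_reps": len(log_folds),
        "true_fold": float(np.exp(true_log_fold)),
        "recovered_fold": float(np.exp(log_folds.mean())),
        "log_fold_mean": float(log_folds.mean()),
        "log_fold_se": float(log_folds.std(ddof=1) / np.sqrt(len(log_folds))),
        "true_log_fold": true_log_fold,
    }


def _meta_sim_frame(truth, grid, model, n_records, rep_seed):
    recs = cr.simulate_resistance_records(n_records, truth, grid=grid,
                                          survival_model=model, seed=rep_seed,
                                          n_pesticides=5, records_per_site_year=3)
    return cr.annotate_sites(cr.compute_effect_sizes(recs), grid, model)


def mixed_model_error_rates(seed: int, n_null: int = 200, n_power: int = 100,
                            n_records: int = 720) -> dict:
    """Type-I error under a null overwintering effect, and power under the
    default (large) injected contrast, for the mixed-model Wald test.

    The simulated design keeps many site-year groups (about n/3), as in
    the study-scale data, so the asymptotic Wald test is well calibrated.
    """
    model = cr.FittedSurvivalModel(cr.ModelSpec("LTDD", "exponential"),
                                   {"a": 0.9, "b": -0.005}, 1.0, 0.0, 220, 0.0)
    null_truth = TruthParams(meta=MetaTruth(
        ow_log_effect={"transient": 0.0, "marginal": 0.0, "permanent": 0.0},
        etdd_slope=3e-4, pesticide_sd=1.0, site_year_sd=0.4, residual_sd=0.8))
    alt_truth = TruthParams(meta=MetaTruth(
        etdd_slope=3e-4, pesticide_sd=1.0, site_year_sd=0.4, residual_sd=0.8))
    grid = cr.simulate_climate_grid(8, 5, 2000, 2010, seed=seed)

    def ow_p(truth, rep_seed):
        df = _meta_sim_frame(truth, grid, model, n_records, rep_seed)
        if df["ow_type"].nunique() < 2:
            return None
        res = cr.mixed_model_anova(df)
        return float(res["table"].set_index("source").loc["overwintering type", "p"])

    null_p = [p for s in _child_seeds(seed, n_null, 105) if (p := ow_p(null_truth, s)) is not None]
    power_p = [p for s in _child_seeds(seed, n_power, 106) if (p := ow_p(alt_truth, s)) is not None]
    return {
        "type_i_rate": float(np.mean([p < 0.05 for p in null_p])),
        "n_null": len(null_p),
        "power": float(np.mean([p < 0.05 for p in power_p])),
        "n_power": len(power_p),
    }


# ------------------------------------------------------ quantile regression

def quantile_recovery(seed: int, n_reps: int = 8, n_records: int = 400,
                      tau: float = 0.85) -> dict:
    """0.85-quantile slope recovery under heteroscedastic synthetic records.

    ln RR = mu + ltdd_slope*LTDD + eps, sd(eps) = s0 + s1*LTDD, so the
    tau-quantile of log10 RR is linear in LTDD with slope
    (ltdd_slope + z_tau * s1) / ln 10.
    """
    s0, s1, beta = 0.5, 2e-4, -8e-4
    truth = TruthParams(meta=MetaTruth(
        ow_log_effect={"transient": 0.0, "marginal": 0.0, "permanent": 0.0},
        etdd_slope=0.0, pesticide_sd=0.0, site_year_sd=0.0,
        residual_sd=s0, het_ltdd_sd_slope=s1, ltdd_slope=beta))
    z_tau = float(stats.norm.ppf(tau))
    true_slope = (beta + z_tau * s1) / np.log(10.0)
    grid = cr.simulate_climate_grid(8, 5, 2000, 2010, seed=seed,
                                    truth=TruthParams(grid=GridTruth(noise_sd=1.0)))
    model = cr.FittedSurvivalModel(cr.ModelSpec("LTDD", "exponential"),
                                   {"a": 0.9, "b": -0.005}, 1.0, 0.0, 220, 0.0)
    slopes = []
    for rep_seed in _child_seeds(seed, n_reps, 107):
        recs = cr.simulate_resistance_records(n_records, truth, grid=grid,
                                              survival_model=model, seed=rep_seed)
        ann = cr.annotate_sites(cr.compute_effect_sizes(recs), grid, model)
        slopes.append(cr.quantile_model(ann, tau=tau)["slope"])
    slopes = np.asarray(slopes)
    return {
        "true_slope": float(true_slope),
        "slope_mean": float(slopes.mean()),
        "slope_se": float(slopes.std(ddof=1) / np.sqrt(len(slopes))),
        "n_reps": n_reps,
    }


def median_regression_oracle_check(seed: int, n: int = 50) -> dict:
    """tau = 0.5 versus a brute-force L1 line (all point-pair candidates)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 108]))
    x = rng.uniform(0, 1000, size=n)
    y = 2.0 - 0.001 * x + 0.4 * rng.standard_t(df=4, size=n)
    df = pd.DataFrame({"rr": 10.0**y, "ltdd_5yr": x})
    res = cr.quantile_model(df, tau=0.5)
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if x[i] == x[j]:
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            intercept = y[i] - slope * x[i]
            best = min(best, float(np.abs(y - intercept - slope * x).sum()))
    got = float(np.abs(y - res["intercept"] - res["slope"] * x).sum())
    return {"l1_objective": got, "l1_objective_bruteforce": best,
            "objective_gap": got - best, "n": n}


# ------------------------------------------------------------ classification

def classification_edges() -> dict:
    """Boundary behaviour of the overwintering and resistance classes."""
    host = cr.HostMask(np.ones((1, 3)))
    ow = cr.classify_overwintering(np.array([[0.009, 0.01, 0.05]]), host)
    ow_ok = list(ow.labels()[0]) == ["transient", "marginal", "permanent"]
    rr_ok = [cr.classify_resistance(v) for v in (1.0, 10.0, 100.0, 1000.0)] == \
        ["susceptible", "moderate", "high", "extremely_high"]
    return {"overwinter_edges_ok": int(ow_ok), "resistance_edges_ok": int(rr_ok)}
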