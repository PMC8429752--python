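"""Weighted meta-analysis of pesticide-resistance bioassays.

Each record is one leaf-dip bioassay comparing a field population's
LC50 to a susceptible reference; the resistance ratio RR = LC50_field /
LC50_susceptible.  Effect sizes follow the log response-ratio
convention: logRR = ln RR, with pooled variance

    V = SE_f^2 / (n_f * LC50_f^2) + SE_s^2 / (n_s * LC50_s^2),

SE recovered from a 95% CI as (upper - lower) / (2 * 1.96), weight
w = 1 / sqrt(V) and weighted effect wlogRR = logRR * w.  Records lacking
a CI or LC50 get the mean variance of complete records (prognostic
imputation).

Sites are annotated with 5-year mean LTDD, ETDD and modelled winter
survival, then classified permanent / marginal / transient.  The
overwintering effect on wlogRR is tested by a linear mixed model
(pesticide and overwintering type fixed, ETDD covariate, two-way
interactions, site x year random intercept) with Wald chi-square tests;
the geography of high resistance comes from a 0.85-quantile regression
of log10 RR on LTDD, and publication bias is screened with a funnel
plot plus Kendall rank correlation of effect size against study size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree_days import ThermalConfig
from .errors import InvalidInputError
from .range_mapper import (
    ClimateGrid,
    HostMask,
    MARGINAL_CUTOFF,
    PERMANENT_CUTOFF,
    HOST_CUTOFF,
    annual_ltdd_grid,
)
from .survival_models import FittedSurvivalModel

__all__ = [
    "RESISTANCE_LEVELS",
    "ResistanceRecord",
    "EffectSize",
    "se_from_ci",
    "pooled_variance",
    "impute_variance",
    "effect_size",
    "compute_effect_sizes",
    "classify_resistance",
    "annotate_sites",
    "weighted_mean_rr",
    "level_frequencies",
    "mixed_model_anova",
    "quantile_model",
    "predict_resistance_map",
    "publication_bias",
]

RESISTANCE_LEVELS = (
    "susceptible",        # RR <= 1
    "low",                # 1 < RR < 10
    "moderate",           # 10 <= RR < 100
    "high",               # 100 <= RR < 1000
    "extremely_high",     # RR >= 1000
)


@dataclass
class ResistanceRecord:
    """One bioassay entry from the resistance literature."""

    pesticide: str
    moa_group: str
    latitude: float
    longitude: float
    year: int
    rr: float
    lc50_field: float | None = None
    lc50_susceptible: float | None = None
    ci_field: tuple | None = None
    ci_susceptible: tuple | None = None
    n_field: float | None = None
    n_susceptible: float | None = None

    def __post_init__(self) -> None:
        if not (self.rr > 0):
            raise InvalidInputError("resistance ratio must be > 0")
        for ci in (self.ci_field, self.ci_susceptible):
            if ci is not None and ci[1] < ci[0]:
                raise InvalidInputError("CI upper limit below lower limit")
        for n in (self.n_field, self.n_susceptible):
            if n is not None and n <= 0:
                raise InvalidInputError("bioassay counts must be > 0")


@dataclass
class EffectSize:
    """logRR effect size with its weight."""

    log_rr: float
    v: float
    w: float
    wlog_rr: float
    imputed_v: bool = False


def se_from_ci(ci) -> float:
    """Standard error from a 95% confidence interval: (upper - lower) / 3.92."""
    lower, upper = float(ci[0]), float(ci[1])
    if upper < lower:
        raise InvalidInputError("inverted confidence interval")
    return (upper - lower) / (2.0 * 1.96)


def pooled_variance(record: ResistanceRecord) -> float:
    """Pooled variance of logRR from both populations' LC50 uncertainty.

    Returns NaN (a missing-variance signal for :func:`impute_variance`)
    when any ingredient — either CI, LC50 or sample size — is absent.
    """
    needed = (record.ci_field, record.ci_susceptible, record.lc50_field,
              record.lc50_susceptible, record.n_field, record.n_susceptible)
    if any(x is None for x in needed):
        return float("nan")
    if record.lc50_field <= 0 or record.lc50_susceptible <= 0:
        raise InvalidInputError("LC50 values must be > 0")
    se_f = se_from_ci(record.ci_field)
    se_s = se_from_ci(record.ci_susceptible)
    return (
        se_f**2 / (record.n_field * record.lc50_field**2)
        + se_s**2 / (record.n_susceptible * record.lc50_susceptible**2)
    )


def impute_variance(variances) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing (NaN) variances with the mean of complete entries.

    Returns (filled variances, imputed flags); raises if no entry is
    complete.
    """
    v = np.asarray(variances, dtype=float)
    missing = np.isnan(v)
    complete = v[~missing]
    if complete.size == 0:
        raise InvalidInputError("no complete entries to impute variance from")
    out = v.copy()
    out[missing] = complete.mean()
    return out, missing


def _floor_variance(v: np.ndarray, imputed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Floor zero variances at the 1st percentile of positive complete values.

    Zero-width CIs would otherwise give infinite weight; floored entries
    are flagged alongside imputed ones.
    """
    positive = v[(v > 0) & ~imputed]
    floored = np.zeros_like(imputed)
    if (v <= 0).any():
        if positive.size == 0:
            raise InvalidInputError("all variances are zero; weights undefined")
        floor = float(np.percentile(positive, 1))
        floored = v <= 0
        v = np.where(floored, floor, v)
    return v, floored


def effect_size(record: ResistanceRecord, v: float, imputed: bool = False) -> EffectSize:
    """logRR, weight 1/sqrt(v) and weighted effect for one record."""
    if not (record.rr > 0):
        raise InvalidInputError("resistance ratio must be > 0")
    if not (v > 0):
        raise InvalidInputError("variance must be > 0 (impute or floor first)")
    log_rr = math.log(record.rr)
    w = 1.0 / math.sqrt(v)
    return EffectSize(log_rr=log_rr, v=v, w=w, wlog_rr=log_rr * w, imputed_v=imputed)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "record_id": i, "pesticide": r.pesticide, "moa_group": r.moa_group,
            "lat": r.latitude, "lon": r.longitude, "year": r.year, "rr": r.rr,
        })
    return pd.DataFrame(rows)


def compute_effect_sizes(records) -> pd.DataFrame:
    """Effect-size table for a record list: logRR, V, w, wlogRR, flags.

    Pipeline order: pooled variance per record, prognostic imputation of
    missing variances, flooring of zero variances, then weights.
    """
    records = list(records)
    df = records_to_frame(records)
    raw_v = np.array([pooled_variance(r) for r in records])
    v, imputed = impute_variance(raw_v)
    v, floored = _floor_variance(v, imputed)
    effects = [effect_size(r, vi, bool(im)) for r, vi, im in zip(records, v, imputed)]
    df["log_rr"] = [e.log_rr for e in effects]
    df["v"] = [e.v for e in effects]
    df["w"] = [e.w for e in effects]
    df["wlog_rr"] = [e.wlog_rr for e in effects]
    df["imputed_v"] = imputed
    df["floored_v"] = floored
    df["n_field"] = [r.n_field for r in records]
    df["level"] = [classify_resistance(r.rr) for r in records]
    return df


def classify_resistance(rr: float) -> str:
    """Five-level resistance class with the conventional RR boundaries.

    susceptible RR <= 1; low 1 < RR < 10; moderate 10 <= RR < 100;
    high 100 <= RR < 1000; extremely_high RR >= 1000.
    """
    if not (rr > 0):
        raise InvalidInputError("resistance ratio must be > 0")
    if rr <= 1:
        return "susceptible"
    if rr < 10:
        return "low"
    if rr < 100:
        return "moderate"
    if rr < 1000:
        return "high"
    return "extremely_high"


def annotate_sites(
    df: pd.DataFrame,
    grid: ClimateGrid,
    model: FittedSurvivalModel,
    config: ThermalConfig = ThermalConfig(),
    n_years: int = 5,
) -> pd.DataFrame:
    """Attach 5-year climate annotations and overwintering type per record.

    For each record the ``n_years`` annual windows preceding the sample
    year give mean LTDD, mean calendar-year ETDD, and mean modelled
    winter survival at the nearest grid cell; the survival mean sets
    ow_type by the permanent / marginal / transient cutoffs.  Records
    whose windows are not covered by the grid are dropped with a count
    in ``df.attrs['n_dropped_coverage']``.
    """
    from .range_mapper import annual_etdd_grid
    from .errors import CoverageError

    out = df.copy()
    years_needed = range(int(out["year"].min()) - n_years, int(out["year"].max()))
    ltdd_by_year: dict[int, np.ndarray] = {}
    etdd_by_year: dict[int, np.ndarray] = {}
    for y in years_needed:
        try:
            ltdd_by_year[y] = annual_ltdd_grid(grid, y, config)
            etdd_by_year[y] = annual_etdd_grid(grid, y, config)
        except CoverageError:
            continue

    cols = {"ltdd_5yr": [], "etdd_5yr": [], "winter_survival_5yr": [], "ow_type": []}
    keep = []
    cache: dict[tuple, tuple] = {}
    for _, row in out.iterrows():
        i, j = grid.nearest_cell(row["lat"], row["lon"])
        key = (i, j, int(row["year"]))
        if key not in cache:
            years = range(int(row["year"]) - n_years, int(row["year"]))
            if all(y in ltdd_by_year and y in etdd_by_year for y in years):
                ltdds = [float(ltdd_by_year[y][i, j]) for y in years]
                etdds = [float(etdd_by_year[y][i, j]) for y in years]
                surv = float(np.mean([model.predict({"LTDD": l}) for l in ltdds]))
                if surv >= PERMANENT_CUTOFF:
                    ow = "permanent"
                elif surv >= MARGINAL_CUTOFF:
                    ow = "marginal"
                else:
                    ow = "transient"
                cache[key] = (float(np.mean(ltdds)), float(np.mean(etdds)), surv, ow)
            else:
                cache[key] = None
        ann = cache[key]
        keep.append(ann is not None)
        if ann is None:
            continue
        for c, v in zip(cols, ann):
            cols[c].append(v)
    out = out.loc[np.asarray(keep)].reset_index(drop=True)
    for c, v in cols.items():
        out[c] = v
    out["site_year"] = (
        out["lat"].round(3).astype(str) + "_" + out["lon"].round(3).astype(str)
        + "_" + out["year"].astype(int).astype(str)
    )
    out.attrs["n_dropped_coverage"] = int(len(keep) - sum(keep))
    return out


def weighted_mean_rr(df: pd.DataFrame, group: str = "ow_type") -> pd.Series:
    """Weighted mean resistance ratio per group.

    The mean is taken on the log scale with weights w and exponentiated
    (a weighted geometric mean), consistent with logRR effect sizes.
    Empty groups are simply absent from the result.
    """
    def back_transform(g: pd.DataFrame) -> float:
        return float(np.exp(np.sum(g["w"] * g["log_rr"]) / np.sum(g["w"])))

    return df.groupby(group).apply(back_transform, include_groups=False)


def level_frequencies(df: pd.DataFrame, group: str = "ow_type") -> pd.DataFrame:
    """Per-group proportions of the five resistance levels (rows sum to 1)."""
    freq = (
        df.groupby(group)["level"].value_counts(normalize=True).unstack(fill_value=0.0)
    )
    for level in RESISTANCE_LEVELS:
        if level not in freq.columns:
            freq[level] = 0.0
    return freq[list(RESISTANCE_LEVELS)]


def _dummies(values: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment-coded dummies, first level as reference, deterministic order."""
    levels = sorted(values.unique())
    return pd.DataFrame(
        {f"{prefix}[{lv}]": (values == lv).astype(float) for lv in levels[1:]},
        index=values.index,
    )


def mixed_model_anova(
    df: pd.DataFrame,
    response: str = "wlog_rr",
    reml: bool = True,
) -> dict:
    """Mixed-model Wald chi-square table for the overwintering analysis.

    Fixed effects: overwintering type, pesticide, ETDD, and the
    pesticide x overwintering-type and ETDD x pesticide interactions;
    random intercept for site x year.  Each term is tested by a Wald
    chi-square on its coefficient block using the REML fit's covariance
    (the three-way interaction is excluded as rank deficient in designs
    like these).  Interaction columns that are empty or collinear in the
    realised design are dropped; the dropped count is reported.

    Returns {'table': DataFrame(source, chi2, df, p), 'converged': bool,
    'n': int, 'n_dropped_columns': int}.
    """
    import statsmodels.api as sm
    from scipy.stats import chi2 as chi2_dist

    needed = {response, "ow_type", "pesticide", "etdd_5yr", "site_year"}
    if not needed <= set(df.columns):
        raise InvalidInputError(f"missing columns: {needed - set(df.columns)}")
    for col in ("ow_type", "pesticide"):
        if df[col].nunique() < 2:
            raise InvalidInputError(f"fixed factor {col} needs >= 2 levels")

    y = df[response].to_numpy(dtype=float)
    etdd_c = df["etdd_5yr"].to_numpy(dtype=float)
    etdd_c = (etdd_c - etdd_c.mean()) / (etdd_c.std() or 1.0)  # scale for stable optimisation
    ow = _dummies(df["ow_type"], "ow")
    pest = _dummies(df["pesticide"], "pest")

    blocks: list[tuple[str, pd.DataFrame]] = [
        ("overwintering type", ow),
        ("pesticide variety", pest),
        ("ETDD", pd.DataFrame({"etdd": etdd_c}, index=df.index)),
    ]
    inter_pw = {}
    for oc in ow.columns:
        for pc in pest.columns:
            inter_pw[f"{pc}:{oc}"] = pest[pc] * ow[oc]
    blocks.append(("pesticide variety:overwintering type", pd.DataFrame(inter_pw, index=df.index)))
    inter_ep = {f"etdd:{pc}": etdd_c * pest[pc] for pc in pest.columns}
    blocks.append(("ETDD:pesticide variety", pd.DataFrame(inter_ep, index=df.index)))

    X = pd.concat([pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)]
                  + [b for _, b in blocks], axis=1)
    n_candidate = X.shape[1]
    # drop empty/collinear columns (never from the main effects)
    protected = {"Intercept"} | set(ow.columns) | set(pest.columns) | {"etdd"}
    keep_cols = [c for c in X.columns if c in protected or X[c].abs().sum() > 0]
    _, r = np.linalg.qr(X[keep_cols].to_numpy())
    diag = np.abs(np.diag(r))
    independent = diag > 1e-8 * max(diag.max(), 1.0)
    keep_cols = [c for c, ok in zip(keep_cols, independent) if ok or c in protected]
    X = X[keep_cols]
    n_dropped = n_candidate - len(keep_cols)

    groups = df["site_year"].to_numpy()
    model = sm.MixedLM(y, X.to_numpy(), groups=groups)
    import warnings

    result, converged = None, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "cg"):
            try:
                candidate = model.fit(reml=reml, method=method, maxiter=400)
            except Exception:
                continue
            result = candidate
            converged = bool(getattr(candidate, "converged", True))
            if converged:
                break
        if result is None:
            # singular fit: report OLS fixed effects with a diagnostic flag
            result = sm.OLS(y, X.to_numpy()).fit()

    params = np.asarray(result.params)[: X.shape[1]]
    cov = np.asarray(result.cov_params())[: X.shape[1], : X.shape[1]]
    col_index = {c: k for k, c in enumerate(X.columns)}

    rows = []
    for name, blk in blocks:
        idx = [col_index[c] for c in blk.columns if c in col_index]
        if not idx:
            rows.append({"source": name, "chi2": np.nan, "df": 0, "p": np.nan})
            continue
        b = params[idx]
        V = cov[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            stat = float(b @ np.linalg.pinv(V) @ b)
        rows.append({
            "source": name, "chi2": stat, "df": len(idx),
            "p": float(chi2_dist.sf(stat, len(idx))),
        })
    return {
        "table": pd.DataFrame(rows),
        "converged": converged,
        "n": len(df),
        "n_dropped_columns": int(max(n_dropped, 0)),
    }


def quantile_model(df: pd.DataFrame, tau: float = 0.85) -> dict:
    """Linear quantile regression of log10(RR) on 5-year LTDD.

    Returns slope, intercept and the slope's two-sided t-test p-value;
    the 0.85 quantile targets the top 15% of resistance levels.
    """
    if not 0 < tau < 1:
        raise InvalidInputError("tau must be in (0, 1)")
    sub = df.dropna(subset=["ltdd_5yr", "rr"])
    if len(sub) < 10:
        raise InvalidInputError("need >= 10 records with finite LTDD")
    import statsmodels.api as sm

    y = np.log10(sub["rr"].to_numpy(dtype=float))
    x = sub["ltdd_5yr"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate design: constant LTDD")
    X = sm.add_constant(x)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, X).fit(q=tau)
    return {
        "tau": tau,
        "intercept": float(res.params[0]),
        "slope": float(res.params[1]),
        "p_slope": float(res.pvalues[1]),
        "n": len(sub),
    }


def predict_resistance_map(
    qmodel: dict,
    ltdd_grid: np.ndarray,
    host_mask: HostMask,
    lats: np.ndarray,
    lons: np.ndarray,
    host_cutoff: float = HOST_CUTOFF,
) -> pd.DataFrame:
    """Top-quantile log10 RR surface over host-suitable cells.

    Cell value = intercept + slope * LTDD; cells with host presence
    probability below the cutoff are zeroed and excluded from the output
    (no host, no resistance problem).
    """
    ltdd_grid = np.asarray(ltdd_grid, dtype=float)
    if host_mask.presence_prob.shape != ltdd_grid.shape:
        raise InvalidInputError("host mask geometry does not match LTDD grid")
    values = qmodel["intercept"] + qmodel["slope"] * ltdd_grid
    values = np.where(host_mask.presence_prob >= host_cutoff, values, 0.0)
    ii, jj = np.nonzero(values != 0.0)
    return pd.DataFrame({
        "lat": np.asarray(lats, dtype=float)[ii],
        "lon": np.asarray(lons, dtype=float)[jj],
        "log10_rr_top": values[ii, jj],
    })


def publication_bias(df: pd.DataFrame) -> dict:
    """Funnel-plot screen: Kendall tau of logRR against bioassay sample size.

    A correlation between effect size and study size suggests selective
    reporting.  Returns tau, its two-sided p, and the funnel table.
    """
    sub = df.dropna(subset=["log_rr", "n_field"])
    if len(sub) < 10:
        raise InvalidInputError("need >= 10 records with sample sizes")
    from scipy.stats import kendalltau

    x = sub["log_rr"].to_numpy(dtype=float)
    n = sub["n_field"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(n) == 0:
        return {"kendall_tau": float("nan"), "p": float("nan"),
                "funnel": sub[["log_rr", "n_field"]].reset_index(drop=True),
                "degenerate": True}
    tau, p = kendalltau(x, n)
    return {"kendall_tau": float(tau), "p": float(p),
            "funnel": sub[["log_rr", "n_field"]].reset_index(drop=True),
            "degenerate": False}
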