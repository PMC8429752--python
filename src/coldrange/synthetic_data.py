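"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study designs the package
is built around, at configurable scale:

* chamber-style winter temperature regimes — piecewise-linear decline /
  hold / rise profiles stepped every 10 days across a latitudinal
  cold gradient (November–April, ~180 days);
* a survival experiment sampling two stages every 10 days from each
  regime, with binomial survival under a known exponential-LTDD law;
* a small lat/lon climate grid with latitudinal gradient, seasonal
  cycle (hemisphere-correct phase), linear warming trend and daily
  noise, plus a smooth host-presence field;
* resistance records whose ln RR is built from known overwintering-type
  effects, pesticide effects, an ETDD slope, site x year random effects
  and residual noise, with LC50s and 95% CIs constructed so the pooled
  variance chain recovers the generating variance exactly.

Everything is reproducible from (parameters, seed); a single seed is
split into independent per-generator streams.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .degree_days import DailyTemperatureSeries, ThermalConfig
from .errors import InvalidInputError
from .range_mapper import ClimateGrid, HostMask, MARGINAL_CUTOFF, PERMANENT_CUTOFF
from .resistance_meta import ResistanceRecord
from .survival_models import FittedSurvivalModel, SurvivalObservation

__all__ = [
    "SurvivalTruth",
    "MetaTruth",
    "GridTruth",
    "TruthParams",
    "RegimeSpec",
    "make_regimes",
    "simulate_survival_experiment",
    "simulate_field_experiment",
    "simulate_climate_grid",
    "simulate_host_mask",
    "simulate_resistance_records",
]


@dataclass(frozen=True)
class SurvivalTruth:
    """S = a * exp(b * LTDD): survival ~0.9 at zero cold load, decaying
    over an LTDD range of roughly 0–1500 degC·day."""

    a: float = 0.9
    b: float = -0.005

    def __post_init__(self) -> None:
        if not (0 < self.a <= 1):
            raise InvalidInputError("a must be in (0, 1]")
        if self.b > 0:
            raise InvalidInputError("b must be <= 0")


@dataclass(frozen=True)
class MetaTruth:
    """Generating parameters for resistance records.

    ow_log_effect holds additive ln-RR shifts per overwintering type;
    defaults put permanent sites ~158-fold above transient and ~5-fold
    above marginal on the ratio scale.  measurement_v is the per-record
    sampling variance of logRR implied by the constructed CIs.
    """

    mu: float = 0.5
    ow_log_effect: dict = dc_field(default_factory=lambda: {
        "transient": 0.0,
        "marginal": float(np.log(158.0 / 5.0)),
        "permanent": float(np.log(158.0)),
    })
    pesticide_sd: float = 1.5
    etdd_slope: float = 5e-4
    ltdd_slope: float = 0.0  # optional direct ln-RR trend in 5-yr LTDD
    site_year_sd: float = 0.5
    residual_sd: float = 1.0
    measurement_v: float = 0.04
    het_ltdd_sd_slope: float = 0.0  # extra residual sd per degC·day of LTDD


@dataclass(frozen=True)
class GridTruth:
    """Idealised climate: T = equator temp - gradient*|lat| + a static
    per-cell offset (continentality/elevation) + seasonal cycle (phase
    flipped across the equator) + linear warming + daily noise."""

    equator_temp: float = 27.0
    lat_gradient: float = 0.6
    cell_offset_sd: float = 2.0
    seasonal_base: float = 2.0
    seasonal_per_lat: float = 0.3
    warming_per_year: float = 0.03
    noise_sd: float = 1.5


@dataclass(frozen=True)
class TruthParams:
    survival: SurvivalTruth = SurvivalTruth()
    meta: MetaTruth = MetaTruth()
    grid: GridTruth = GridTruth()


@dataclass(frozen=True)
class RegimeSpec:
    """Piecewise-linear winter regime: (days, start degC, end degC) pieces."""

    site_label: str
    segments: tuple
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d, _, _ in self.segments):
            raise InvalidInputError("segment lengths must be > 0")


def _regime_daily_temps(spec: RegimeSpec, step_days: int = 10) -> np.ndarray:
    """Daily temperatures for a regime, held constant over 10-day steps."""
    daily = []
    for days, start, end in spec.segments:
        t = np.linspace(start, end, days, endpoint=False)
        daily.append(t)
    daily = np.concatenate(daily)
    # chambers adjust the setpoint every `step_days`: quantise to blocks
    n_blocks = int(np.ceil(len(daily) / step_days))
    out = np.empty_like(daily)
    for k in range(n_blocks):
        lo, hi = k * step_days, min((k + 1) * step_days, len(daily))
        out[lo:hi] = daily[lo]
    return out


def default_regime_specs(n_sites: int = 10, noise_sd: float = 0.0) -> list[RegimeSpec]:
    """Regimes spanning a cold gradient: decline, hold, rise over ~180 days.

    Site 0 is the warmest (minimum ~12 degC, almost no cold load); the
    coldest site reaches about -11 degC, so LTDD varies far more than
    5-fold across the set.
    """
    if n_sites < 1:
        raise InvalidInputError("n_sites must be >= 1")
    specs = []
    for k in range(n_sites):
        f = k / max(n_sites - 1, 1)
        start = 16.0 - 3.0 * f
        minimum = 12.0 - 23.0 * f
        specs.append(RegimeSpec(
            site_label=f"regime_{k:02d}",
            segments=((60, start, minimum), (60, minimum, minimum), (60, minimum, start)),
            noise_sd=noise_sd,
        ))
    return specs


def make_regimes(
    n_sites: int = 10,
    seed: int = 0,
    start_date: dt.date = dt.date(2010, 11, 1),
    noise_sd: float = 0.0,
) -> list[DailyTemperatureSeries]:
    """Deterministic winter temperature series for ``n_sites`` regimes."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    series = []
    for k, spec in enumerate(default_regime_specs(n_sites, noise_sd)):
        temps = _regime_daily_temps(spec)
        if spec.noise_sd > 0:
            temps = temps + rng.normal(0.0, spec.noise_sd, size=len(temps))
        dates = pd.date_range(start_date, periods=len(temps), freq="D")
        lat = 45.0 - 22.0 * (k / max(n_sites - 1, 1))  # cold gradient ~ latitude
        series.append(DailyTemperatureSeries(
            site_id=spec.site_label, latitude=lat, longitude=110.0,
            dates=dates, temps=temps,
        ))
    return series


def _window_predictors(series, n_days_list, config=ThermalConfig()):
    """Predictors for exposure windows starting at day 0, via prefix sums.

    Assumes a gap-free series (generators always emit one); agrees with
    the per-window functions in degree_days exactly.
    """
    t = series.temps
    deficit = np.concatenate([[0.0], np.cumsum(np.maximum(0.0, config.cold_threshold - t))])
    csum = np.concatenate([[0.0], np.cumsum(t)])
    cmin = np.minimum.accumulate(t)
    out = {}
    for d in n_days_list:
        out[d] = {
            "LTDD": float(deficit[d]),
            "MinDTmean": float(cmin[d - 1]),
            "DTmean": float(csum[d] / d),
            "exposure_days": int(d),
        }
    return out


def _observation(series, start, end, stage, setting, n, p, rng, noiseless,
                 predictors):
    if noiseless:
        survived = p * n
    else:
        survived = int(rng.binomial(n, p))
    return SurvivalObservation(
        site_id=series.site_id, stage=stage, setting=setting,
        exposure_start=start, exposure_end=end,
        n_exposed=n, n_survived=survived, predictors=dict(predictors),
    )


def simulate_survival_experiment(
    regimes,
    truth: TruthParams = TruthParams(),
    stage_n: dict | None = None,
    sample_every_days: int = 10,
    n_samples: int = 11,
    seed: int = 0,
    noiseless: bool = False,
) -> list[SurvivalObservation]:
    """Chamber survival experiment under the exponential-LTDD truth.

    Each regime is sampled destructively every ``sample_every_days`` days
    for ``n_samples`` points; per point, each stage's cohort survives
    Binomial(n, a*exp(b*LTDD)).  Samples are independent (no individual
    is measured twice).  Defaults give 10 regimes x 11 points x 2 stages
    = 220 observations.
    """
    if stage_n is None:
        stage_n = {"larva": 55, "pupa": 65}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    a, b = truth.survival.a, truth.survival.b
    observations = []
    for series in regimes:
        start = series.dates[0]
        days = [k * sample_every_days for k in range(1, n_samples + 1)]
        preds = _window_predictors(series, days)
        for d in days:
            end = start + pd.Timedelta(days=d - 1)
            p = float(np.clip(a * np.exp(b * preds[d]["LTDD"]), 0.0, 1.0))
            for stage, n in stage_n.items():
                observations.append(_observation(
                    series, start, end, stage, "lab", n, p, rng, noiseless,
                    preds[d]))
    return observations


def simulate_field_experiment(
    truth: TruthParams = TruthParams(),
    n_sites: int = 12,
    n_months: int = 4,
    n_per_cage: int = 30,
    cages_per_stage: int = 2,
    seed: int = 0,
    noise_sd: float = 2.0,
) -> list[SurvivalObservation]:
    """Field-cage survival design: monthly destructive samples at many sites.

    Site climates are noisy winter regimes across the cold gradient;
    larvae/pupae/adults on standing plants, larvae/pupae in buried jars.
    Survival is binomial around the same exponential-LTDD truth, so the
    data are noisy but unbiased with respect to the lab law.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 33]))
    regimes = make_regimes(n_sites, seed=int(seed) + 1, noise_sd=noise_sd)
    a, b = truth.survival.a, truth.survival.b
    observations = []
    for series in regimes:
        start = series.dates[0]
        days = [30 * month for month in range(1, n_months + 1)]
        preds = _window_predictors(series, days)
        for d in days:
            end = start + pd.Timedelta(days=d - 1)
            p = float(np.clip(a * np.exp(b * preds[d]["LTDD"]), 0.0, 1.0))
            for setting, stages in (("field_plant", ("larva", "pupa", "adult")),
                                    ("field_jar", ("larva", "pupa"))):
                for stage in stages:
                    for _ in range(cages_per_stage):
                        observations.append(_observation(
                            series, start, end, stage, setting,
                            n_per_cage, p, rng, False, preds[d]))
    return observations


def simulate_climate_grid(
    n_lat: int = 6,
    n_lon: int = 4,
    year_start: int = 2000,
    year_end: int = 2006,
    truth: TruthParams = TruthParams(),
    seed: int = 0,
    lat_min: float = -55.0,
    lat_max: float = 55.0,
) -> ClimateGrid:
    """Toy global grid of daily mean temperatures.

    Covers 1 Jan ``year_start`` .. 30 Jun ``year_end + 1`` so that both
    the southern (calendar-year) and northern (July–June) windows of all
    label years in [year_start, year_end] are complete.  Both hemispheres
    are represented when lat_min < 0 < lat_max.
    """
    if n_lat < 1 or n_lon < 1:
        raise InvalidInputError("grid dimensions must be >= 1")
    g = truth.grid
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 44]))
    lats = np.linspace(lat_min, lat_max, n_lat)
    lons = np.linspace(-30.0, 30.0, n_lon)
    dates = pd.date_range(dt.date(year_start, 1, 1), dt.date(year_end + 1, 6, 30), freq="D")
    doy = dates.dayofyear.to_numpy()
    frac_year = (dates - dates[0]).days.to_numpy() / 365.25
    base = g.equator_temp - g.lat_gradient * np.abs(lats)            # (n_lat,)
    amp = g.seasonal_base + g.seasonal_per_lat * np.abs(lats)        # (n_lat,)
    # northern cells peak mid-July, southern mid-January
    phase = np.where(lats[:, None] >= 0, 196.0, 15.0)                # (n_lat, 1)
    season = np.cos(2 * np.pi * (doy[None, :] - phase) / 365.25)     # (n_lat, n_t)
    cell = base[:, None] + amp[:, None] * season                     # (n_lat, n_t)
    trend = g.warming_per_year * frac_year                           # (n_t,)
    offsets = (rng.normal(0.0, g.cell_offset_sd, size=(n_lat, n_lon))
               if g.cell_offset_sd > 0 else np.zeros((n_lat, n_lon)))
    tmean = cell[:, None, :] + trend[None, None, :] + offsets[:, :, None]
    if g.noise_sd > 0:
        tmean = tmean + rng.normal(0.0, g.noise_sd, size=(n_lat, n_lon, len(dates)))
    else:
        tmean = np.broadcast_to(tmean, (n_lat, n_lon, len(dates))).copy()
    return ClimateGrid(lats=lats, lons=lons, dates=dates, tmean=tmean,
                       metadata={"seed": int(seed), "warming_per_year": g.warming_per_year})


def simulate_host_mask(grid: ClimateGrid, seed: int = 0,
                       mean_level: float = 0.55) -> HostMask:
    """Smooth random host-presence field in [0, 1] on the grid geometry.

    A few low-frequency sin/cos harmonics over lat/lon give spatially
    coherent structure mimicking a species-distribution-model surface.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55]))
    la = (grid.lats - grid.lats.min()) / max(np.ptp(grid.lats), 1.0)
    lo = (grid.lons - grid.lons.min()) / max(np.ptp(grid.lons), 1.0)
    LA, LO = np.meshgrid(la, lo, indexing="ij")
    fld = np.zeros_like(LA)
    for _ in range(4):
        fa, fb = rng.uniform(0.5, 2.5, size=2)
        pa, pb = rng.uniform(0, 2 * np.pi, size=2)
        fld += rng.normal(0, 1) * np.sin(2 * np.pi * fa * LA + pa) * np.cos(2 * np.pi * fb * LO + pb)
    fld = (fld - fld.mean()) / (fld.std() or 1.0)
    prob = np.clip(mean_level + 0.25 * fld, 0.0, 1.0)
    return HostMask(presence_prob=prob)


def _grid_annual_metrics(grid, years, config):
    """{year: (ltdd grid, etdd grid)} for the years the grid covers."""
    from .errors import CoverageError
    from .range_mapper import annual_etdd_grid, annual_ltdd_grid

    out = {}
    for y in years:
        try:
            out[y] = (annual_ltdd_grid(grid, y, config), annual_etdd_grid(grid, y, config))
        except CoverageError:
            continue
    return out


def simulate_resistance_records(
    n_records: int,
    truth: TruthParams = TruthParams(),
    grid: ClimateGrid | None = None,
    survival_model: FittedSurvivalModel | None = None,
    config: ThermalConfig = ThermalConfig(),
    n_pesticides: int = 15,
    records_per_site_year: int = 3,
    missing_ci_frac: float = 0.1,
    seed: int = 0,
) -> list[ResistanceRecord]:
    """Resistance records with a known effect structure.

    ln RR = mu + ow_effect + pesticide_effect + etdd_slope * ETDD_5yr
    + site-year random intercept + residual.  The overwintering type of
    a site is determined by the supplied survival law applied to its
    5-year mean LTDD, so the generator and the annotation pipeline agree
    by construction.  LC50s, sample sizes and 95% CIs are built so that
    the pooled-variance chain returns each record's generating
    measurement variance exactly; a ``missing_ci_frac`` fraction of
    records loses its field CI to exercise prognostic imputation.
    """
    m = truth.meta
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 66]))
    if grid is None:
        grid = simulate_climate_grid(seed=int(seed) + 7, truth=truth)
    a, b = truth.survival.a, truth.survival.b
    year_lo = grid.dates[0].year + 6  # leave 5 preceding windows + spin-up
    year_hi = grid.dates[-1].year - 1
    if year_hi < year_lo:
        raise InvalidInputError("grid too short for 5-year annotations")

    pest_names = [f"pesticide_{k:02d}" for k in range(n_pesticides)]
    pest_effects = rng.normal(0.0, m.pesticide_sd, size=n_pesticides)
    moa = [f"moa_{k % 6}" for k in range(n_pesticides)]

    metrics = _grid_annual_metrics(grid, range(year_lo - 5, year_hi), config)
    records: list[ResistanceRecord] = []
    while len(records) < n_records:
        i = int(rng.integers(0, len(grid.lats)))
        j = int(rng.integers(0, len(grid.lons)))
        year = int(rng.integers(year_lo, year_hi + 1))
        yrs = range(year - 5, year)
        yearly_ltdd = [float(metrics[y][0][i, j]) for y in yrs]
        ltdd5 = float(np.mean(yearly_ltdd))
        etdd5 = float(np.mean([metrics[y][1][i, j] for y in yrs]))
        # mean of yearly survivals, matching the annotation pipeline
        if survival_model is not None:
            surv5 = float(np.mean([survival_model.predict({"LTDD": l}) for l in yearly_ltdd]))
        else:
            surv5 = float(np.mean(np.clip(a * np.exp(b * np.asarray(yearly_ltdd)), 0.0, 1.0)))
        ow = ("permanent" if surv5 >= PERMANENT_CUTOFF
              else "marginal" if surv5 >= MARGINAL_CUTOFF else "transient")
        u_site_year = rng.normal(0.0, m.site_year_sd)
        lat = float(grid.lats[i])
        lon = float(grid.lons[j])
        for _ in range(records_per_site_year):
            if len(records) >= n_records:
                break
            k = int(rng.integers(0, n_pesticides))
            sd = m.residual_sd + m.het_ltdd_sd_slope * ltdd5
            ln_rr = (m.mu + m.ow_log_effect[ow] + pest_effects[k]
                     + m.etdd_slope * etdd5 + m.ltdd_slope * ltdd5
                     + u_site_year + rng.normal(0.0, sd))
            rr = float(np.exp(ln_rr))
            lc50_sus = float(rng.lognormal(mean=np.log(0.05), sigma=0.5))
            lc50_field = rr * lc50_sus
            v = m.measurement_v * float(np.exp(rng.normal(0.0, 0.3)))
            split = rng.uniform(0.3, 0.7)
            n_f = int(rng.integers(150, 601))
            n_s = int(rng.integers(150, 601))
            se_f = lc50_field * np.sqrt(n_f * v * split)
            se_s = lc50_sus * np.sqrt(n_s * v * (1 - split))
            ci_f = (lc50_field - 1.96 * se_f, lc50_field + 1.96 * se_f)
            ci_s = (lc50_sus - 1.96 * se_s, lc50_sus + 1.96 * se_s)
            if rng.uniform() < missing_ci_frac:
                ci_f = None
            records.append(ResistanceRecord(
                pesticide=pest_names[k], moa_group=moa[k],
                latitude=lat, longitude=lon, year=year, rr=rr,
                lc50_field=lc50_field, lc50_susceptible=lc50_sus,
                ci_field=ci_f, ci_susceptible=ci_s,
                n_field=n_f, n_susceptible=n_s,
            ))
    return records
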