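"""Projection of the winter-survival model onto gridded climate.

Per-cell annual LTDD (hemisphere-aware windows) feeds the fitted
survival model; 5-year mean survival classifies cells into permanent
(>= 5%), marginal (1–5%) and transient (< 1%) overwintering status.
Cells where the host-plant presence probability falls below 0.3 are
masked out: a crucifer specialist cannot overwinter without its host.
Areas are cos-latitude weighted on the sphere; warming scenarios shift
every daily temperature by a constant offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degree_days import ThermalConfig, annual_window_for
from .errors import CoverageError, InvalidInputError
from .survival_models import FittedSurvivalModel

__all__ = [
    "EARTH_KM_PER_DEGREE",
    "CLASS_CODES",
    "ClimateGrid",
    "HostMask",
    "OverwinterMap",
    "annual_ltdd_grid",
    "survival_grid",
    "classify_overwintering",
    "cell_area_km2",
    "overwinter_area",
    "expansion_series",
    "warming_scenario",
    "marginal_belt_trend",
]

# 2*pi*R/360 for mean Earth radius 6371 km
EARTH_KM_PER_DEGREE = 111.195

PERMANENT_CUTOFF = 0.05
MARGINAL_CUTOFF = 0.01
HOST_CUTOFF = 0.3

CLASS_CODES = {"transient": 0, "marginal": 1, "permanent": 2, "masked": 9}


@dataclass
class ClimateGrid:
    """Regular lat/lon grid of daily mean temperatures.

    tmean has shape (n_lat, n_lon, n_days), degC; lats/lons are 1-degree
    cell centers (any regular spacing is accepted).
    """

    lats: np.ndarray
    lons: np.ndarray
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if self.tmean.shape != (len(self.lats), len(self.lons), len(self.dates)):
            raise InvalidInputError("tmean shape must be (n_lat, n_lon, n_days)")
        if not np.all(np.isfinite(self.tmean)):
            raise InvalidInputError("temperatures must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (lat, lon, date, tmean_c) frame for CSV round-trips."""
        ii, jj, kk = np.meshgrid(
            np.arange(len(self.lats)), np.arange(len(self.lons)),
            np.arange(len(self.dates)), indexing="ij",
        )
        return pd.DataFrame(
            {
                "lat": self.lats[ii.ravel()],
                "lon": self.lons[jj.ravel()],
                "date": self.dates[kk.ravel()],
                "tmean_c": self.tmean.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, metadata: dict | None = None) -> "ClimateGrid":
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"])
        lats = np.sort(frame["lat"].unique())
        lons = np.sort(frame["lon"].unique())
        dates = pd.DatetimeIndex(np.sort(frame["date"].unique()))
        pivot = frame.set_index(["lat", "lon", "date"])["tmean_c"]
        full = pd.MultiIndex.from_product([lats, lons, dates], names=["lat", "lon", "date"])
        values = pivot.reindex(full)
        if values.isna().any():
            raise CoverageError("grid frame is not a complete lat x lon x date cube")
        tmean = values.to_numpy().reshape(len(lats), len(lons), len(dates))
        return cls(lats=lats, lons=lons, dates=dates, tmean=tmean,
                   metadata=metadata or {})

    def extract_series(self, i_lat: int, j_lon: int):
        from .degree_days import DailyTemperatureSeries

        return DailyTemperatureSeries(
            site_id=f"cell_{i_lat}_{j_lon}",
            latitude=float(self.lats[i_lat]),
            longitude=float(self.lons[j_lon]),
            dates=self.dates,
            temps=self.tmean[i_lat, j_lon, :],
        )

    def nearest_cell(self, latitude: float, longitude: float) -> tuple[int, int]:
        return (
            int(np.argmin(np.abs(self.lats - latitude))),
            int(np.argmin(np.abs(self.lons - longitude))),
        )


@dataclass
class HostMask:
    """Per-cell host-plant presence probability in [0, 1]."""

    presence_prob: np.ndarray

    def __post_init__(self) -> None:
        self.presence_prob = np.asarray(self.presence_prob, dtype=float)
        if np.any((self.presence_prob < 0) | (self.presence_prob > 1)):
            raise InvalidInputError("presence probabilities must lie in [0, 1]")


@dataclass
class OverwinterMap:
    """Per-cell survival and overwintering class on a grid."""

    lats: np.ndarray
    lons: np.ndarray
    survival: np.ndarray
    owclass: np.ndarray  # integer codes per CLASS_CODES

    def labels(self) -> np.ndarray:
        inv = {v: k for k, v in CLASS_CODES.items()}
        return np.vectorize(inv.get)(self.owclass)

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.meshgrid(np.arange(len(self.lats)), np.arange(len(self.lons)),
                             indexing="ij")
        return pd.DataFrame(
            {
                "lat": self.lats[ii.ravel()],
                "lon": self.lons[jj.ravel()],
                "survival": self.survival.ravel(),
                "class_code": self.owclass.ravel(),
            }
        )


def _window_time_mask(dates: pd.DatetimeIndex, window) -> np.ndarray:
    mask = (dates >= pd.Timestamp(window.start_date)) & (dates <= pd.Timestamp(window.end_date))
    n_expected = (pd.Timestamp(window.end_date) - pd.Timestamp(window.start_date)).days + 1
    if int(mask.sum()) != n_expected:
        raise CoverageError(
            f"grid dates cover {int(mask.sum())}/{n_expected} days of window "
            f"{window.start_date}..{window.end_date}"
        )
    return np.asarray(mask)


def annual_ltdd_grid(
    grid: ClimateGrid,
    year: int,
    config: ThermalConfig = ThermalConfig(),
) -> np.ndarray:
    """Per-cell annual LTDD for label year ``year`` (degC·day).

    Northern-hemisphere rows (lat >= 0) use the July–June window, southern
    rows the calendar year; grids are assumed gap-free.
    """
    deficit = np.maximum(0.0, config.cold_threshold - grid.tmean)
    out = np.empty(grid.shape, dtype=float)
    north = grid.lats >= 0
    for hemi, rows in (("north", north), ("south", ~north)):
        if not rows.any():
            continue
        window = annual_window_for(90 if hemi == "north" else -90, year)
        tmask = _window_time_mask(grid.dates, window)
        out[rows, :] = deficit[rows][:, :, tmask].sum(axis=2)
    return out


def annual_etdd_grid(
    grid: ClimateGrid,
    year: int,
    config: ThermalConfig = ThermalConfig(),
) -> np.ndarray:
    """Per-cell calendar-year ETDD (degC·day): growing-season heat.

    Daily contribution max(0, min(T, dev_upper) - dev_lower); the window
    is the calendar year at all latitudes.
    """
    start, end = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
    mask = (grid.dates >= start) & (grid.dates <= end)
    n_expected = (end - start).days + 1
    if int(mask.sum()) != n_expected:
        raise CoverageError(f"grid dates cover {int(mask.sum())}/{n_expected} days of {year}")
    t = grid.tmean[:, :, np.asarray(mask)]
    return np.maximum(0.0, np.minimum(t, config.dev_upper) - config.dev_lower).sum(axis=2)


def survival_grid(
    ltdd_grids,
    model: FittedSurvivalModel,
) -> np.ndarray:
    """Mean predicted survival over one or more annual LTDD grids.

    ``ltdd_grids`` is a single 2-D array or a sequence of them (one per
    year); predictions for each year are averaged, so the result is the
    mean of yearly survivals, not the survival at the mean LTDD.
    """
    if model.spec.predictor != "LTDD":
        raise InvalidInputError("survival_grid requires an LTDD-driven model")
    grids = [np.asarray(ltdd_grids, dtype=float)] if np.ndim(ltdd_grids) == 2 else [
        np.asarray(g, dtype=float) for g in ltdd_grids
    ]
    preds = [np.asarray(model.predict({"LTDD": g.ravel()})).reshape(g.shape) for g in grids]
    return np.mean(preds, axis=0)


def classify_overwintering(
    survival: np.ndarray,
    host_mask: HostMask,
    lats: np.ndarray | None = None,
    lons: np.ndarray | None = None,
    permanent_cutoff: float = PERMANENT_CUTOFF,
    marginal_cutoff: float = MARGINAL_CUTOFF,
    host_cutoff: float = HOST_CUTOFF,
) -> OverwinterMap:
    """Classify each cell: masked overrides, then permanent/marginal/transient.

    Boundaries: survival >= 5% permanent; 1% <= survival < 5% marginal;
    < 1% transient; host presence < 0.3 masked regardless of climate.
    """
    survival = np.asarray(survival, dtype=float)
    if host_mask.presence_prob.shape != survival.shape:
        raise InvalidInputError("host mask geometry does not match survival grid")
    owclass = np.full(survival.shape, CLASS_CODES["transient"], dtype=int)
    owclass[survival >= marginal_cutoff] = CLASS_CODES["marginal"]
    owclass[survival >= permanent_cutoff] = CLASS_CODES["permanent"]
    owclass[host_mask.presence_prob < host_cutoff] = CLASS_CODES["masked"]
    n_lat, n_lon = survival.shape
    return OverwinterMap(
        lats=np.arange(n_lat, dtype=float) if lats is None else np.asarray(lats, dtype=float),
        lons=np.arange(n_lon, dtype=float) if lons is None else np.asarray(lons, dtype=float),
        survival=survival,
        owclass=owclass,
    )


def cell_area_km2(latitude, cell_degrees: float = 1.0) -> float | np.ndarray:
    """Area of a cell_degrees x cell_degrees cell centred at ``latitude``.

    Spherical Earth, mean radius 6371 km: (111.195 * d)^2 * cos(lat).
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise InvalidInputError("latitude out of range")
    area = (EARTH_KM_PER_DEGREE * cell_degrees) ** 2 * np.cos(np.radians(lat))
    area = np.maximum(area, 0.0)  # cos(90) may round slightly negative
    return float(area) if np.ndim(latitude) == 0 else area


def overwinter_area(
    ow_map: OverwinterMap,
    survival_cutoff: float = PERMANENT_CUTOFF,
    cell_degrees: float = 1.0,
) -> tuple[int, float]:
    """(cell count, cos-weighted km^2) of unmasked cells with survival >= cutoff."""
    unmasked = ow_map.owclass != CLASS_CODES["masked"]
    qualifying = unmasked & (ow_map.survival >= survival_cutoff)
    lat_areas = cell_area_km2(ow_map.lats, cell_degrees)
    area = float((qualifying * lat_areas[:, None]).sum())
    return int(qualifying.sum()), area


def warming_scenario(grid: ClimateGrid, delta_t: float) -> ClimateGrid:
    """Uniformly warmed copy of the grid; scenario recorded in metadata."""
    if not math.isfinite(delta_t):
        raise InvalidInputError("delta_t must be finite")
    meta = dict(grid.metadata)
    meta["scenario_delta_t"] = delta_t
    return ClimateGrid(
        lats=grid.lats.copy(), lons=grid.lons.copy(), dates=grid.dates,
        tmean=grid.tmean + delta_t, metadata=meta,
    )


def _coverable_years(grid: ClimateGrid) -> list[int]:
    years = []
    for y in range(grid.dates[0].year - 1, grid.dates[-1].year + 1):
        try:
            _window_time_mask(grid.dates, annual_window_for(90, y))
            _window_time_mask(grid.dates, annual_window_for(-90, y))
        except CoverageError:
            continue
        years.append(y)
    return years


def expansion_series(
    grid: ClimateGrid,
    model: FittedSurvivalModel,
    host_mask: HostMask,
    baseline_year: int,
    config: ThermalConfig = ThermalConfig(),
    years: list[int] | None = None,
    block: int = 5,
) -> pd.DataFrame:
    """Yearly overwintering-area change versus a baseline year.

    For each label year with full window coverage (both hemispheres) the
    yearly survival map is classified and the area at the >= 1% and >= 5%
    cutoffs is differenced against ``baseline_year``.  ``block_start``
    labels non-overlapping ``block``-year means anchored at the baseline.
    """
    if years is None:
        years = _coverable_years(grid)
    if baseline_year not in years:
        raise CoverageError(f"baseline year {baseline_year} not covered by grid")
    rows = []
    for y in years:
        surv = survival_grid(annual_ltdd_grid(grid, y, config), model)
        ow = classify_overwintering(surv, host_mask, lats=grid.lats, lons=grid.lons)
        n5, a5 = overwinter_area(ow, PERMANENT_CUTOFF)
        n1, a1 = overwinter_area(ow, MARGINAL_CUTOFF)
        rows.append({"year": y, "cells_ge5": n5, "area_ge5_km2": a5,
                     "cells_ge1": n1, "area_ge1_km2": a1})
    df = pd.DataFrame(rows).set_index("year").sort_index()
    base = df.loc[baseline_year]
    df["delta_area_ge5_km2"] = df["area_ge5_km2"] - base["area_ge5_km2"]
    df["delta_area_ge1_km2"] = df["area_ge1_km2"] - base["area_ge1_km2"]
    df["block_start"] = baseline_year + ((df.index - baseline_year) // block) * block
    return df.reset_index()


def marginal_belt_trend(
    grid: ClimateGrid,
    model: FittedSurvivalModel,
    host_mask: HostMask,
    baseline_year: int,
    config: ThermalConfig = ThermalConfig(),
    years: list[int] | None = None,
) -> dict:
    """Linear trend of mean annual LTDD over the baseline marginal belt.

    The belt is the set of unmasked cells classified marginal (survival in
    [1%, 5%)) in ``baseline_year``.  Belt-mean LTDD per year is regressed
    on year by OLS; the p-value is the slope's two-sided t-test
    (equivalently the regression F-test with one predictor).
    """
    if years is None:
        years = _coverable_years(grid)
    base_surv = survival_grid(annual_ltdd_grid(grid, baseline_year, config), model)
    ow = classify_overwintering(base_surv, host_mask, lats=grid.lats, lons=grid.lons)
    belt = ow.owclass == CLASS_CODES["marginal"]
    if not belt.any():
        raise InvalidInputError("baseline year has no marginal-belt cells")
    means = [float(annual_ltdd_grid(grid, y, config)[belt].mean()) for y in years]
    from scipy.stats import linregress

    fit = linregress(np.asarray(years, dtype=float), np.asarray(means))
    return {
        "slope_per_year": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n_years": len(years),
        "n_belt_cells": int(belt.sum()),
        "belt_mean_ltdd": means,
        "years": list(years),
    }
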