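"""Thermal predictors of overwintering survival from daily mean temperatures.

The central quantity is the low-temperature degree-day sum (LTDD): the
accumulated deficit of the daily mean air temperature below a cold
threshold (11.0 degC for the diamondback moth) over an annual window.
Cold seasons straddle the calendar year in the northern hemisphere, so
the annual window there runs 1 July to 30 June of the following year;
in the southern hemisphere it is the calendar year itself.

The module also computes the companion predictors used for model
comparison — the lowest daily mean temperature (MinDTmean), the window
mean temperature paired with exposure duration (DTmean + days) — and the
effective-temperature degree-days (ETDD) accumulated inside the
developmental band (7.4–33 degC), a growing-season covariate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidInputError

__all__ = [
    "ThermalConfig",
    "DailyTemperatureSeries",
    "AnnualWindow",
    "daily_cold_deficit",
    "annual_window_for",
    "ltdd",
    "etdd",
    "min_dt_mean",
    "dt_mean_exposure",
    "multi_year_mean_ltdd",
]


@dataclass(frozen=True)
class ThermalConfig:
    """Thermal thresholds, degC.

    cold_threshold : daily means below this accumulate LTDD (default 11.0)
    dev_lower/dev_upper : developmental band for ETDD (defaults 7.4, 33.0)
    max_gap_fraction : tolerated fraction of missing days in a window,
        filled by linear interpolation in time; above it a CoverageError
        is raised.
    """

    cold_threshold: float = 11.0
    dev_lower: float = 7.4
    dev_upper: float = 33.0
    max_gap_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not np.isfinite(self.cold_threshold):
            raise InvalidInputError("cold_threshold must be finite")
        if not self.dev_lower < self.dev_upper:
            raise InvalidInputError("dev_lower must be < dev_upper")
        if not 0.0 <= self.max_gap_fraction < 1.0:
            raise InvalidInputError("max_gap_fraction must be in [0, 1)")


@dataclass
class DailyTemperatureSeries:
    """Daily mean air temperatures (degC) for one site.

    Dates must be strictly increasing calendar days; gaps are allowed and
    handled per :class:`ThermalConfig.max_gap_fraction` at aggregation time.
    """

    site_id: str
    latitude: float
    longitude: float
    dates: pd.DatetimeIndex
    temps: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.temps = np.asarray(self.temps, dtype=float)
        if len(self.dates) != len(self.temps):
            raise InvalidInputError("dates and temps must have equal length")
        if len(self.dates) == 0:
            raise InvalidInputError("series must not be empty")
        if not self.dates.is_monotonic_increasing or self.dates.has_duplicates:
            raise InvalidInputError("dates must be strictly increasing, no duplicates")
        if not np.all(np.isfinite(self.temps)):
            raise InvalidInputError("temperatures must be finite")
        if not (-90.0 <= self.latitude <= 90.0):
            raise InvalidInputError("latitude out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise InvalidInputError("longitude out of range")

    def as_series(self) -> pd.Series:
        return pd.Series(self.temps, index=self.dates, name=self.site_id)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        site_id: str | None = None,
        latitude: float = 0.0,
        longitude: float = 0.0,
    ) -> "DailyTemperatureSeries":
        """Build from a frame with columns site_id, date, tmean_c (lat/lon optional)."""
        if site_id is not None:
            frame = frame[frame["site_id"] == site_id]
        elif "site_id" in frame.columns:
            site_id = str(frame["site_id"].iloc[0])
        else:
            site_id = "site"
        if "lat" in frame.columns:
            latitude = float(frame["lat"].iloc[0])
        if "lon" in frame.columns:
            longitude = float(frame["lon"].iloc[0])
        frame = frame.sort_values("date")
        return cls(
            site_id=str(site_id),
            latitude=latitude,
            longitude=longitude,
            dates=pd.DatetimeIndex(pd.to_datetime(frame["date"])),
            temps=frame["tmean_c"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class AnnualWindow:
    """One labelled cold-season accounting year."""

    label_year: int
    hemisphere: str  # "north" or "south"
    start_date: dt.date = field(init=False)
    end_date: dt.date = field(init=False)

    def __post_init__(self) -> None:
        if self.hemisphere == "north":
            start = dt.date(self.label_year, 7, 1)
            end = dt.date(self.label_year + 1, 6, 30)
        elif self.hemisphere == "south":
            start = dt.date(self.label_year, 1, 1)
            end = dt.date(self.label_year, 12, 31)
        else:
            raise InvalidInputError(f"unknown hemisphere {self.hemisphere!r}")
        object.__setattr__(self, "start_date", start)
        object.__setattr__(self, "end_date", end)


def annual_window_for(latitude: float, year: int) -> AnnualWindow:
    """Hemisphere-aware annual window for LTDD accounting.

    Latitude >= 0 (equator inclusive, for determinism) gets the northern
    July-to-June window; southern latitudes the calendar year.
    """
    if not -90.0 <= latitude <= 90.0:
        raise InvalidInputError("latitude out of range")
    hemi = "north" if latitude >= 0 else "south"
    return AnnualWindow(label_year=int(year), hemisphere=hemi)


def daily_cold_deficit(temp, config: ThermalConfig = ThermalConfig()):
    """Per-day LTDD contribution: max(0, cold_threshold - temp), degC·day.

    Accepts a scalar or array; days at or above the threshold contribute 0.
    """
    arr = np.asarray(temp, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("temperature must be finite")
    out = np.maximum(0.0, config.cold_threshold - arr)
    return float(out) if np.isscalar(temp) or arr.ndim == 0 else out


def _as_date_range(window) -> tuple[pd.Timestamp, pd.Timestamp]:
    if isinstance(window, AnnualWindow):
        return pd.Timestamp(window.start_date), pd.Timestamp(window.end_date)
    start, end = window
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end < start:
        raise InvalidInputError("window end precedes start")
    return start, end


def window_temps(
    series: DailyTemperatureSeries,
    window,
    max_gap_fraction: float = 0.02,
) -> pd.Series:
    """Daily temperatures over a window, linearly filling tolerated gaps.

    The window must lie inside the series' first/last dates; interior gaps
    up to ``max_gap_fraction`` of the window length are interpolated from
    neighbouring days (the record itself may supply the neighbours).
    """
    start, end = _as_date_range(window)
    if start < series.dates[0] or end > series.dates[-1]:
        raise CoverageError(
            f"window {start.date()}..{end.date()} outside series coverage "
            f"{series.dates[0].date()}..{series.dates[-1].date()} for {series.site_id}"
        )
    full = pd.date_range(start, end, freq="D")
    s = series.as_series()
    present = s.index.intersection(full)
    missing = len(full) - len(present)
    if missing > max_gap_fraction * len(full):
        raise CoverageError(
            f"{missing}/{len(full)} days missing in window for {series.site_id} "
            f"(tolerance {max_gap_fraction:.1%})"
        )
    if missing == 0:
        return s.loc[full]
    # interpolate on the union index so gap edges can use neighbours
    # just outside the window
    filled = s.reindex(s.index.union(full)).interpolate(method="time")
    return filled.loc[full]


def ltdd(
    series: DailyTemperatureSeries,
    window,
    config: ThermalConfig = ThermalConfig(),
) -> float:
    """Low-temperature degree-days over a window (AnnualWindow or (start, end)).

    Sum of daily deficits below ``cold_threshold``; always >= 0 and additive
    over a partition of the window into disjoint sub-windows.
    """
    temps = window_temps(series, window, config.max_gap_fraction)
    return float(np.maximum(0.0, config.cold_threshold - temps.to_numpy()).sum())


def etdd(
    series: DailyTemperatureSeries,
    year: int,
    config: ThermalConfig = ThermalConfig(),
) -> float:
    """Effective-temperature degree-days over the calendar year.

    Daily contribution max(0, min(T, dev_upper) - dev_lower): nothing below
    the developmental floor, capped at the developmental ceiling.
    """
    window = (dt.date(year, 1, 1), dt.date(year, 12, 31))
    temps = window_temps(series, window, config.max_gap_fraction).to_numpy()
    return float(np.maximum(0.0, np.minimum(temps, config.dev_upper) - config.dev_lower).sum())


def min_dt_mean(series: DailyTemperatureSeries, window) -> float:
    """Lowest daily mean temperature in the window (degC)."""
    temps = window_temps(series, window)
    if len(temps) == 0:
        raise InvalidInputError("empty window")
    return float(temps.min())


def dt_mean_exposure(series: DailyTemperatureSeries, window) -> tuple[float, int]:
    """(mean daily temperature over the window, number of exposure days).

    The mean is taken over every day of the exposure window; duration is
    carried separately as the paired covariate.
    """
    temps = window_temps(series, window)
    if len(temps) == 0:
        raise InvalidInputError("empty window")
    return float(temps.mean()), int(len(temps))


def multi_year_mean_ltdd(
    series: DailyTemperatureSeries,
    end_year: int,
    n_years: int = 5,
    config: ThermalConfig = ThermalConfig(),
    latitude: float | None = None,
) -> float:
    """Mean annual LTDD over the ``n_years`` windows ending at ``end_year``.

    Window hemisphere follows the series latitude unless overridden.
    """
    if n_years < 1:
        raise InvalidInputError("n_years must be >= 1")
    lat = series.latitude if latitude is None else latitude
    values = [
        ltdd(series, annual_window_for(lat, y), config)
        for y in range(end_year - n_years + 1, end_year + 1)
    ]
    return float(np.mean(values))
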