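"""Plain-text I/O for the package's tabular artifacts (CSV throughout)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .range_mapper import ClimateGrid, HostMask
from .resistance_meta import ResistanceRecord
from .survival_models import SurvivalObservation

OBSERVATION_COLUMNS = [
    "site_id", "stage", "setting", "start", "end", "n_exposed", "n_survived",
    "LTDD", "MinDTmean", "DTmean", "exposure_days",
]

RECORD_COLUMNS = [
    "pesticide", "moa_group", "lat", "lon", "year",
    "lc50_field", "ci_field_lo", "ci_field_hi", "n_field",
    "lc50_susceptible", "ci_sus_lo", "ci_sus_hi", "n_susceptible", "rr",
]


def write_observations(observations, path) -> None:
    rows = []
    for o in observations:
        rows.append({
            "site_id": o.site_id, "stage": o.stage, "setting": o.setting,
            "start": pd.Timestamp(o.exposure_start).date(),
            "end": pd.Timestamp(o.exposure_end).date(),
            "n_exposed": o.n_exposed, "n_survived": o.n_survived,
            **{k: o.predictors.get(k) for k in ("LTDD", "MinDTmean", "DTmean", "exposure_days")},
        })
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_observations(path) -> list[SurvivalObservation]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(SurvivalObservation(
            site_id=str(r["site_id"]), stage=str(r["stage"]), setting=str(r["setting"]),
            exposure_start=pd.Timestamp(r["start"]), exposure_end=pd.Timestamp(r["end"]),
            n_exposed=float(r["n_exposed"]), n_survived=float(r["n_survived"]),
            predictors={k: float(r[k]) for k in ("LTDD", "MinDTmean", "DTmean", "exposure_days")
                        if pd.notna(r.get(k))},
        ))
    return out


def write_records(records, path) -> None:
    rows = []
    for r in records:
        rows.append({
            "pesticide": r.pesticide, "moa_group": r.moa_group,
            "lat": r.latitude, "lon": r.longitude, "year": r.year,
            "lc50_field": r.lc50_field,
            "ci_field_lo": r.ci_field[0] if r.ci_field else None,
            "ci_field_hi": r.ci_field[1] if r.ci_field else None,
            "n_field": r.n_field,
            "lc50_susceptible": r.lc50_susceptible,
            "ci_sus_lo": r.ci_susceptible[0] if r.ci_susceptible else None,
            "ci_sus_hi": r.ci_susceptible[1] if r.ci_susceptible else None,
            "n_susceptible": r.n_susceptible, "rr": r.rr,
        })
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)


def read_records(path) -> list[ResistanceRecord]:
    df = pd.read_csv(path)

    def opt(v):
        return None if pd.isna(v) else float(v)

    out = []
    for _, r in df.iterrows():
        ci_f = (float(r["ci_field_lo"]), float(r["ci_field_hi"])) \
            if pd.notna(r["ci_field_lo"]) and pd.notna(r["ci_field_hi"]) else None
        ci_s = (float(r["ci_sus_lo"]), float(r["ci_sus_hi"])) \
            if pd.notna(r["ci_sus_lo"]) and pd.notna(r["ci_sus_hi"]) else None
        out.append(ResistanceRecord(
            pesticide=str(r["pesticide"]), moa_group=str(r["moa_group"]),
            latitude=float(r["lat"]), longitude=float(r["lon"]), year=int(r["year"]),
            rr=float(r["rr"]), lc50_field=opt(r["lc50_field"]),
            lc50_susceptible=opt(r["lc50_susceptible"]),
            ci_field=ci_f, ci_susceptible=ci_s,
            n_field=opt(r["n_field"]), n_susceptible=opt(r["n_susceptible"]),
        ))
    return out


def write_grid(grid: ClimateGrid, path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_grid(path) -> ClimateGrid:
    return ClimateGrid.from_frame(pd.read_csv(path))


def write_host_mask(mask: HostMask, grid: ClimateGrid, path) -> None:
    ii, jj = np.meshgrid(np.arange(len(grid.lats)), np.arange(len(grid.lons)), indexing="ij")
    pd.DataFrame({
        "lat": grid.lats[ii.ravel()], "lon": grid.lons[jj.ravel()],
        "presence_prob": mask.presence_prob.ravel(),
    }).to_csv(path, index=False)


def read_host_mask(path, grid: ClimateGrid) -> HostMask:
    df = pd.read_csv(path)
    pivot = df.pivot(index="lat", columns="lon", values="presence_prob")
    pivot = pivot.reindex(index=grid.lats, columns=grid.lons)
    return HostMask(presence_prob=pivot.to_numpy())


def write_site_series(series_list, path) -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "site_id": s.site_id, "date": s.dates.date, "tmean_c": s.temps,
            "lat": s.latitude, "lon": s.longitude,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_site_series(path):
    from .degree_days import DailyTemperatureSeries

    df = pd.read_csv(path)
    return [DailyTemperatureSeries.from_frame(df, site_id=sid)
            for sid in df["site_id"].unique()]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
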