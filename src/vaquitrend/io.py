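"""Reading, validation and aggregation of daily acoustic monitoring records.

The monitoring design is a fixed grid of moored echolocation-click loggers
(46 sites in the vaquita study) sampled every summer.  The raw unit of data
is a *site-day*: on each day a logger is in the water ("sampled") it reports
the number of vaquita clicks in validated click trains and the number of
detection-positive minutes (DPM).  The trend model consumes an annualized
summary per site and year: ``W_ti``, the mean clicks per sampled day inside
a fixed 62-day core window (Julian day 170-231, i.e. 19 June - 19 August),
and ``n_ti``, the number of sampled days behind that mean.

Input files are headered CSV.  Canonical column names are
``site_id, date, clicks, dpm`` (detections), ``site_id, date`` (effort;
optionally a 0/1 ``sampled`` column) and ``site_id, easting_km, northing_km``
(sites); a column-mapping dict adapts files with other headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance_matrix as _distance_matrix

#: Core sampling window, inclusive Julian-day bounds (19 June - 19 August
#: in the non-leap day-of-year convention used throughout).
DEFAULT_CORE_WINDOW = (170, 231)

MINUTES_PER_DAY = 1440


class DataValidationError(ValueError):
    """Raised when an input table violates the monitoring-data contract."""


@dataclass(frozen=True)
class SiteGrid:
    """Fixed grid of monitoring sites with planar coordinates in kilometres."""

    site_ids: tuple
    coords_km: np.ndarray  # shape (n_sites, 2): easting, northing

    def __post_init__(self):
        coords = np.asarray(self.coords_km, dtype=float)
        object.__setattr__(self, "coords_km", coords)
        if len(self.site_ids) != len(set(self.site_ids)):
            raise DataValidationError("site ids must be unique")
        if coords.shape != (len(self.site_ids), 2):
            raise DataValidationError("coords_km must be (n_sites, 2)")
        if not np.all(np.isfinite(coords)):
            raise DataValidationError("site coordinates must be finite")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean inter-site distances h_ij in km."""
        return _distance_matrix(self.coords_km, self.coords_km)

    def index_of(self, site_id) -> int:
        return self.site_ids.index(site_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, column_map: dict | None = None) -> "SiteGrid":
        frame = _apply_column_map(frame, column_map)
        _require_columns(frame, ["site_id", "easting_km", "northing_km"], "sites")
        return cls(
            site_ids=tuple(frame["site_id"].tolist()),
            coords_km=frame[["easting_km", "northing_km"]].to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": list(self.site_ids),
                "easting_km": self.coords_km[:, 0],
                "northing_km": self.coords_km[:, 1],
            }
        )


def load_site_grid(path, column_map: dict | None = None) -> SiteGrid:
    """Read site coordinates (already projected, km) from a CSV file."""
    return SiteGrid.from_frame(pd.read_csv(path), column_map)


def geographic_to_km(lon_deg, lat_deg, lon0=None, lat0=None):
    """Convert geographic coordinates to planar km by equirectangular projection.

    A single stated convention for users whose site table is in degrees:
    eastings are ``R*cos(lat0)*(lon-lon0)``, northings ``R*(lat-lat0)`` with
    R = 6371 km and the reference point defaulting to the centroid.  Adequate
    over the tens-of-kilometre extent of a monitoring grid.
    """
    lon = np.asarray(lon_deg, dtype=float)
    lat = np.asarray(lat_deg, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    r_km = 6371.0
    east = np.radians(lon - lon0) * r_km * np.cos(np.radians(lat0))
    north = np.radians(lat - lat0) * r_km
    return east, north


@dataclass(frozen=True)
class MonitoringDataset:
    """Annualized site-by-year summaries ready for the geostatistical model.

    ``summaries`` has one row per (year, site) with data: columns
    ``year, site_id, W, n``.  Site-years with no sampling inside the core
    window are simply absent (missing, never imputed as zero).
    """

    grid: SiteGrid
    summaries: pd.DataFrame
    core_window: tuple = DEFAULT_CORE_WINDOW

    def __post_init__(self):
        s = self.summaries
        if s.duplicated(subset=["year", "site_id"]).any():
            raise DataValidationError("at most one summary per (year, site)")
        unknown = set(s["site_id"]) - set(self.grid.site_ids)
        if unknown:
            raise DataValidationError(f"summary sites not in grid: {sorted(unknown)!r}")
        if (s["n"] <= 0).any():
            raise DataValidationError("summaries must have n > 0 (missing rows are absent)")
        if (s["W"] < 0).any():
            raise DataValidationError("W must be nonnegative")

    @property
    def years(self) -> list:
        return sorted(self.summaries["year"].unique().tolist())

    def response_matrices(self):
        """(Y, n) matrices of shape (n_years, n_sites); NaN / 0 where missing.

        Y is the log-transformed response log(W+1).
        """
        years = self.years
        sites = list(self.grid.site_ids)
        ymat = np.full((len(years), len(sites)), np.nan)
        nmat = np.zeros((len(years), len(sites)), dtype=float)
        yidx = {y: k for k, y in enumerate(years)}
        sidx = {s: k for k, s in enumerate(sites)}
        for row in self.summaries.itertuples(index=False):
            t, i = yidx[row.year], sidx[row.site_id]
            ymat[t, i] = np.log1p(row.W)
            nmat[t, i] = row.n
        return ymat, nmat

    def write_csv(self, path) -> None:
        self.summaries.to_csv(path, index=False)


def _apply_column_map(frame: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    return frame


def _require_columns(frame: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{what} table missing columns {missing}")


def julian_day(dates) -> np.ndarray:
    """Day-of-year in the non-leap convention (19 June is 170 every year).

    In leap years the calendar day-of-year after 28 February is one larger
    than in common years; subtracting that offset anchors the core window on
    fixed Julian-day numbers so day 170-231 always spans 19 June - 19 August.
    """
    d = pd.DatetimeIndex(pd.to_datetime(dates))
    doy = d.dayofyear.to_numpy()
    leap_shift = (d.is_leap_year & (d.month > 2)).astype(int)
    return doy - leap_shift


def load_daily_records(
    detections_path,
    effort_path,
    column_map: dict | None = None,
    grid: SiteGrid | None = None,
) -> pd.DataFrame:
    """Combine effort and detection tables into one row per sampled site-day.

    The effort table lists site-days with a logger recording (rows with a
    ``sampled`` column equal to 0 are dropped).  A sampled site-day absent
    from the detections table is a day with zero detections, not missing
    data.  Returns a frame with columns ``site_id, date, clicks, dpm,
    sampled`` (sampled is always True in the returned rows).
    """
    eff = _apply_column_map(pd.read_csv(effort_path, parse_dates=["date"]), column_map)
    det = _apply_column_map(pd.read_csv(detections_path, parse_dates=["date"]), column_map)
    _require_columns(eff, ["site_id", "date"], "effort")
    _require_columns(det, ["site_id", "date", "clicks"], "detections")
    if "dpm" not in det.columns:
        det = det.assign(dpm=0)
    if "sampled" in eff.columns:
        eff = eff[eff["sampled"].astype(bool)]
    eff = eff[["site_id", "date"]].copy()

    for name, frame in [("effort", eff), ("detections", det)]:
        dup = frame.duplicated(subset=["site_id", "date"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise DataValidationError(
                f"duplicate (site, date) in {name}: {row['site_id']!r} {row['date'].date()}"
            )
    if grid is not None:
        for name, frame in [("effort", eff), ("detections", det)]:
            unknown = set(frame["site_id"]) - set(grid.site_ids)
            if unknown:
                raise DataValidationError(f"unknown site id(s) in {name}: {sorted(unknown)!r}")
    bad = det[(det["clicks"] < 0) | (det["dpm"] < 0)]
    if len(bad):
        r = bad.iloc[0]
        raise DataValidationError(
            f"negative count at site {r['site_id']!r} on {r['date'].date()}"
        )
    if (det["dpm"] > MINUTES_PER_DAY).any():
        raise DataValidationError(f"dpm exceeds {MINUTES_PER_DAY} minutes/day")

    merged = eff.merge(det, on=["site_id", "date"], how="outer", indicator=True)
    orphans = merged[(merged["_merge"] == "right_only") & (merged["clicks"] > 0)]
    if len(orphans):
        r = orphans.iloc[0]
        raise DataValidationError(
            f"detections without effort at site {r['site_id']!r} on {r['date'].date()} "
            "(clicks > 0 implies the day was sampled)"
        )
    merged = merged[merged["_merge"] != "right_only"]
    records = merged.drop(columns="_merge").fillna({"clicks": 0, "dpm": 0})
    records["clicks"] = records["clicks"].astype(float)
    records["dpm"] = records["dpm"].astype(float)
    records["sampled"] = True
    return records.sort_values(["date", "site_id"]).reset_index(drop=True)


def annualize(
    records: pd.DataFrame,
    core_window: tuple = DEFAULT_CORE_WINDOW,
    grid: SiteGrid | None = None,
) -> pd.DataFrame | MonitoringDataset:
    """Aggregate daily records to W_ti (mean clicks/sampled day) and n_ti.

    Only sampled days with Julian day inside ``core_window`` (inclusive)
    contribute; site-years with no such days are omitted.  Returns the
    summary frame, or a full :class:`MonitoringDataset` when ``grid`` is
    given.
    """
    if len(records) == 0:
        raise DataValidationError("empty record set")
    rec = records[records["sampled"].astype(bool)].copy()
    jday = julian_day(rec["date"])
    lo, hi = core_window
    rec = rec[(jday >= lo) & (jday <= hi)]
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    grouped = (
        rec.groupby(["year", "site_id"], sort=True)
        .agg(W=("clicks", "mean"), n=("clicks", "size"))
        .reset_index()
    )
    if grid is None:
        return grouped
    return MonitoringDataset(grid=grid, summaries=grouped, core_window=core_window)


def mean_clicks_per_sensor_day(
    records: pd.DataFrame, year: int, core_window: tuple = DEFAULT_CORE_WINDOW
) -> float:
    """Raw total clicks / total sampled sensor-days for one year's core window."""
    rec = records[records["sampled"].astype(bool)]
    jday = julian_day(rec["date"])
    lo, hi = core_window
    rec = rec[(jday >= lo) & (jday <= hi)]
    rec = rec[pd.DatetimeIndex(rec["date"]).year == year]
    if len(rec) == 0:
        raise DataValidationError(f"no sampled records in {year}")
    return float(rec["clicks"].sum() / len(rec))


def raw_change(dataset: MonitoringDataset | pd.DataFrame, year_a: int, year_b: int):
    """Ratio of cross-site mean W between two years, ignoring unequal effort.

    Returns ``(ratio, percent_decline)`` where decline = (1 - ratio) * 100.
    Each year's mean runs over the sites with data in that year; NaN (with a
    warning) when the earlier year's mean is zero.
    """
    summaries = dataset.summaries if isinstance(dataset, MonitoringDataset) else dataset
    means = {}
    for year in (year_a, year_b):
        sub = summaries[summaries["year"] == year]
        if len(sub) == 0:
            raise DataValidationError(f"no data for year {year}")
        means[year] = float(sub["W"].mean())
    if means[year_a] == 0.0:
        warnings.warn(f"cross-site mean W is zero in {year_a}; ratio undefined")
        return float("nan"), float("nan")
    ratio = means[year_b] / means[year_a]
    return ratio, (1.0 - ratio) * 100.0


def effort_series(records: pd.DataFrame) -> pd.DataFrame:
    """Active loggers per (year, Julian day): the monitoring-effort picture."""
    rec = records[records["sampled"].astype(bool)].copy()
    rec["year"] = pd.DatetimeIndex(rec["date"]).year
    rec["julian_day"] = julian_day(rec["date"])
    out = (
        rec.groupby(["year", "julian_day"], sort=True)
        .agg(active_sites=("site_id", "nunique"))
        .reset_index()
    )
    return out
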