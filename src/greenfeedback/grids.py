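"""Gridded-field data model, calendar/season conventions, masking and I/O.

Everything downstream (LAI scenarios, the toy simulator, paired-experiment
differencing, the energy-balance decomposition and the seasonal statistics)
exchanges data through :class:`GriddedField`: a regular cell-centred
lat-lon array, optionally with a monthly time axis, where masked cells are
encoded as NaN and excluded from every reduction.

Seasons follow the standard meteorological convention: MAM (Mar-May),
JJA (Jun-Aug), SON (Sep-Nov) and DJF (Dec-Feb).  DJF labelled with year *y*
aggregates Dec(y) with Jan(y+1) and Feb(y+1), i.e. the winter *following*
the growing season of year *y*; a trailing incomplete winter is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import xarray as xr

__all__ = [
    "Season",
    "SEASON_MONTHS",
    "season_of_month",
    "GriddedField",
    "YearlyField",
    "month_range",
    "seasonal_series",
    "area_weighted_mean",
    "climatological_lai_mask",
    "read_field",
    "write_field",
    "regular_grid",
]

logger = logging.getLogger(__name__)


class Season(str, Enum):
    """Meteorological season keys."""

    MAM = "MAM"
    JJA = "JJA"
    SON = "SON"
    DJF = "DJF"


SEASON_MONTHS: dict[Season, tuple[int, int, int]] = {
    Season.MAM: (3, 4, 5),
    Season.JJA: (6, 7, 8),
    Season.SON: (9, 10, 11),
    Season.DJF: (12, 1, 2),
}

_MONTH_TO_SEASON = {m: s for s, months in SEASON_MONTHS.items() for m in months}


def season_of_month(month: int) -> Season:
    """Return the season containing calendar ``month`` (1..12)."""
    if not (isinstance(month, (int, np.integer)) and 1 <= month <= 12):
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    return _MONTH_TO_SEASON[int(month)]


def month_range(start_year: int, end_year: int) -> list[tuple[int, int]]:
    """All (year, month) stamps from Jan ``start_year`` to Dec ``end_year``."""
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    return [(y, m) for y in range(start_year, end_year + 1) for m in range(1, 13)]


def regular_grid(
    nlat: int, nlon: int, lat_bounds: tuple[float, float] = (25.0, 90.0),
    lon_bounds: tuple[float, float] = (0.0, 360.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre coordinates of a regular lat-lon grid.

    Defaults to the northern study domain (25-90N, all longitudes).
    """
    lat0, lat1 = lat_bounds
    lon0, lon1 = lon_bounds
    dlat = (lat1 - lat0) / nlat
    dlon = (lon1 - lon0) / nlon
    lat = lat0 + dlat * (np.arange(nlat) + 0.5)
    lon = lon0 + dlon * (np.arange(nlon) + 0.5)
    return lat, lon


def _validate_months(months: list[tuple[int, int]]) -> None:
    if len(set(months)) != len(months):
        raise ValueError("time stamps must be unique")
    for (y0, m0), (y1, m1) in zip(months[:-1], months[1:]):
        nxt = (y0, m0 + 1) if m0 < 12 else (y0 + 1, 1)
        if (y1, m1) != nxt:
            raise ValueError(
                f"time stamps must be contiguous in calendar order; "
                f"{(y0, m0)} is followed by {(y1, m1)}"
            )


@dataclass
class GriddedField:
    """A (time x) lat x lon array with units and NaN-masked cells.

    ``values`` is ``(nlat, nlon)`` for static fields or ``(ntime, nlat,
    nlon)`` for monthly fields, in which case ``months`` holds one
    ``(year, month)`` stamp per time step, unique and contiguous.
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    months: list[tuple[int, int]] | None = None
    units: str = ""
    name: str = field(default="field")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.lat = np.asarray(self.lat, dtype=np.float64)
        self.lon = np.asarray(self.lon, dtype=np.float64)
        if np.any(self.lat < -90.0) or np.any(self.lat > 90.0):
            raise ValueError("latitudes must lie in [-90, 90]")
        if self.lat.ndim != 1 or np.any(np.diff(self.lat) <= 0):
            raise ValueError("lat must be 1-D ascending")
        if self.months is not None:
            self.months = [(int(y), int(m)) for y, m in self.months]
            _validate_months(self.months)
            expected = (len(self.months), self.lat.size, self.lon.size)
        else:
            expected = (self.lat.size, self.lon.size)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"coordinates {expected}"
            )

    @property
    def has_time(self) -> bool:
        return self.months is not None

    @property
    def years(self) -> list[int]:
        if self.months is None:
            raise ValueError("static field has no time axis")
        return sorted({y for y, _ in self.months})

    def month_index(self, year: int, month: int) -> int:
        return self.months.index((year, month))  # type: ignore[union-attr]

    def copy_with(self, **kw) -> "GriddedField":
        if "values" in kw:
            kw["values"] = np.array(kw["values"], dtype=np.float64)
        return replace(self, **kw)

    def calendar_month_values(self, month: int) -> tuple[np.ndarray, np.ndarray]:
        """(years, values[year, lat, lon]) for one calendar month."""
        if self.months is None:
            raise ValueError("static field has no time axis")
        idx = [i for i, (_, m) in enumerate(self.months) if m == month]
        years = np.array([self.months[i][0] for i in idx])
        return years, self.values[idx]


@dataclass
class YearlyField:
    """One value per year per cell: the output of seasonal aggregation."""

    values: np.ndarray  # (nyear, nlat, nlon)
    lat: np.ndarray
    lon: np.ndarray
    years: np.ndarray
    units: str = ""
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.years = np.asarray(self.years, dtype=np.int64)
        if self.values.shape[0] != self.years.size:
            raise ValueError("one value per year required")


def seasonal_series(fld: GriddedField, season: Season | str) -> YearlyField:
    """Per-year mean of a monthly field over one season's months.

    DJF labelled year *y* averages Dec(y), Jan(y+1), Feb(y+1); the final
    year's incomplete winter is dropped, so a span of N years yields N-1
    DJF values.
    """
    season = Season(season)
    if fld.months is None:
        raise ValueError("seasonal_series requires a monthly field")
    stamp_to_idx = {ym: i for i, ym in enumerate(fld.months)}
    years_out, stacks = [], []
    for y in fld.years:
        if season is Season.DJF:
            wanted = [(y, 12), (y + 1, 1), (y + 1, 2)]
        else:
            wanted = [(y, m) for m in SEASON_MONTHS[season]]
        if all(w in stamp_to_idx for w in wanted):
            years_out.append(y)
            stacks.append(np.mean([fld.values[stamp_to_idx[w]] for w in wanted], axis=0))
    if not stacks:
        raise ValueError(f"no complete {season.value} season in the record")
    return YearlyField(
        values=np.array(stacks), lat=fld.lat, lon=fld.lon,
        years=np.array(years_out), units=fld.units, name=f"{fld.name}_{season.value}",
    )


def _cos_weights(lat: np.ndarray, nlon: int) -> np.ndarray:
    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, nlon))
    return w


def area_weighted_mean(
    fld: GriddedField | YearlyField, mask: np.ndarray | None = None
) -> np.ndarray | float:
    """Cosine-latitude weighted mean over unmasked, non-NaN cells.

    ``mask`` is boolean with True = include.  Weights are renormalised over
    the cells that actually contribute at each time step.  Returns a scalar
    for static fields, a 1-D series for time-typed fields.
    """
    vals = fld.values
    static = vals.ndim == 2
    if static:
        vals = vals[None]
    w = _cos_weights(fld.lat, fld.lon.size)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != w.shape:
            raise ValueError("mask shape does not match grid")
        w = np.where(mask, w, 0.0)
    out = np.empty(vals.shape[0])
    n_skipped = 0
    for t in range(vals.shape[0]):
        valid = np.isfinite(vals[t]) & (w > 0)
        wt = np.where(valid, w, 0.0)
        tot = wt.sum()
        if tot == 0.0:
            raise ValueError("all cells masked: area mean undefined")
        n_skipped += int((~valid).sum())
        out[t] = np.nansum(wt * np.where(valid, vals[t], 0.0)) / tot
    if n_skipped:
        logger.debug("area_weighted_mean skipped %d masked cell-steps", n_skipped)
    return float(out[0]) if static else out


def climatological_lai_mask(lai: GriddedField, threshold: float = 0.1) -> np.ndarray:
    """Vegetated-land mask: True where time-mean LAI >= ``threshold``.

    The default 0.1 m2 m-2 cutoff drops barren/ice cells where prescribed
    vegetation cannot plausibly act on the energy balance.
    """
    if lai.months is None:
        raise ValueError("climatological mask needs the monthly LAI record")
    clim = np.nanmean(lai.values, axis=0)
    # inclusive boundary; tolerance absorbs float accumulation in the mean
    mask = np.isfinite(clim) & (clim >= threshold - 1e-12)
    logger.debug("LAI mask keeps %d / %d cells", int(mask.sum()), mask.size)
    return mask


# ---------------------------------------------------------------------------
# I/O: CF-style netCDF through xarray (scipy backend, classic format)

def _to_dataset(fld: GriddedField) -> xr.Dataset:
    coords = {
        "lat": ("lat", fld.lat, {"units": "degrees_north"}),
        "lon": ("lon", fld.lon, {"units": "degrees_east"}),
    }
    if fld.months is not None:
        y0, m0 = fld.months[0]
        tvals = np.array(
            [(y - y0) * 12 + (m - m0) for y, m in fld.months], dtype=np.int32
        )
        coords["time"] = (
            "time", tvals, {"units": f"months since {y0:04d}-{m0:02d}-15"}
        )
        dims = ("time", "lat", "lon")
    else:
        dims = ("lat", "lon")
    da = xr.DataArray(fld.values, dims=dims, attrs={"units": fld.units})
    return xr.Dataset({fld.name: da}, coords=coords)


def write_field(path, fld: GriddedField) -> None:
    """Write a field as a CF-style netCDF file (classic format)."""
    _to_dataset(fld).to_netcdf(path, engine="scipy")


def read_field(path, name: str | None = None, require_time: bool | None = None) -> GriddedField:
    """Read a field written by :func:`write_field` (or CF-compatible)."""
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        ds.load()
    if name is None:
        candidates = [v for v in ds.data_vars if v not in ("lat", "lon", "time")]
        if len(candidates) != 1:
            raise ValueError(f"ambiguous file: variables {candidates}")
        name = candidates[0]
    da = ds[name]
    for axis in ("lat", "lon"):
        if axis not in da.dims:
            raise ValueError(f"malformed file: missing '{axis}' axis")
    months = None
    if "time" in da.dims:
        tattr = ds["time"].attrs.get("units", "")
        if not tattr.startswith("months since "):
            raise ValueError(f"malformed 'time' axis units: {tattr!r}")
        anchor = tattr.split("since ")[1]
        y0, m0 = int(anchor[0:4]), int(anchor[5:7])
        months = []
        for off in np.asarray(ds["time"].values, dtype=int):
            tot = (m0 - 1) + off
            months.append((y0 + tot // 12, tot % 12 + 1))
        da = da.transpose("time", "lat", "lon")
    elif require_time:
        raise ValueError("file has no 'time' axis but a time-typed field was requested")
    return GriddedField(
        values=da.values,
        lat=ds["lat"].values,
        lon=ds["lon"].values,
        months=months,
        units=da.attrs.get("units", ""),
        name=name,
    )
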