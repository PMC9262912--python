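"""LAI preparation: composites to monthly maps, aggregation, PFT weighting,
and the synthetic satellite-record generator.

The real preparation chain takes 15-day satellite LAI composites, keeps the
monthly maximum per cell, aggregates to a coarse regular grid, and splits
the cell LAI over plant functional types (PFTs) by fractional cover.  The
scenario generator replaces the satellite archive: it produces a monthly
LAI record with a prescribed seasonal climatology, season-specific linear
trends and interannual noise, which is what the paired experiments consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GriddedField, Season, month_range, season_of_month

__all__ = [
    "PftCover",
    "LaiScenario",
    "monthly_max_composite",
    "aggregate_to_grid",
    "pft_level_lai",
    "generate_lai_scenario",
    "DEFAULT_SEASON_SLOPES",
]

logger = logging.getLogger(__name__)

# NH-mean seasonal greening rates (m2 m-2 decade-1) used as generator
# defaults: strongest in summer, weaker in autumn and spring, none imposed
# in winter when the canopy is dormant.
DEFAULT_SEASON_SLOPES: dict[Season, float] = {
    Season.MAM: 0.019,
    Season.JJA: 0.046,
    Season.SON: 0.027,
    Season.DJF: 0.0,
}


@dataclass
class PftCover:
    """Fractional vegetation cover per PFT per cell, plus a bare-soil class.

    ``fractions`` is (npft, nlat, nlon); ``bare_index`` marks the bare-soil
    class, every other class is vegetated.
    """

    fractions: np.ndarray
    names: list[str]
    bare_index: int = -1

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.ndim != 3 or self.fractions.shape[0] != len(self.names):
            raise ValueError("fractions must be (npft, nlat, nlon) matching names")
        if np.any(self.fractions < 0):
            raise ValueError("cover fractions must be nonnegative")
        total = self.fractions.sum(axis=0)
        if np.any(total > 1.0 + 1e-6):
            raise ValueError("cover fractions sum above 1")
        self.bare_index = range(len(self.names))[self.bare_index]

    @property
    def vegetated_fraction(self) -> np.ndarray:
        veg = np.ones(len(self.names), dtype=bool)
        veg[self.bare_index] = False
        return self.fractions[veg].sum(axis=0)


def monthly_max_composite(
    values: np.ndarray,
    stamps: list[tuple[int, int]],
    lat: np.ndarray,
    lon: np.ndarray,
    units: str = "m2 m-2",
) -> GriddedField:
    """Reduce sub-monthly composites to monthly maps by per-cell maximum.

    ``stamps`` gives the (year, month) each composite falls in (repeats
    expected: ~two 15-day composites per month).  Taking the within-month
    maximum limits the low bias from residual cloud/snow contamination.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] != len(stamps):
        raise ValueError("one stamp per composite required")
    months = sorted(set(stamps))
    expected = month_range(months[0][0], months[-1][0])
    expected = [ym for ym in expected if months[0] <= ym <= months[-1]]
    missing = [ym for ym in expected if ym not in set(stamps)]
    if missing:
        raise ValueError(f"months without any composite: {missing}")
    out = np.empty((len(expected), values.shape[1], values.shape[2]))
    for i, ym in enumerate(expected):
        idx = [j for j, s in enumerate(stamps) if s == ym]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            out[i] = np.nanmax(values[idx], axis=0)
    return GriddedField(out, lat, lon, months=expected, units=units, name="lai")


def aggregate_to_grid(fine: GriddedField, factor: int) -> GriddedField:
    """Block-aggregate a fine grid to a coarser one by an integer factor.

    Coarse cell = cosine-latitude-weighted mean of its unmasked children;
    a coarse cell whose children are all masked stays masked.  Requires the
    fine grid to nest integrally (shape divisible by ``factor``).
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    nlat, nlon = fine.lat.size, fine.lon.size
    if nlat % factor or nlon % factor:
        raise ValueError(
            f"fine grid {nlat}x{nlon} does not nest in blocks of {factor}"
        )
    vals = fine.values if fine.has_time else fine.values[None]
    nt = vals.shape[0]
    w = np.cos(np.deg2rad(fine.lat))[None, :, None] * np.ones((nt, 1, nlon))
    w = np.where(np.isfinite(vals), w, 0.0)
    v = np.where(np.isfinite(vals), vals, 0.0)

    def blocks(a):
        return a.reshape(nt, nlat // factor, factor, nlon // factor, factor)

    wsum = blocks(w).sum(axis=(2, 4))
    vsum = blocks(w * v).sum(axis=(2, 4))
    with np.errstate(invalid="ignore", divide="ignore"):
        coarse = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    lat_c = fine.lat.reshape(-1, factor).mean(axis=1)
    lon_c = fine.lon.reshape(-1, factor).mean(axis=1)
    if not fine.has_time:
        coarse = coarse[0]
    return GriddedField(coarse, lat_c, lon_c, months=fine.months,
                        units=fine.units, name=fine.name)


def pft_level_lai(cell_lai: GriddedField, cover: PftCover) -> dict[str, GriddedField]:
    """Assign the cell LAI uniformly to every vegetated PFT.

    The cover-weighted mean over vegetated classes then reconstructs the
    cell LAI exactly, which is the quantity the experiments prescribe.
    Bare soil gets LAI 0.  Cells with zero vegetated cover but nonzero LAI
    are masked (with a warning) as physically inconsistent.
    """
    veg_frac = cover.vegetated_fraction
    vals = cell_lai.values
    lai2d = vals if not cell_lai.has_time else np.nanmax(vals, axis=0)
    bad = (veg_frac <= 0) & np.isfinite(lai2d) & (lai2d > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cells have LAI > 0 but no vegetated cover; masked",
            stacklevel=2,
        )
    out: dict[str, GriddedField] = {}
    for i, name in enumerate(cover.names):
        if i == cover.bare_index:
            pft_vals = np.where(np.isfinite(vals), 0.0, np.nan)
        else:
            pft_vals = np.where(bad, np.nan, vals) if not cell_lai.has_time else \
                np.where(bad[None], np.nan, vals)
        out[name] = cell_lai.copy_with(values=pft_vals, name=f"lai_{name}")
    return out


@dataclass
class LaiScenario:
    """Synthetic monthly LAI record: climatology + seasonal trends + noise.

    * ``season_slopes`` — imposed NH-mean trend per season (m2 m-2 decade-1).
    * ``clim_peak``/``clim_min`` — July peak and winter floor of the
      latitude-tapered seasonal climatology (m2 m-2).
    * ``noise_cell_sd`` — white noise per cell-month; averages out in
      NH means.  ``noise_shared_sd`` — a spatially coherent anomaly shared
      by all cells each month, which sets the interannual variability of
      the NH-mean series (and hence the trend standard error).
    * ``pattern`` — optional (nlat, nlon) weights modulating the trend
      spatially (mean ~1); None = uniform.
    """

    season_slopes: dict[Season, float] = field(
        default_factory=lambda: dict(DEFAULT_SEASON_SLOPES)
    )
    clim_peak: float = 2.5
    clim_min: float = 0.3
    noise_cell_sd: float = 0.10
    noise_shared_sd: float = 0.03
    pattern: np.ndarray | None = None
    seed: int = 0

    def climatology(self, lat: np.ndarray, nlon: int) -> np.ndarray:
        """(12, nlat, nlon) seasonal cycle peaking in July, tapered poleward."""
        if self.clim_min < 0 or self.clim_peak < self.clim_min:
            raise ValueError("need 0 <= clim_min <= clim_peak")
        m = np.arange(1, 13)
        cycle = 0.5 * (1.0 - np.cos(2 * np.pi * (m - 1) / 12.0))  # 0 in Jan, 1 in Jul
        taper = np.clip((88.0 - lat) / 45.0, 0.15, 1.0)
        clim = self.clim_min + (self.clim_peak - self.clim_min) * (
            cycle[:, None, None] * taper[None, :, None]
        )
        return np.broadcast_to(clim, (12, lat.size, nlon)).copy()


def generate_lai_scenario(
    scenario: LaiScenario,
    lat: np.ndarray,
    lon: np.ndarray,
    years: tuple[int, int] = (1982, 2014),
) -> GriddedField:
    """Generate the monthly LAI record for the study span.

    LAI(y, m, cell) = clim(m, cell) + slope(season(m)) * (y - y0)/10 *
    pattern(cell) + noise, clipped at zero.  Reproducible under the
    scenario seed.
    """
    y0, y1 = years
    if y1 - y0 + 1 < 2:
        raise ValueError("need at least 2 years")
    lat = np.asarray(lat, dtype=np.float64)
    lon = np.asarray(lon, dtype=np.float64)
    months = month_range(y0, y1)
    clim = scenario.climatology(lat, lon.size)
    pattern = (
        np.ones((lat.size, lon.size))
        if scenario.pattern is None
        else np.asarray(scenario.pattern, dtype=np.float64)
    )
    rng = np.random.default_rng(scenario.seed)
    out = np.empty((len(months), lat.size, lon.size))
    for i, (y, m) in enumerate(months):
        slope = scenario.season_slopes.get(season_of_month(m), 0.0)
        fld = clim[m - 1] + slope * (y - y0) / 10.0 * pattern
        fld = fld + rng.normal(0.0, scenario.noise_shared_sd)
        fld = fld + rng.normal(0.0, scenario.noise_cell_sd, size=fld.shape)
        out[i] = fld
    n_clip = int((out < 0).sum())
    if n_clip:
        logger.debug("LAI generator clipped %d negative cell-months at 0", n_clip)
    np.clip(out, 0.0, None, out=out)
    return GriddedField(out, lat, lon, months=months, units="m2 m-2", name="lai")
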