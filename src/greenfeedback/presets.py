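"""Canonical study conditions for the mechanism experiments.

Each preset fixes one scenario the package's headline mechanism checks run
under: summer-only greening over a wet domain (evaporative cooling),
spring-only greening with a semi-arid band (soil-moisture carryover), and
a warming-winter / cooling-summer background drift (seasonal-amplitude
attenuation).  Keeping them here guarantees the test-suite, the acceptance
script and the analysis drivers all exercise identical conditions.
"""

from __future__ import annotations

import numpy as np

from .grids import GriddedField, Season, climatological_lai_mask, regular_grid
from .lai import DEFAULT_SEASON_SLOPES, LaiScenario, generate_lai_scenario
from .simulator import Forcing, SimParams, default_forcing

__all__ = [
    "STUDY_YEARS",
    "MECHANISM_GRID",
    "DRY_BAND",
    "jja_greening_wet",
    "mam_greening_dry",
    "seasonal_drift_forcing",
    "closure_pair_inputs",
]

# 1981 is spin-up (discarded); 1982-2014 is the analysed 33-year span.
STUDY_YEARS = (1981, 2014)
MECHANISM_GRID = (16, 16)
DRY_BAND = (35.0, 45.0)


def _grid(nlat=None, nlon=None):
    nlat = nlat or MECHANISM_GRID[0]
    nlon = nlon or MECHANISM_GRID[1]
    return regular_grid(nlat, nlon)


def jja_greening_wet(
    seed: int = 0, nlat: int | None = None, nlon: int | None = None
) -> tuple[GriddedField, Forcing, SimParams, np.ndarray]:
    """Summer-only greening over a moisture-unlimited domain.

    Only the JJA LAI trends (at the default summer greening rate); ample
    precipitation everywhere so the evaporative-cooling pathway is
    unobstructed.  Returns (lai, forcing, params, land mask).
    """
    lat, lon = _grid(nlat, nlon)
    slopes = {s: 0.0 for s in Season}
    slopes[Season.JJA] = DEFAULT_SEASON_SLOPES[Season.JJA]
    sc = LaiScenario(season_slopes=slopes, seed=seed)
    lai = generate_lai_scenario(sc, lat, lon, years=STUDY_YEARS)
    forcing = default_forcing(lat, dry_band=None)
    return lai, forcing, SimParams(), climatological_lai_mask(lai)


def mam_greening_dry(
    seed: int = 0, nlat: int | None = None, nlon: int | None = None
) -> tuple[GriddedField, Forcing, SimParams, np.ndarray, np.ndarray]:
    """Spring-only greening with a semi-arid band (soil-moisture carryover).

    Only the MAM LAI trends; precipitation in the 35-45N band is reduced so
    summer evaporation there is bucket-limited.  Extra spring transpiration
    then draws the bucket down before summer, and the deficit carries over.
    Returns (lai, forcing, params, land mask, dry-band row mask).
    """
    lat, lon = _grid(nlat, nlon)
    slopes = {s: 0.0 for s in Season}
    slopes[Season.MAM] = DEFAULT_SEASON_SLOPES[Season.MAM]
    sc = LaiScenario(season_slopes=slopes, seed=seed)
    lai = generate_lai_scenario(sc, lat, lon, years=STUDY_YEARS)
    forcing = default_forcing(lat, dry_band=DRY_BAND)
    band = (lat >= DRY_BAND[0]) & (lat < DRY_BAND[1])
    band_mask = np.broadcast_to(band[:, None], (lat.size, lon.size))
    return lai, forcing, SimParams(), climatological_lai_mask(lai), band_mask


def seasonal_drift_forcing(
    seed: int = 0, nlat: int | None = None, nlon: int | None = None,
    winter_rate: float = 0.5,
) -> tuple[GriddedField, Forcing, SimParams, np.ndarray]:
    """Warming-winter / cooling-summer background drift.

    The background air temperature trend follows +winter_rate K decade-1 in
    January fading to -winter_rate in July (cosine over the calendar), on
    top of the default LAI scenario.  The July-minus-January amplitude of
    the simulated climate must then shrink.
    """
    lat, lon = _grid(nlat, nlon)
    trend = winter_rate * np.cos(2 * np.pi * (np.arange(1, 13) - 1) / 12.0)
    forcing = default_forcing(lat, t_bg_trend=trend)
    lai = generate_lai_scenario(LaiScenario(seed=seed), lat, lon,
                                years=STUDY_YEARS)
    return lai, forcing, SimParams(), climatological_lai_mask(lai)


def closure_pair_inputs(
    seed: int = 2, nlat: int = 8, nlon: int = 8, years=(2000, 2007)
) -> tuple[GriddedField, Forcing, SimParams]:
    """Noise-free, circulation-quiet setup for linearisation checks."""
    lat, lon = _grid(nlat, nlon)
    sc = LaiScenario(seed=seed, noise_cell_sd=0.0, noise_shared_sd=0.0)
    lai = generate_lai_scenario(sc, lat, lon, years=years)
    return lai, default_forcing(lat, dry_band=None), SimParams(ar1_sd=0.0)
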