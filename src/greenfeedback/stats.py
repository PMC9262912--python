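"""Trend, significance, amplitude, correlation and phase-space diagnostics.

Trends are ordinary least squares on yearly series, reported per decade
with the two-sided t-test p-value (n-2 degrees of freedom, independent
residuals assumed) and the conventional star classes (*** p<0.01,
** p<0.05, * p<0.1).  The seasonal amplitude of temperature (SAT) is July
minus January air temperature, one value per year.  The phase-space
summary bins a response-trend map in the plane of two driver-trend maps
(soil moisture, z500) and reports binned means plus the marginal partial
dependence on each driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .grids import GriddedField, YearlyField, area_weighted_mean

__all__ = [
    "TrendResult",
    "SatSeries",
    "ols_trend",
    "ols_trend_field",
    "sat_amplitude",
    "lai_delta_correlation",
    "PhaseSpaceSummary",
    "phase_space_summary",
    "latitudinal_profile",
    "stipple_mask",
]

logger = logging.getLogger(__name__)


def _star_class(p: float) -> str:
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return "n.s."


@dataclass
class TrendResult:
    """OLS linear trend of a yearly series, scaled per decade."""

    slope_per_decade: float
    se_per_decade: float
    p_value: float
    significance: str
    n: int

    @classmethod
    def from_fit(cls, slope: float, se: float, p: float, n: int) -> "TrendResult":
        return cls(slope * 10.0, se * 10.0, p, _star_class(p), n)


def ols_trend(years, values) -> TrendResult:
    """OLS trend of a yearly scalar series (units per decade)."""
    years = np.asarray(years, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if years.size != values.size or years.size < 3:
        raise ValueError("need >= 3 paired (year, value) points")
    res = sps.linregress(years, values)
    se, p = res.stderr, res.pvalue
    if not np.isfinite(se) or se == 0.0:
        # exact line (or exact constant): no residual variance
        se = 0.0
        p = 0.0 if res.slope != 0.0 else 1.0
    return TrendResult.from_fit(res.slope, se, p, years.size)


def ols_trend_field(fld: YearlyField) -> dict[str, np.ndarray]:
    """Per-cell OLS trends of a yearly field (vectorised).

    Returns maps of slope and SE per decade and the two-sided p-value;
    cells with any missing year come back NaN.
    """
    y = fld.years.astype(np.float64)
    v = fld.values
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 years")
    yc = y - y.mean()
    sxx = (yc**2).sum()
    valid = np.all(np.isfinite(v), axis=0)
    vv = np.where(np.isfinite(v), v, 0.0)
    slope = np.tensordot(yc, vv, axes=(0, 0)) / sxx
    resid = vv - vv.mean(axis=0) - slope[None] * yc[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (resid**2).sum(axis=0) / (n - 2)
        se = np.sqrt(s2 / sxx)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf * np.sign(slope))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(se == 0, np.where(slope == 0, 1.0, 0.0), p)
    nanify = lambda a: np.where(valid, a, np.nan)
    return {
        "slope_per_decade": nanify(slope * 10.0),
        "se_per_decade": nanify(se * 10.0),
        "p_value": nanify(p),
        "n": n,
    }


@dataclass
class SatSeries:
    """Per-year seasonal amplitude: July minus January air temperature."""

    years: np.ndarray
    values: np.ndarray  # K
    units: str = "K"


def sat_amplitude(ta) -> SatSeries:
    """SAT series from a monthly field or a (months, values) scalar series.

    Accepts a monthly :class:`GriddedField` (NH mean is taken with cosine
    weights) or a tuple ``(months, values)`` of an already-reduced scalar
    series.  One value per year that has both July and January.
    """
    if isinstance(ta, GriddedField):
        months = ta.months
        series = area_weighted_mean(ta)
    else:
        months, series = ta
        series = np.asarray(series, dtype=np.float64)
    if months is None:
        raise ValueError("sat_amplitude needs a monthly time axis")
    idx = {ym: i for i, ym in enumerate(months)}
    years, values = [], []
    for y in sorted({yy for yy, _ in months}):
        if (y, 7) in idx and (y, 1) in idx:
            years.append(y)
            values.append(series[idx[(y, 7)]] - series[idx[(y, 1)]])
    if not years:
        raise ValueError("no year has both July and January")
    return SatSeries(years=np.array(years), values=np.array(values))


def lai_delta_correlation(
    x, y, detrend: bool = False
) -> tuple[float, float]:
    """Pearson correlation between two yearly series (e.g. LAI vs dT_a).

    With ``detrend=True`` each series has its own OLS linear trend removed
    first, so a shared secular trend cannot masquerade as covariability.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series with >= 3 points")
    if detrend:
        t = np.arange(x.size, dtype=np.float64)
        x = x - np.polynomial.polynomial.polyval(t, np.polynomial.polynomial.polyfit(t, x, 1))
        y = y - np.polynomial.polynomial.polyval(t, np.polynomial.polynomial.polyfit(t, y, 1))
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PhaseSpaceSummary:
    """Binned response surface over two driver axes plus marginals."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    surface: np.ndarray  # (nx, ny) mean response, NaN where dropped
    counts: np.ndarray
    x_centers: np.ndarray
    y_centers: np.ndarray
    marginal_x: np.ndarray  # mean response per x bin
    marginal_y: np.ndarray
    x_bin_means: np.ndarray  # mean driver value per bin (use for slope fits:
    y_bin_means: np.ndarray  # edge-bin centers are biased abscissae)


def phase_space_summary(
    response: np.ndarray,
    driver_x: np.ndarray,
    driver_y: np.ndarray,
    bins: int = 20,
    min_count: int = 5,
) -> PhaseSpaceSummary:
    """Bin a response map in the plane of two driver maps.

    All three maps must be aligned; NaN cells are dropped.  Bins holding
    fewer than ``min_count`` cells are blanked (logged).  Marginals are
    the binned means along each single axis — the empirical partial
    dependence of the response on that driver.
    """
    r = np.asarray(response, dtype=np.float64).ravel()
    x = np.asarray(driver_x, dtype=np.float64).ravel()
    y = np.asarray(driver_y, dtype=np.float64).ravel()
    ok = np.isfinite(r) & np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        raise ValueError("no valid cells")
    r, x, y = r[ok], x[ok], y[ok]
    surf, xe, ye, _ = sps.binned_statistic_2d(x, y, r, statistic="mean", bins=bins)
    cnt, _, _, _ = sps.binned_statistic_2d(x, y, r, statistic="count", bins=(xe, ye))
    dropped = int(((cnt > 0) & (cnt < min_count)).sum())
    if dropped:
        logger.debug("phase space: blanked %d bins below min_count=%d",
                     dropped, min_count)
    surf = np.where(cnt >= min_count, surf, np.nan)
    mx, _, _ = sps.binned_statistic(x, r, statistic="mean", bins=xe)
    cx, _, _ = sps.binned_statistic(x, r, statistic="count", bins=xe)
    my, _, _ = sps.binned_statistic(y, r, statistic="mean", bins=ye)
    cy, _, _ = sps.binned_statistic(y, r, statistic="count", bins=ye)
    bx, _, _ = sps.binned_statistic(x, x, statistic="mean", bins=xe)
    by, _, _ = sps.binned_statistic(y, y, statistic="mean", bins=ye)
    mx = np.where(cx >= min_count, mx, np.nan)
    my = np.where(cy >= min_count, my, np.nan)
    return PhaseSpaceSummary(
        x_edges=xe, y_edges=ye, surface=surf, counts=cnt,
        x_centers=0.5 * (xe[:-1] + xe[1:]), y_centers=0.5 * (ye[:-1] + ye[1:]),
        marginal_x=mx, marginal_y=my,
        x_bin_means=np.where(cx >= min_count, bx, np.nan),
        y_bin_means=np.where(cy >= min_count, by, np.nan),
    )


def latitudinal_profile(
    trend_map: np.ndarray, lat: np.ndarray, band_width_deg: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine-weighted band means of a map; returns (band_centers, means)."""
    trend_map = np.asarray(trend_map, dtype=np.float64)
    lat = np.asarray(lat, dtype=np.float64)
    lo = np.floor(lat.min() / band_width_deg) * band_width_deg
    hi = np.ceil(lat.max() / band_width_deg) * band_width_deg
    edges = np.arange(lo, hi + band_width_deg / 2, band_width_deg)
    centers, means = [], []
    w_lat = np.cos(np.deg2rad(lat))
    for e0, e1 in zip(edges[:-1], edges[1:]):
        rows = (lat >= e0) & (lat < e1)
        if not rows.any():
            continue
        block = trend_map[rows]
        w = (w_lat[rows][:, None] * np.ones((1, trend_map.shape[1])))
        ok = np.isfinite(block)
        tot = w[ok].sum()
        centers.append(0.5 * (e0 + e1))
        means.append(np.nan if tot == 0 else float((w[ok] * block[ok]).sum() / tot))
    return np.array(centers), np.array(means)


def stipple_mask(
    p_map: np.ndarray, alpha: float = 0.05, land_mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Significance stipple: True where p < alpha; plus the area fraction.

    The fraction is the share of unmasked land cells whose trend is
    significant at ``alpha`` (unweighted cell count, no multiplicity
    correction).
    """
    p_map = np.asarray(p_map, dtype=np.float64)
    sig = np.isfinite(p_map) & (p_map < alpha)
    if land_mask is not None:
        sig = sig & np.asarray(land_mask, dtype=bool)
        denom = int(np.asarray(land_mask, dtype=bool).sum())
    else:
        denom = int(np.isfinite(p_map).sum())
    frac = sig.sum() / denom if denom else 0.0
    return sig, float(frac)
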