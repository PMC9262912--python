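"""End-to-end toy study: scenario -> ensembles -> deltas -> decomposition
-> seasonal statistics -> figure-ready tables.

``run_study`` reproduces the full analysis chain at a configurable scale
and writes plain-text tables: seasonal intra-/inter-seasonal temperature
trends, the monthly response-trend matrix, forcing-component trends with
radiative/non-radiative grouping, the seasonal-amplitude (SAT) series, a
phase-space summary of the carried-over response, and ensemble sign
agreement.  Identical configuration and seeds give byte-identical tables;
every output directory carries a manifest with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decomposition as dec
from .experiments import (
    DeltaField,
    ExperimentSet,
    build_experiment_set,
    delta_field,
    lagged_sum,
    sign_agreement,
    split_intra_inter,
)
from .grids import GriddedField, Season, climatological_lai_mask
from .lai import LaiScenario, generate_lai_scenario
from .simulator import SimParams, default_forcing
from .stats import (
    ols_trend,
    ols_trend_field,
    phase_space_summary,
    sat_amplitude,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "write_tables"]

logger = logging.getLogger(__name__)

GROWING = (Season.MAM, Season.JJA, Season.SON)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one toy study."""

    nlat: int = 16
    nlon: int = 16
    lat_bounds: tuple[float, float] = (25.0, 90.0)
    years: tuple[int, int] = (1981, 2014)  # first year is spin-up
    members: int = 30
    seed_base: int = 1000
    discard_years: int = 1
    seasons: tuple[str, ...] = ("MAM", "JJA", "SON")
    scenario: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    phase_bins: int = 20
    phase_min_count: int = 5

    def __post_init__(self) -> None:
        if self.members < 1:
            raise ValueError("members must be >= 1")
        if self.years[1] <= self.years[0]:
            raise ValueError("need a multi-year span")
        bad = [s for s in self.seasons if s not in {"MAM", "JJA", "SON"}]
        if bad:
            raise ValueError(f"controls only exist for growing seasons, got {bad}")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lat_bounds", "years", "seasons"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def canonical(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def seeds(self) -> list[int]:
        return [self.seed_base + i for i in range(self.members)]


@dataclass
class StudyResult:
    """Figure-ready tables of one study run."""

    config: StudyConfig
    tables: dict[str, pd.DataFrame]
    experiment: ExperimentSet | None = None
    mask: np.ndarray | None = None

    def summary_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(_table_bytes(self.tables[name]))
        return h.hexdigest()


def _table_bytes(df: pd.DataFrame) -> bytes:
    return df.to_csv(index=False, float_format="%.10g").encode()


def _nh_mean_series(delta: DeltaField, mask: np.ndarray) -> np.ndarray:
    # DeltaField months may be non-contiguous, so reduce without GriddedField
    w = np.cos(np.deg2rad(delta.lat))[:, None] * np.ones((1, delta.lon.size))
    w = np.where(mask, w, 0.0)
    out = np.empty(delta.values.shape[0])
    for t in range(delta.values.shape[0]):
        v = delta.values[t]
        ok = np.isfinite(v) & (w > 0)
        tot = w[ok].sum()
        if tot == 0:
            raise ValueError("all cells masked")
        out[t] = (w[ok] * v[ok]).sum() / tot
    return out


def _seasonal_yearly(delta: DeltaField, season: Season, mask: np.ndarray):
    """Yearly seasonal means of the NH-mean Delta series (DJF spans years)."""
    series = _nh_mean_series(delta, mask)
    idx = {ym: i for i, ym in enumerate(delta.months)}
    years, vals = [], []
    for y in sorted({yy for yy, _ in delta.months}):
        if season is Season.DJF:
            wanted = [(y, 12), (y + 1, 1), (y + 1, 2)]
        else:
            from .grids import SEASON_MONTHS
            wanted = [(y, m) for m in SEASON_MONTHS[season]]
        if all(w in idx for w in wanted):
            years.append(y)
            vals.append(np.mean([series[idx[w]] for w in wanted]))
    return np.array(years), np.array(vals)


def _control_baseline(exp: ExperimentSet, season: Season) -> dict[str, np.ndarray]:
    """Per-calendar-month climatology of the control ensemble mean."""
    from .experiments import ensemble_mean
    base = {}
    months = exp.sce[0]["t_a"].months
    for var in ("s_dn", "alpha", "r_a", "t_s", "t_a"):
        em = ensemble_mean(exp.controls[season], var)
        clim = np.empty_like(em.values)
        for m in range(1, 13):
            rows = [i for i, (_, mm) in enumerate(months) if mm == m]
            clim[rows] = np.mean(em.values[rows], axis=0)
        base[var] = clim
    return base


def run_study(config: StudyConfig, keep_experiment: bool = False) -> StudyResult:
    """Run the full toy study and return its tables."""
    from .grids import regular_grid

    lat, lon = regular_grid(config.nlat, config.nlon, config.lat_bounds)
    forcing = default_forcing(lat)
    scenario = LaiScenario(**config.scenario)
    lai = generate_lai_scenario(scenario, lat, lon, years=config.years)
    mask = climatological_lai_mask(lai)
    params = SimParams(**config.params)
    seasons = [Season(s) for s in config.seasons]

    exp = build_experiment_set(
        lai, forcing, params, config.seeds(), seasons=seasons,
        discard_years=config.discard_years,
    )
    deltas = {s: delta_field(exp, "t_a", s) for s in seasons}

    tables: dict[str, pd.DataFrame] = {}

    # --- seasonal intra/inter trend table (Delta T_a, degC per decade)
    rows = []
    for s in seasons:
        parts = split_intra_inter(deltas[s])
        y_i, v_i = _seasonal_yearly(parts["intra"], s, mask)
        tr_i = ols_trend(y_i, v_i)
        row = {"season": s.value, "kind": "intra",
               "slope_degC_per_decade": tr_i.slope_per_decade,
               "se": tr_i.se_per_decade, "p": tr_i.p_value,
               "class": tr_i.significance}
        rows.append(row)
    if set(seasons) >= set(GROWING):
        for s in list(GROWING) + [Season.DJF]:
            lag = lagged_sum(deltas, s)
            y_l, v_l = _seasonal_yearly(lag, s, mask)
            tr_l = ols_trend(y_l, v_l)
            rows.append({"season": s.value, "kind": "inter",
                         "slope_degC_per_decade": tr_l.slope_per_decade,
                         "se": tr_l.se_per_decade, "p": tr_l.p_value,
                         "class": tr_l.significance})
    tables["delta_ta_trends"] = pd.DataFrame(rows)

    # --- monthly Delta trend matrix (one row per control + combined)
    month_rows = []
    combined = None
    for s in seasons:
        series = _nh_mean_series(deltas[s], mask)
        if combined is None:
            combined = series.copy()
        else:
            combined = combined + series
        row = {"control": s.value}
        for m in range(1, 13):
            idx = [i for i, (_, mm) in enumerate(deltas[s].months) if mm == m]
            years = np.array([deltas[s].months[i][0] for i in idx])
            tr = ols_trend(years, series[idx])
            row[f"m{m:02d}"] = tr.slope_per_decade
        month_rows.append(row)
    if combined is not None and len(seasons) == 3:
        row = {"control": "combined"}
        s0 = seasons[0]
        for m in range(1, 13):
            idx = [i for i, (_, mm) in enumerate(deltas[s0].months) if mm == m]
            years = np.array([deltas[s0].months[i][0] for i in idx])
            tr = ols_trend(years, combined[idx])
            row[f"m{m:02d}"] = tr.slope_per_decade
        month_rows.append(row)
    tables["monthly_delta_trends"] = pd.DataFrame(month_rows)

    # --- forcing-component trends per season (W m-2 per decade)
    comp_rows = []
    for s in seasons:
        baseline = _control_baseline(exp, s)
        dvals = {
            var: delta_field(exp, var, s).values
            for var in ("alpha", "s_dn", "lam_e", "r_a", "eps_a")
        }
        comps = dec.forcing_components(baseline, dvals)
        groups = dec.group_r_nr(comps)
        named = dict(comps.as_dict())
        named.update(groups)
        months = deltas[s].months
        for name, vals in named.items():
            d = DeltaField(vals, deltas[s].lat, deltas[s].lon, months,
                           variable=name, control_season=s, units="W m-2")
            yy, vv = _seasonal_yearly(d, s, mask)
            tr = ols_trend(yy, vv)
            comp_rows.append({
                "season": s.value, "component": name,
                "slope_wm2_per_decade": tr.slope_per_decade,
                "se": tr.se_per_decade, "p": tr.p_value, "class": tr.significance,
            })
    tables["forcing_component_trends"] = pd.DataFrame(comp_rows)

    # --- SAT: seasonal amplitude of SCE and of the induced combined signal
    from .experiments import ensemble_mean
    sce_ta = ensemble_mean(exp.sce, "t_a")
    sat_rows = []
    sat_sce = sat_amplitude((sce_ta.months, _nh_mean_series(
        DeltaField(sce_ta.values, sce_ta.lat, sce_ta.lon, list(sce_ta.months),
                   "t_a", seasons[0]), mask)))
    if len(seasons) == 3:
        comb_months = deltas[seasons[0]].months
        comb_vals = sum(_nh_mean_series(deltas[s], mask) for s in seasons)
        sat_ind = sat_amplitude((comb_months, comb_vals))
        for y, v_s, v_i in zip(sat_sce.years, sat_sce.values, sat_ind.values):
            sat_rows.append({"year": int(y), "sat_sce_K": v_s, "sat_induced_K": v_i})
    else:
        for y, v_s in zip(sat_sce.years, sat_sce.values):
            sat_rows.append({"year": int(y), "sat_sce_K": v_s})
    tables["sat_series"] = pd.DataFrame(sat_rows)
    trow = []
    tr = ols_trend(sat_sce.years, sat_sce.values)
    trow.append({"series": "sat_sce", "slope_K_per_decade": tr.slope_per_decade,
                 "se": tr.se_per_decade, "p": tr.p_value, "class": tr.significance})
    if len(seasons) == 3:
        tr = ols_trend(sat_ind.years, sat_ind.values)
        trow.append({"series": "sat_induced",
                     "slope_K_per_decade": tr.slope_per_decade,
                     "se": tr.se_per_decade, "p": tr.p_value,
                     "class": tr.significance})
    tables["sat_trends"] = pd.DataFrame(trow)

    # --- phase space of the carried-over response (per control season)
    ps_rows = []
    for s in seasons:
        parts = split_intra_inter(deltas[s])
        dsm = split_intra_inter(delta_field(exp, "sm", s))["inter"]
        dz = split_intra_inter(delta_field(exp, "z500", s))["inter"]
        # annual-mean inter-seasonal deltas per year, then per-cell trends
        maps = {}
        for nm, d in (("t_a", parts["inter"]), ("sm", dsm), ("z500", dz)):
            years = sorted({yy for yy, _ in d.months})
            stack = []
            kept_years = []
            for y in years:
                rows_y = [i for i, (yy, _) in enumerate(d.months) if yy == y]
                if rows_y:
                    kept_years.append(y)
                    stack.append(np.mean(d.values[rows_y], axis=0))
            from .grids import YearlyField
            yf = YearlyField(np.array(stack), d.lat, d.lon, np.array(kept_years))
            res = ols_trend_field(yf)
            maps[nm] = np.where(mask, res["slope_per_decade"], np.nan)
        try:
            ps = phase_space_summary(
                maps["t_a"], maps["z500"], maps["sm"],
                bins=config.phase_bins, min_count=config.phase_min_count,
            )
        except ValueError:
            continue
        for c, v in zip(ps.x_centers, ps.marginal_x):
            ps_rows.append({"control": s.value, "axis": "z500_trend",
                            "bin_center": c, "mean_dta_trend": v})
        for c, v in zip(ps.y_centers, ps.marginal_y):
            ps_rows.append({"control": s.value, "axis": "sm_trend",
                            "bin_center": c, "mean_dta_trend": v})
    tables["phase_space_marginals"] = pd.DataFrame(ps_rows)

    # --- ensemble sign agreement of the JJA intra-seasonal response
    sign_rows = []
    for s in seasons:
        per_member = []
        ctl = exp.controls[s]
        for m_sce, m_ctl in zip(exp.sce, ctl):
            d = DeltaField(
                m_sce["t_a"].values - m_ctl["t_a"].values,
                lai.lat, lai.lon, list(m_sce["t_a"].months), "t_a", s,
            )
            yy, vv = _seasonal_yearly(d, s, mask)
            tr = ols_trend(yy, vv)
            per_member.append(tr.slope_per_decade)
        count, frac = sign_agreement(np.array(per_member))
        sign_rows.append({"season": s.value, "agreeing_members": count,
                          "members": len(per_member), "fraction": frac})
    tables["sign_agreement"] = pd.DataFrame(sign_rows)

    return StudyResult(config=config, tables=tables,
                       experiment=exp if keep_experiment else None, mask=mask)


def write_tables(result: StudyResult, out_dir) -> Path:
    """Write all tables and the manifest; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        (out / f"{name}.csv").write_bytes(_table_bytes(df))
    manifest = {
        "config_hash": result.config.config_hash(),
        "summary_hash": result.summary_hash(),
        "config": json.loads(result.config.canonical()),
        "tables": sorted(result.tables),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
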