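"""A minimal LAI-driven land-atmosphere column model on the grid.

One column per grid cell, monthly time step, no diurnal cycle.  Each month
the model:

1. maps LAI and the prescribed snow state to surface albedo (exponential
   canopy masking of the brighter ground/snow) and to aerodynamic
   resistance (denser canopies couple the surface to the air more
   efficiently);
2. diagnoses an evaporative fraction beta from LAI, bucket soil moisture
   and temperature (the Clausius-Clapeyron slope makes latent heat a more
   efficient sink when it is warm);
3. lets column humidity track the recent latent-heat history, which raises
   the air longwave emissivity eps_a (water-vapor feedback) and slightly
   dims downward shortwave;
4. solves the surface energy balance S_net + L_net = H + lambda_E by
   Newton iteration, with the near-surface air temperature coupled to the
   surface (T_a = w*T_s + (1-w)*T_bg + b*z500) so the accepted state closes
   the balance with the *reported* T_a;
5. updates the soil-moisture bucket (precip in, evaporation and runoff
   out), carrying moisture anomalies across months and seasons;
6. advances a seeded AR(1) circulation proxy (z500) shared across the
   member, plus a humidity-forced component, which feeds back on T_a.

Ground heat flux is neglected: on monthly and interannual scales soil heat
storage is a small residual of the balance.  All fields are exchanged as
numpy arrays over the (lat, lon) grid; runs are bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import GriddedField

__all__ = [
    "SimParams",
    "Forcing",
    "SimOutput",
    "default_forcing",
    "albedo_from_lai",
    "aerodynamic_resistance_from_lai",
    "evaporative_fraction",
    "svp_slope",
    "solve_surface_temperature",
    "step_soil_moisture",
    "air_emissivity",
    "simulate_run",
    "SECONDS_PER_MONTH",
    "LATENT_HEAT_VAPORIZATION",
]

SECONDS_PER_MONTH = 2.6298e6  # 365.25/12 days
LATENT_HEAT_VAPORIZATION = 2.5e6  # J kg-1


@dataclass
class SimParams:
    """Physical constants and tunable parameters of the toy model.

    The four physical constants match the decomposition's convention:
    surface emissivity 0.95, Stefan-Boltzmann 5.67e-8 W m-2 K-4, air
    density 1.205 kg m-3, specific heat 1013 J kg-1 K-1.
    """

    # constants shared with the decomposition
    eps_s: float = 0.95
    sigma: float = 5.67e-8
    rho: float = 1.205
    cp: float = 1013.0

    # albedo: alpha = a_canopy + (a_ground|a_snow - a_canopy) * exp(-k*LAI)
    alpha_canopy: float = 0.15
    alpha_ground: float = 0.25
    alpha_snow: float = 0.70
    k_ext: float = 0.5  # canopy extinction, also drives T/ET share

    # evaporative fraction
    beta_max: float = 0.75
    soil_evap: float = 0.08  # bare-soil evaporation relative to closed canopy
    sm_stress_point: float = 0.45  # beta ramps linearly below this bucket fill
    gamma_psy: float = 66.0  # psychrometric constant, Pa K-1

    # aerodynamic resistance: r_a = r_a0 / (1 + c_ra * LAI)
    r_a0: float = 120.0
    c_ra: float = 0.25

    # bucket hydrology
    capacity_mm: float = 150.0
    runoff_coef: float = 0.10  # per month, times SM

    # air coupling and humidity/emissivity feedback
    w_air: float = 0.6  # T_a = w*T_s + (1-w)*T_bg + b*z500
    b_z500: float = 0.02  # K per m of z500 anomaly
    eps_dry: float = 0.72
    eps_gain: float = 0.10  # eps_a increase per unit normalised humidity
    eps_max: float = 0.95
    lam_ref: float = 120.0  # W m-2, latent-heat normalisation for humidity
    q_memory: float = 0.5  # humidity EMA weight on the newest month
    sdn_dim: float = 0.03  # fractional S_dn dimming per unit humidity

    # circulation proxy (AR(1) scalar mode times a fixed spatial pattern,
    # plus a humidity-forced local component)
    ar1_rho: float = 0.7
    ar1_sd: float = 8.0  # m, innovation SD; 0 disables internal variability
    z_gain: float = 30.0  # m per unit humidity anomaly (greening -> high)
    q_ref: float = 0.35

    # Newton solver
    newton_tol_flux: float = 1e-3  # W m-2
    newton_tol_dt: float = 1e-6  # K
    newton_max_iter: int = 50

    def replace(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class Forcing:
    """Prescribed zonally symmetric monthly boundary conditions.

    All arrays are (12, nlat): downward shortwave at the surface before
    humidity dimming (W m-2), background free-air temperature (K), monthly
    precipitation (mm), and the prescribed snow flag.  ``t_bg_trend``
    (K decade-1 per calendar month) imposes a secular background drift,
    used e.g. to force a warming-winter / cooling-summer climate.
    """

    s_dn0: np.ndarray
    t_bg: np.ndarray
    precip_mm: np.ndarray
    snow: np.ndarray
    t_bg_trend: np.ndarray | None = None

    def background_t(self, month: int, year_frac: float) -> np.ndarray:
        t = self.t_bg[month - 1]
        if self.t_bg_trend is not None:
            t = t + self.t_bg_trend[month - 1] * year_frac / 10.0
        return t


def default_forcing(
    lat: np.ndarray,
    dry_band: tuple[float, float] | None = (35.0, 45.0),
    dry_factor: float = 0.40,
    t_bg_trend: np.ndarray | None = None,
) -> Forcing:
    """Idealised northern-hemisphere seasonal cycles on a latitude column.

    Insolation follows a solar-declination cosine; background air
    temperature has a latitude-increasing annual amplitude; precipitation
    is weakly summer-peaked with an optional semi-arid band where the
    bucket runs moisture-limited in summer.  Snow is prescribed wherever
    the background air is below -2 degC.
    """
    lat = np.asarray(lat, dtype=np.float64)
    m = np.arange(1, 13)[:, None]
    decl = 23.44 * np.sin(2 * np.pi * (m - 3.0) / 12.0)
    s_dn0 = np.maximum(20.0, 330.0 * np.cos(np.deg2rad(lat[None, :] - decl)))
    t_ann = 302.0 - 0.60 * lat
    amp = 3.0 + 0.28 * lat
    t_bg = t_ann[None, :] - amp[None, :] * np.cos(2 * np.pi * (m - 1.0) / 12.0)
    precip = 80.0 * (1.0 + 0.30 * np.cos(2 * np.pi * (m - 7.0) / 12.0)) * np.ones_like(t_bg)
    if dry_band is not None:
        band = (lat >= dry_band[0]) & (lat < dry_band[1])
        precip[:, band] *= dry_factor
    snow = t_bg < 271.15
    return Forcing(s_dn0=s_dn0, t_bg=t_bg, precip_mm=precip, snow=snow,
                   t_bg_trend=t_bg_trend)


# ---------------------------------------------------------------------------
# pointwise physics (vectorised over arrays)

def albedo_from_lai(lai, snow, p: SimParams):
    """Exponential canopy masking of the ground (or snow) albedo."""
    lai = np.asarray(lai, dtype=np.float64)
    base = np.where(snow, p.alpha_snow, p.alpha_ground)
    return p.alpha_canopy + (base - p.alpha_canopy) * np.exp(-p.k_ext * lai)


def aerodynamic_resistance_from_lai(lai, p: SimParams):
    """Denser canopies are rougher: r_a falls hyperbolically with LAI."""
    lai = np.asarray(lai, dtype=np.float64)
    return p.r_a0 / (1.0 + p.c_ra * lai)


def svp_slope(t_kelvin):
    """Slope of saturation vapour pressure (Pa K-1), Magnus form."""
    tc = np.asarray(t_kelvin, dtype=np.float64) - 273.15
    es = 610.94 * np.exp(17.625 * tc / (tc + 243.04))
    return 4098.0 * es / (tc + 243.04) ** 2


def evaporative_fraction(lai, sm, t_s, p: SimParams, snow=False):
    """Fraction beta of available energy going to latent heat, and T/ET.

    beta = beta_max * cover * stress(SM) * s(T)/(s(T)+gamma): vegetation
    cover saturates exponentially in LAI (with a small bare-soil floor),
    the bucket stress ramps linearly below the stress point, and the
    Clausius-Clapeyron slope favours evaporation in warm months.  Snow
    shuts transpiration down to the bare-soil floor.  The transpiration
    share of total evapotranspiration is the canopy cover fraction itself.
    """
    lai = np.asarray(lai, dtype=np.float64)
    sm = np.asarray(sm, dtype=np.float64)
    f_veg = 1.0 - np.exp(-p.k_ext * lai)
    f_veg_eff = np.where(snow, 0.0, f_veg)
    cover = f_veg_eff + p.soil_evap * (1.0 - f_veg_eff)
    stress = np.clip(sm / p.sm_stress_point, 0.0, 1.0)
    s = svp_slope(t_s)
    beta = p.beta_max * cover * stress * s / (s + p.gamma_psy)
    total = cover
    t_share = np.where(total > 0, f_veg_eff / np.where(total > 0, total, 1.0), 0.0)
    return beta, t_share


def solve_surface_temperature(
    s_dn, alpha, eps_a, t_a, r_a, beta, p: SimParams,
    t_bg=None, w_air: float = 0.0, t_init=None,
):
    """Newton solve of the surface energy balance for T_s.

    With ``w_air = 0`` the air temperature is held fixed at ``t_a``
    (the classic offline balance).  With ``w_air > 0`` the air couples to
    the surface, T_a = w*T_s + (1-w)*t_bg_eff, where ``t_bg_eff`` already
    contains the circulation term; the balance is then closed with the
    coupled T_a, so the accepted state satisfies
    |S_net + L_net - H - lambda_E| < tol with the reported air temperature.

    lambda_E = beta * max(0, S_net + L_net); returns a dict of T_s, T_a and
    all fluxes.  Raises on non-convergence with the worst residual.
    """
    s_dn = np.asarray(s_dn, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    eps_a = np.asarray(eps_a, dtype=np.float64)
    r_a = np.asarray(r_a, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if w_air > 0.0:
        t_bg_eff = np.asarray(t_bg, dtype=np.float64)
    else:
        t_bg_eff = np.asarray(t_a, dtype=np.float64)

    def air_t(t_s):
        if w_air > 0.0:
            return w_air * t_s + (1.0 - w_air) * t_bg_eff
        return t_bg_eff

    es_sig = p.eps_s * p.sigma
    rcp_ra = p.rho * p.cp / r_a

    t_s = np.array(t_init if t_init is not None else air_t(t_bg_eff),
                   dtype=np.float64, copy=True)
    if t_s.shape != np.broadcast_shapes(s_dn.shape, t_s.shape):
        t_s = np.broadcast_to(t_s, s_dn.shape).copy()

    converged = np.zeros(t_s.shape, dtype=bool) if t_s.ndim else np.zeros((), bool)
    for _ in range(p.newton_max_iter):
        ta = air_t(t_s)
        avail = s_dn * (1.0 - alpha) + es_sig * (eps_a * ta**4 - t_s**4)
        pos = avail > 0.0
        h = rcp_ra * (t_s - ta)
        f = avail * (1.0 - beta * pos) - h
        d_avail = es_sig * (4.0 * eps_a * ta**3 * w_air - 4.0 * t_s**3)
        d_h = rcp_ra * (1.0 - w_air)
        df = d_avail * (1.0 - beta * pos) - d_h
        step = np.clip(f / np.where(np.abs(df) > 1e-12, df, -1e-12), -20.0, 20.0)
        t_s_new = t_s - step
        converged = (np.abs(f) < p.newton_tol_flux) & (
            np.abs(t_s_new - t_s) < p.newton_tol_dt
        )
        t_s = t_s_new  # converged cells take a (vanishing) extra step
        if np.all(converged):
            break
    else:
        ta = air_t(t_s)
        avail = s_dn * (1.0 - alpha) + es_sig * (eps_a * ta**4 - t_s**4)
        h = rcp_ra * (t_s - ta)
        resid = avail * (1.0 - beta * (avail > 0)) - h
        raise RuntimeError(
            f"surface-balance Newton did not converge in {p.newton_max_iter} "
            f"iterations; worst residual {np.nanmax(np.abs(resid)):.3e} W m-2"
        )

    ta = air_t(t_s)
    s_net = s_dn * (1.0 - alpha)
    l_net = es_sig * (eps_a * ta**4 - t_s**4)
    avail = s_net + l_net
    lam_e = beta * np.maximum(0.0, avail)
    h = rcp_ra * (t_s - ta)
    return {
        "t_s": t_s, "t_a": ta, "s_net": s_net, "l_net": l_net,
        "lam_e": lam_e, "h": h,
    }


def step_soil_moisture(sm, precip_mm, lam_e, p: SimParams):
    """Advance the bucket one month; returns (sm_new, diagnostics).

    Evaporation draws the bucket down at lambda_E converted to water depth;
    runoff is a linear leak.  Both are limited so the bucket cannot go
    negative, and any excess above capacity leaves as overflow, so the
    budget precip - evap - runoff - overflow = d(SM)*capacity closes
    exactly.
    """
    sm = np.asarray(sm, dtype=np.float64)
    precip_mm = np.asarray(precip_mm, dtype=np.float64)
    if np.any(precip_mm < 0):
        raise ValueError("negative precipitation")
    evap_mm = np.asarray(lam_e, dtype=np.float64) * SECONDS_PER_MONTH / (
        LATENT_HEAT_VAPORIZATION
    )  # kg m-2 == mm
    runoff_mm = p.runoff_coef * sm * p.capacity_mm
    store = sm * p.capacity_mm + precip_mm
    # evaporation first, then runoff, each limited by what is left
    evap_act = np.minimum(evap_mm, store)
    store = store - evap_act
    runoff_act = np.minimum(runoff_mm, store)
    store = store - runoff_act
    overflow = np.maximum(0.0, store - p.capacity_mm)
    store = store - overflow
    sm_new = store / p.capacity_mm
    diag = {"evap_mm": evap_act, "runoff_mm": runoff_act + overflow}
    return sm_new, diag


def air_emissivity(q, p: SimParams):
    """Longwave emissivity of the air column given normalised humidity q.

    q is the exponential moving average of lambda_E / lam_ref; moister
    columns trap more outgoing longwave (water-vapor feedback).
    """
    return np.minimum(p.eps_max, p.eps_dry + p.eps_gain * np.asarray(q))


@dataclass
class SimOutput:
    """Monthly output fields of one simulation run, keyed by variable."""

    fields: dict[str, GriddedField]
    seed: int
    params: SimParams = field(repr=False, default=None)

    def __getitem__(self, key: str) -> GriddedField:
        return self.fields[key]

    @property
    def variables(self) -> list[str]:
        return sorted(self.fields)


_OUT_UNITS = {
    "t_s": "K", "t_a": "K", "alpha": "1", "s_dn": "W m-2", "lam_e": "W m-2",
    "h": "W m-2", "r_a": "s m-1", "eps_a": "1", "sm": "1", "snow": "1",
    "z500": "m", "t_share": "1", "lai": "m2 m-2",
}


def simulate_run(
    lai: GriddedField,
    forcing: Forcing,
    params: SimParams,
    seed: int,
    discard_years: int = 1,
) -> SimOutput:
    """Run the column model over the full monthly LAI record.

    The member ``seed`` draws the initial bucket fill, initial humidity and
    the AR(1) circulation innovations, emulating an initial-condition
    ensemble member.  The first ``discard_years`` years are dropped from
    the output as spin-up.  Identical (lai, forcing, params, seed) give
    bit-identical output.
    """
    if lai.months is None:
        raise ValueError("simulate_run needs a monthly LAI record")
    p = params
    nlat, nlon = lai.lat.size, lai.lon.size
    y0 = lai.months[0][0]
    rng = np.random.default_rng(seed)

    sm = rng.uniform(0.35, 0.75, size=(nlat, nlon))
    q = rng.uniform(0.25, 0.45, size=(nlat, nlon))
    ar_state = 0.0
    # fixed smooth teleconnection-like pattern (member-independent)
    lon_g, lat_g = np.meshgrid(lai.lon, lai.lat)
    z_pattern = np.sin(np.deg2rad(2.0 * lon_g)) * np.cos(np.deg2rad(1.5 * (lat_g - 55.0)))

    t_s_prev = forcing.t_bg[lai.months[0][1] - 1][:, None] * np.ones((1, nlon))
    lam_prev = np.zeros((nlat, nlon))

    keep = {k: [] for k in _OUT_UNITS}
    months_kept = []
    for i, (year, month) in enumerate(lai.months):
        lai_t = np.nan_to_num(lai.values[i], nan=0.0)
        snow_t = np.broadcast_to(forcing.snow[month - 1][:, None], (nlat, nlon))
        year_frac = year - y0 + (month - 0.5) / 12.0

        q = (1.0 - p.q_memory) * q + p.q_memory * (lam_prev / p.lam_ref)
        eps_a = air_emissivity(q, p)
        s_dn = np.broadcast_to(
            forcing.s_dn0[month - 1][:, None], (nlat, nlon)
        ) * (1.0 - p.sdn_dim * q)

        innov = rng.normal(0.0, 1.0)  # drawn every month for seed alignment
        ar_state = p.ar1_rho * ar_state + p.ar1_sd * innov
        z500 = z_pattern * ar_state + p.z_gain * (q - p.q_ref)

        alpha = albedo_from_lai(lai_t, snow_t, p)
        r_a = aerodynamic_resistance_from_lai(lai_t, p)
        beta, t_share = evaporative_fraction(lai_t, sm, t_s_prev, p, snow=snow_t)

        t_bg = forcing.background_t(month, year_frac)[:, None] * np.ones((1, nlon))
        # T_a = w T_s + (1-w) t_bg + b z500; fold the circulation term into
        # the background so the solver keeps its two-parameter coupled form
        t_bg_eff = t_bg + p.b_z500 * z500 / (1.0 - p.w_air)

        sol = solve_surface_temperature(
            s_dn, alpha, eps_a, None, r_a, beta, p,
            t_bg=t_bg_eff, w_air=p.w_air, t_init=t_s_prev,
        )
        sm, _ = step_soil_moisture(
            sm, np.broadcast_to(forcing.precip_mm[month - 1][:, None], (nlat, nlon)),
            sol["lam_e"], p,
        )
        t_s_prev = sol["t_s"]
        lam_prev = sol["lam_e"]

        if year - y0 >= discard_years:
            months_kept.append((year, month))
            keep["t_s"].append(sol["t_s"])
            keep["t_a"].append(sol["t_a"])
            keep["alpha"].append(alpha)
            keep["s_dn"].append(s_dn)
            keep["lam_e"].append(sol["lam_e"])
            keep["h"].append(sol["h"])
            keep["r_a"].append(r_a)
            keep["eps_a"].append(eps_a)
            keep["sm"].append(sm)
            keep["snow"].append(snow_t.astype(np.float64))
            keep["z500"].append(z500)
            keep["t_share"].append(t_share)
            keep["lai"].append(lai_t)

    fields = {
        k: GriddedField(np.array(v), lai.lat, lai.lon, months=months_kept,
                        units=_OUT_UNITS[k], name=k)
        for k, v in keep.items()
    }
    return SimOutput(fields=fields, seed=seed, params=p)
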