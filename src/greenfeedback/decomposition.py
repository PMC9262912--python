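"""Attribution of paired-run temperature differences to surface processes.

Linearising the surface energy balance

    S_dn (1 - alpha) + eps_s sigma (eps_a T_a^4 - T_s^4)
        = rho C_p (T_s - T_a) / r_a + lambda_E

about the control state converts the between-run differences of albedo,
downward shortwave, latent heat, aerodynamic resistance and air emissivity
into equivalent surface radiative forcings (W m-2):

    F_alpha = -S_dn dAlpha            F_Sdn = (1 - alpha) dS_dn
    F_lamE  = -dLambda_E              F_ra  = rho C_p r_a^-2 (T_s - T_a) dr_a
    F_eps   = eps_s sigma T_a^4 dEps_a

A surface forcing of 1 W m-2 changes T_s by 1/f_s and T_a by 1/f_a, where
f_s and f_a are the energy redistribution factors.  The part of the actual
air-temperature difference not explained by these local surface exchanges
is the circulation residual, attributable to advection and large-scale
circulation changes.

Coefficients (S_dn, alpha, r_a, T_s - T_a, T_a^4 ...) are evaluated on the
control state: it is the reference being perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Constants",
    "DEFAULT_CONSTANTS",
    "ForcingComponents",
    "DecomposedDelta",
    "redistribution_factor_fs",
    "redistribution_factor_fa",
    "forcing_components",
    "decompose_delta_ts",
    "decompose_delta_ta",
    "group_r_nr",
]

COMPONENT_NAMES = ("alpha", "s_dn", "lam_e", "r_a", "eps_a")
RADIATIVE = ("alpha", "s_dn", "eps_a")
NON_RADIATIVE = ("lam_e", "r_a")


@dataclass(frozen=True)
class Constants:
    """Physical constants of the decomposition."""

    eps_s: float = 0.95  # land surface emissivity
    sigma: float = 5.67e-8  # Stefan-Boltzmann, W m-2 K-4
    rho: float = 1.205  # air density, kg m-3
    cp: float = 1013.0  # specific heat of air, J kg-1 K-1


DEFAULT_CONSTANTS = Constants()


def redistribution_factor_fs(t_s, r_a, c: Constants = DEFAULT_CONSTANTS):
    """Surface energy redistribution factor f_s (W m-2 K-1).

    f_s = rho C_p / r_a + 4 eps_s sigma T_s^3: the flux response of the
    surface to a 1 K warming, i.e. how effectively the surface sheds an
    imposed radiative forcing.  Larger over rough/warm surfaces, hence a
    given forcing moves T_s less there.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    r_a = np.asarray(r_a, dtype=np.float64)
    if np.any(t_s <= 0) or np.any(r_a <= 0):
        raise ValueError("t_s and r_a must be positive")
    return c.rho * c.cp / r_a + 4.0 * c.eps_s * c.sigma * t_s**3


def redistribution_factor_fa(t_s, r_a, eps_a, c: Constants = DEFAULT_CONSTANTS):
    """Redistribution factor for air temperature, f_a (W m-2 K-1).

    f_a = rho C_p / r_a + 4 eps_s sigma eps_a T_s^3; equals f_s when the
    air is a perfect longwave emitter (eps_a = 1) and is smaller otherwise.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    eps_a = np.asarray(eps_a, dtype=np.float64)
    if np.any((eps_a < 0) | (eps_a > 1)):
        raise ValueError("eps_a must lie in [0, 1]")
    rad = 4.0 * c.eps_s * c.sigma * t_s**3
    return redistribution_factor_fs(t_s, r_a, c) - rad + eps_a * rad


@dataclass
class ForcingComponents:
    """The five equivalent surface radiative forcings (W m-2)."""

    alpha: np.ndarray
    s_dn: np.ndarray
    lam_e: np.ndarray
    r_a: np.ndarray
    eps_a: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in COMPONENT_NAMES}

    @property
    def total(self) -> np.ndarray:
        return self.alpha + self.s_dn + self.lam_e + self.r_a + self.eps_a


def forcing_components(
    baseline: dict[str, np.ndarray],
    deltas: dict[str, np.ndarray],
    c: Constants = DEFAULT_CONSTANTS,
) -> ForcingComponents:
    """Convert between-run deltas into equivalent surface radiative forcing.

    ``baseline`` needs control-state s_dn, alpha, r_a, t_s, t_a;
    ``deltas`` the five differences keyed alpha, s_dn, lam_e, r_a, eps_a.
    Signs follow the greening convention: canopy darkening (dAlpha < 0)
    and moister air (dEps_a > 0) warm (positive forcing); extra latent
    heat (dLambda_E > 0) cools.
    """
    b = {k: np.asarray(v, dtype=np.float64) for k, v in baseline.items()}
    d = {k: np.asarray(v, dtype=np.float64) for k, v in deltas.items()}
    return ForcingComponents(
        alpha=-b["s_dn"] * d["alpha"],
        s_dn=(1.0 - b["alpha"]) * d["s_dn"],
        lam_e=-d["lam_e"],
        r_a=c.rho * c.cp / b["r_a"] ** 2 * (b["t_s"] - b["t_a"]) * d["r_a"],
        eps_a=c.eps_s * c.sigma * b["t_a"] ** 4 * d["eps_a"],
    )


def decompose_delta_ts(
    components: ForcingComponents,
    f_s,
    delta_t_a,
    t_s,
    t_a,
    r_a,
    eps_a,
    c: Constants = DEFAULT_CONSTANTS,
    ta_coefficient: str = "ta",
):
    """First-order prediction of the surface-temperature difference.

    dT_s = (sum of forcings)/f_s
         + (rho C_p/r_a + 4 eps_s sigma eps_a T_x^3) dT_a / f_s

    where T_x is the air temperature (``ta_coefficient="ta"``, the exact
    linearisation of the balance) or the surface temperature ("ts", the
    commonly quoted approximation valid when T_a is close to T_s).
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    t_a = np.asarray(t_a, dtype=np.float64)
    if ta_coefficient == "ta":
        t_x = t_a
    elif ta_coefficient == "ts":
        t_x = t_s
    else:
        raise ValueError("ta_coefficient must be 'ta' or 'ts'")
    num = c.rho * c.cp / np.asarray(r_a, dtype=np.float64) + (
        4.0 * c.eps_s * c.sigma * np.asarray(eps_a, dtype=np.float64) * t_x**3
    )
    return components.total / f_s + num * np.asarray(delta_t_a) / f_s


@dataclass
class DecomposedDelta:
    """Radiatively explained and circulation-residual parts of dT_a (K)."""

    per_component: dict[str, np.ndarray]
    t_a_rad: np.ndarray
    t_a_cir: np.ndarray
    t_a_total: np.ndarray


def decompose_delta_ta(
    delta_t_a_actual, components: ForcingComponents, f_a
) -> DecomposedDelta:
    """Split the actual dT_a into surface-forced and circulation parts.

    Each component's contribution is F_x / f_a; the residual
    dT_a_cir = dT_a - sum(F)/f_a is assigned to advection/circulation.
    The reconstruction dT_a_rad + dT_a_cir = dT_a is exact by construction.
    """
    f_a = np.asarray(f_a, dtype=np.float64)
    if np.any(f_a <= 0):
        raise ValueError("f_a must be positive")
    delta_t_a_actual = np.asarray(delta_t_a_actual, dtype=np.float64)
    per = {k: v / f_a for k, v in components.as_dict().items()}
    t_a_rad = components.total / f_a
    return DecomposedDelta(
        per_component=per,
        t_a_rad=t_a_rad,
        t_a_cir=delta_t_a_actual - t_a_rad,
        t_a_total=delta_t_a_actual,
    )


def group_r_nr(components: ForcingComponents) -> dict[str, np.ndarray]:
    """Group the five forcings into radiative and non-radiative sums.

    R collects how much energy the surface *receives* (albedo, downward
    shortwave, air emissivity); NR collects how the surface *dissipates*
    it (latent heat, aerodynamic resistance).  All = R + NR exactly.
    """
    d = components.as_dict()
    r = sum(d[k] for k in RADIATIVE)
    nr = sum(d[k] for k in NON_RADIATIVE)
    return {"R": r, "NR": nr, "All": r + nr}
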