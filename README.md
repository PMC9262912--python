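# greenfeedback

Seasonal vegetation greening — the multi-year increase in leaf area index
(LAI) over northern (25–90°N) vegetated land — perturbs the surface energy
budget and with it near-surface air temperature, differently in each
season: summer greening cools through enhanced evapotranspiration, while
in spring and autumn radiative warming from canopy darkening and extra
atmospheric water vapor can offset the evaporative cooling, and energy
perturbed in one season is carried into later ones by soil moisture and
circulation. `greenfeedback` implements the full analysis chain used to
quantify these biophysical feedbacks — at toy scale, so every step is
testable end to end:

* a **synthetic LAI record** with seasonal climatology, season-specific
  greening rates and interannual noise, plus the satellite-style
  preparation chain (composite maxima, grid aggregation, PFT weighting,
  LAI ≥ 0.1 masking);
* a minimal **LAI-driven land–atmosphere column model** on the grid
  (exponential canopy albedo masking with snow, bucket soil moisture,
  Clausius–Clapeyron-shaped evaporative fraction, humidity→emissivity
  water-vapor feedback, an AR(1) circulation proxy), solved monthly by
  Newton iteration on the surface energy balance;
* the **paired seasonal-control experiment design**: a dynamic-LAI run
  against controls with one season's LAI fixed to climatology, run as
  seed-matched initial-condition ensembles, differenced into intra- and
  inter-seasonal response fields;
* the **surface-energy-balance decomposition** of those responses into
  equivalent surface radiative forcings and temperature contributions;
* **seasonal statistics**: OLS trends with significance classes,
  significance stippling, the July-minus-January seasonal amplitude (SAT),
  LAI–response correlation, latitudinal profiles, and binned phase-space
  summaries with partial-dependence marginals.

## The decomposition

With the surface energy balance
S_dn(1−α) + ε_s σ(ε_a T_a⁴ − T_s⁴) = ρC_p(T_s−T_a)/r_a + λE
(ground heat flux neglected), paired-run differences of albedo α,
downward shortwave S_dn, latent heat λE, aerodynamic resistance r_a and
air emissivity ε_a become equivalent surface radiative forcings

    F_α = −S_dn Δα,  F_Sdn = (1−α) ΔS_dn,  F_λE = −ΔλE,
    F_ra = ρC_p r_a⁻² (T_s−T_a) Δr_a,  F_εa = ε_s σ T_a⁴ Δε_a,

grouped into radiative (α, S_dn, ε_a) and non-radiative (λE, r_a)
processes. The energy redistribution factors
f_s = ρC_p/r_a + 4ε_sσT_s³ and f_a = ρC_p/r_a + 4ε_sσε_aT_s³ convert a
1 W m⁻² forcing into surface and air temperature change; the part of the
actual ΔT_a not explained by ΣF/f_a is the circulation residual
ΔT_a^cir. The linearisation is first-order exact: on seed-matched pairs
its error shrinks ~4× per halving of the LAI perturbation.

## Worked example

Run the full toy study (dynamic run + three seasonal controls, 12
seed-matched members, 16×16 grid, 1982–2014):

```
python analysis/02_run_toy_study.py
```

which prints:

```
NH-mean LAI-induced T_a trends (degC decade-1):
  MAM intra: +0.0045 +/- 0.0028 (n.s.)
  JJA intra: -0.0324 +/- 0.0024 (***)
  SON intra: +0.0010 +/- 0.0014 (n.s.)
  MAM inter: +0.0003 +/- 0.0000 (***)
  JJA inter: +0.0049 +/- 0.0010 (***)
  SON inter: +0.0062 +/- 0.0006 (***)
  DJF inter: +0.0023 +/- 0.0002 (***)
SAT trend [sat_sce]: +0.0010 K decade-1 (n.s.)
SAT trend [sat_induced]: -0.0289 K decade-1 (***)
```

Reading: within-season ("intra") responses show significant summer
cooling from evaporative enhancement while spring and autumn stay weak
and insignificant — the radiative terms offset the evaporative ones
there; the carried-over ("inter") responses are small but nonzero,
reaching winter through the circulation proxy; and the LAI-induced
July-minus-January amplitude trend is negative: greening makes the
simulated seasonal cycle flatter. Figure-ready tables (trend tables, the
monthly response matrix, forcing-component trends with R/NR grouping, SAT
series, phase-space marginals, ensemble sign agreement) are written to
`results/study/` with a config-hashed manifest; reruns are byte-identical.

The other drivers follow the same pattern: `01_lai_scenario.py` (generator
trends), `03_mechanism_experiments.py` (summer cooling, spring→summer
soil-moisture carryover, amplitude attenuation under a seasonal
background drift), `04_decomposition_closure.py` (the 2%→1%→0.5% closure
ladder and a worked forcing example), `05_calibration.py` (type-I error,
stipple null, correlation null, generator-slope and phase-space
recovery). An equivalent orchestrated run is available as
`greenfeedback run --config study.yaml`.

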