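# Methods

`greenfeedback` studies how multi-year increases in leaf area index (LAI,
"greening") of northern vegetated land perturb near-surface air
temperature season by season. Because the question is about *method*
rather than any particular climate realisation, the package pairs a
deliberately minimal land–atmosphere column model with the full analysis
chain a coupled-model study would use: paired dynamic-vs-fixed-LAI
experiments run as initial-condition ensembles, a surface-energy-balance
decomposition of the resulting temperature differences, and seasonal
trend/amplitude/phase-space statistics.

## The paired-experiment design

A dynamic run (SCE) is forced by the full monthly LAI record. For each
growing season (MAM, JJA, SON) a control run replaces that season's LAI —
and only that season's — with its per-calendar-month multi-year
climatology, so the fixed season carries exactly zero LAI trend. Each run
is an ensemble over member seeds; a member's seed fixes its initial bucket
fill, initial column humidity and circulation-noise path. SCE and control
members are **seed-matched pairwise**: when their LAI coincides the runs
are bit-identical, so any difference isolates the fixed season's LAI
variations. The ensemble-mean difference ΔX = mean(SCE) − mean(CTL) is the
response field. A response month inside the fixed season is
*intra-seasonal*; all other months are *inter-seasonal* (carry-over) — the
column reaches them only through soil-moisture and circulation memory.
The total carried-over response in a target season is the sum of the other
growing-season controls' responses evaluated there (all three for winter,
whose LAI is never perturbed).

Design choices that were genuinely open:

* **Ensemble averaging precedes spatial averaging and trend fitting.**
* **Paired seeds** rather than independent draws: variance reduction, and
  the degenerate-scenario identity (Δ ≡ 0) becomes an exact test.
* **Spin-up** is one discarded simulated year per member; the bucket and
  humidity EMA equilibrate within a few months at this time step.
* **Winter labelling**: DJF of year *y* is Dec(y)+Jan(y+1)+Feb(y+1), the
  winter *following* growing-season *y*, preserving causal ordering; a
  33-year record therefore yields 32 winters.

## The column model

One column per grid cell, monthly step, no diurnal cycle. Per month:

* **Albedo**: α = α_c + (α_g − α_c)·e^(−k·LAI), with the snow albedo
  substituted for the ground albedo where snow is prescribed — dense dark
  canopies mask bright ground or snow. Defaults α_c = 0.15, α_g = 0.25,
  α_snow = 0.70, k = 0.5.
* **Aerodynamic resistance**: r_a = r_a0/(1 + c·LAI) (r_a0 = 120 s m⁻¹,
  c = 0.25): rougher canopies couple the surface to the air better.
* **Evaporative fraction**: β = β_max · cover · stress(SM) ·
  s(T)/(s(T)+γ), where cover = (1−e^(−k·LAI)) with a small bare-soil
  floor (0.08), stress ramps linearly below 45% bucket fill, and s(T) is
  the Magnus slope of saturation vapour pressure — evaporation is a more
  efficient sink in warm months. The transpiration share of total
  evapotranspiration is the canopy cover fraction itself, so summer
  canopies dominate ET more than shoulder-season ones.
* **Energy balance**: S_dn(1−α) + ε_sσ(ε_aT_a⁴ − T_s⁴) = ρC_p(T_s−T_a)/r_a
  + λE with λE = β·max(0, S_net+L_net) and ground heat flux neglected
  (a small residual at monthly and interannual scales). Solved by Newton
  iteration with the air coupled to the surface,
  T_a = w·T_s + (1−w)·T_bg + b·z500 (w = 0.6, b = 0.02 K m⁻¹), so the
  accepted state closes the balance with the *reported* air temperature.
* **Humidity and emissivity**: column humidity q is an exponential moving
  average of λE/λ_ref; air emissivity ε_a = min(0.95, 0.72 + 0.10·q)
  (water-vapor feedback) and S_dn is dimmed by 3%·q (vapor/cloud proxy).
* **Bucket hydrology**: SM' = clip(SM + (P − E − R)/capacity);
  evaporation converts λE to water depth, runoff is a linear leak
  (10%/month), capacity 150 mm. Limits are applied so the water budget
  closes exactly given the returned diagnostics. The bucket is the only
  intra-annual memory connecting spring transpiration to summer moisture.
* **Circulation proxy**: z500 = pattern(cell)·a_t + g·(q − q_ref), where
  a_t is a seeded AR(1) scalar mode (ρ = 0.7, innovation SD 8 m; 0
  disables internal variability) and the humidity-forced term lets
  greening raise heights (an anomalous-high response), which feeds back on
  T_a and carries signal into winter.

Physical constants match the decomposition: ε_s = 0.95,
σ = 5.67×10⁻⁸ W m⁻² K⁻⁴, ρ = 1.205 kg m⁻³, C_p = 1013 J kg⁻¹ K⁻¹.
Every functional form here is an artifact of this package, chosen as the
simplest one that makes the corresponding mechanism testable; none should
be read as a GCM parameterisation. In particular the ε_a–humidity link is
a monotone placeholder.

Prescribed forcing is zonally symmetric: a declination-following
insolation cycle, a background air-temperature cycle whose annual
amplitude grows poleward, weakly summer-peaked precipitation with an
optional semi-arid band (35–45°N at 40% precipitation) where the bucket
runs moisture-limited in summer, and snow prescribed wherever the
background air is below −2 °C (snow affects albedo only; it is not
prognostic). An optional per-calendar-month background trend imposes
secular drifts such as warming winters with cooling summers.

## The synthetic LAI record

The generator emulates a satellite-derived monthly LAI archive:
LAI(y,m,cell) = clim(m,cell) + slope(season(m))·(y−y₀)/10·pattern(cell) +
noise, clipped at zero. The climatology peaks in July (2.5 m² m⁻²,
winter floor 0.3) and tapers poleward. Default seasonal greening rates are
0.019 (MAM), 0.046 (JJA), 0.027 (SON) and 0 (DJF) m² m⁻² decade⁻¹ —
summer strongest, then autumn, then spring, the ordering observed in the
satellite era. Noise has two parts: per-cell white noise (SD 0.10) that
averages out of hemispheric means, and a spatially coherent monthly
anomaly (SD 0.03) that sets the interannual variability — and hence the
trend standard error — of the NH-mean series. What the generator does
*not* emulate: spatial trend heterogeneity tied to land cover, snow/cloud
gaps, retrieval artefacts, or autocorrelated interannual variability; a
passing recovery test therefore shows the pipeline is calibrated for
white-noise records, not that real archives are this friendly.

The preparation chain of a real archive is implemented alongside:
within-month maximum over ~15-day composites (limiting residual
cloud/snow low bias), integer-block aggregation to a coarse grid with
cosine-latitude weights, and uniform assignment of the cell LAI to every
vegetated plant functional type so the cover-weighted vegetated mean
reconstructs the cell value exactly (bare soil gets zero). The
"redistribution" reading of PFT weighting was rejected because it would
not conserve the cell LAI that the experiments prescribe. Cells with
climatological LAI below 0.1 m² m⁻² are masked everywhere.

## The decomposition

Linearising the balance about the control state converts the paired-run
differences into equivalent surface radiative forcings (W m⁻²):

    F_α  = −S_dn·Δα              F_Sdn = (1−α)·ΔS_dn
    F_λE = −ΔλE                  F_ra  = ρC_p·r_a⁻²·(T_s−T_a)·Δr_a
    F_εa = ε_s·σ·T_a⁴·Δε_a

with redistribution factors f_s = ρC_p/r_a + 4ε_sσT_s³ and
f_a = ρC_p/r_a + 4ε_sσε_aT_s³ (W m⁻² K⁻¹) converting forcing to ΔT_s and
ΔT_a. The surface-temperature prediction is

    ΔT_s = ΣF/f_s + (ρC_p/r_a + 4ε_sσε_aT_a³)·ΔT_a / f_s

and the air-temperature split is ΔT_a^rad = ΣF/f_a (per component
F_x/f_a) with the circulation residual ΔT_a^cir = ΔT_a − ΔT_a^rad, exact
by construction.

Three points needed a decision:

* **Grouping.** R = {F_α, F_Sdn, F_εa} (how much energy the surface
  receives), NR = {F_λE, F_ra} (how it dissipates it), All = R + NR
  exactly. Source formulations of this decomposition sometimes list −ΔλE
  inside both sums; we treat that as a transcription slip — λE is the
  canonical non-radiative flux — and keep the groups disjoint.
* **ΔT_a-term coefficient.** The exact first-order differential of the
  balance puts ε_a·T_a³ in the numerator of the ΔT_a term (we re-derived
  it); a common shorthand uses T_s³ throughout, valid when T_a ≈ T_s.
  Both are available (`ta_coefficient="ta"|"ts"`), the exact form is the
  default; the closure test below discriminates empirically in its
  favour.
* **Baseline state.** Coefficients (S_dn, α, r_a, T_s−T_a, T_a⁴) are taken
  from the control run — it is the reference being perturbed. In study
  tables the control ensemble-mean per-calendar-month climatology is used;
  in the closure ladder the control state itself (they coincide there, as
  noise is off and the cycle is periodic).

Cross-terms between simultaneous deltas are second order and land in the
circulation residual; this is the content of the closure check: on
seed-matched pairs with circulation noise off, max|ΔT_s(sim) −
ΔT_s(linearised)| shrinks by ≈4× per halving of the LAI perturbation
(measured: 3.98 and 3.99 on the 2% → 1% → 0.5% ladder).

## Statistics

Trends are OLS on yearly series, reported per decade with the two-sided
t-test (n−2 df) and star classes (*** p<0.01, ** p<0.05, * p<0.1).
Residuals are assumed independent year to year — no autocorrelation
correction — matching the simplest convention; under the generator's
white noise the test is exactly calibrated (measured type-I rate 0.042 at
nominal 0.05 over 1000 replicates). Figure-caption "1 SD" uncertainty is
read as ±1 standard error of the trend estimate. Significance stippling
is per-cell p < α with no multiplicity correction. The seasonal amplitude
of temperature (SAT) is July-minus-January air temperature, one value per
year. The LAI–ΔT_a correlation is Pearson's r with optional per-series
linear detrending (both paths supported; detrended is used in the
mechanism metrics so the shared trend cannot inflate |r|). The
phase-space summary bins the ΔT_a-trend map in the (ΔSM trend, Δz500
trend) plane (default 20×20 bins, bins under 5 cells dropped); marginal
partial-dependence slopes are fitted against per-bin *driver means*
weighted by bin population — bin centers are biased abscissae in edge
bins.

## Numerical choices

Newton solve: tolerance 1e-3 W m⁻² on the residual and 1e-6 K on the
step, 50-iteration cap (error with last residual on failure), steps
clipped at ±20 K, initial guess the previous month's T_s. Accepted states
close the balance to <1e-3 W m⁻² with the reported T_a. Area means use
cosine-latitude weights renormalised over contributing cells; masked cells
are NaN and excluded from every reduction. All algebra is float64; the
ΔT_a reconstruction and R/NR/All additivity hold to 1e-12. Gridded I/O is
CF-style netCDF (classic format via the scipy backend) with exact float64
round-trip.

## Problem sizes

The mechanism experiments run 30-member ensembles on a 16×16 grid of the
25–90°N domain over 1982–2014 (33 analysed years after one spin-up year);
the closure ladder uses an 8×8 grid over 8 years; calibration checks use
1000 replicates (trend and correlation nulls) and a 40×40 null map;
generator recovery uses 100 replicates. These sizes were chosen so the
ensemble statistics are stable while the full chain stays cheap enough to
re-run routinely.

## Known limitations

The column model has no advection between cells (the circulation proxy is
a statistical mode, not dynamics), no prognostic snow or clouds, no CO₂
physiological forcing, no diurnal cycle, and a single-layer bucket. The
sign and convergence properties demonstrated here are properties of the
method — the experiment design, the decomposition algebra and the
statistics — not quantitative predictions for any real climate; magnitude
agreement with GCM-scale results is outside what a column toy can or
should claim.
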