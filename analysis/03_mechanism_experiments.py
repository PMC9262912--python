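#!/usr/bin/env python
"""Run the three mechanism experiments and record what each shows.

1. Summer-only greening over a wet domain: enhanced evapotranspiration
   cools JJA air (negative dT_a trend, negative latent-heat forcing).
2. Spring-only greening with a semi-arid band: extra spring transpiration
   draws the bucket down, the deficit carries into summer and warms it.
3. Warming-winter / cooling-summer background drift: the July-minus-
   January amplitude of the simulated climate shrinks.

Writes results/mechanisms.csv.
"""

from pathlib import Path

import pandas as pd

from greenfeedback import mechanisms as M

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []

    jja = M.jja_cooling_metrics(members=30, seed_base=100, scenario_seed=0)
    print("summer greening (wet regime):")
    print(f"  JJA dT_a trend: {jja['dta_trend']:+.4f} degC decade-1 "
          f"(p={jja['dta_trend_p']:.2g})")
    print(f"  latent-heat forcing trend: {jja['f_lam_e_trend']:+.4f} "
          f"W m-2 decade-1")
    print(f"  sign agreement: {jja['sign_agreement_count']}/{jja['members']}"
          f" members; LAI-dT_a correlation r={jja['lai_dta_correlation']:.2f}")
    rows.append({"experiment": "jja_greening_wet", **{
        k: v for k, v in jja.items()}})

    carry = M.carryover_metrics(members=30, seed_base=300, scenario_seed=0)
    print("spring greening (semi-arid band), summer response:")
    print(f"  JJA dSM trend: {carry['dsm_trend']:+.5f} decade-1 "
          f"(p={carry['dsm_trend_p']:.2g})")
    print(f"  JJA dT_a trend: {carry['dta_trend']:+.4f} degC decade-1 "
          f"(p={carry['dta_trend_p']:.2g})")
    rows.append({"experiment": "mam_greening_dry", **carry})

    sat = M.sat_attenuation_metric(members=30, seed_base=500, scenario_seed=0)
    print("seasonal background drift:")
    print(f"  SAT trend: {sat['sat_trend']:+.4f} K decade-1 "
          f"(p={sat['sat_trend_p']:.2g})")
    rows.append({"experiment": "seasonal_drift", **sat})

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "mechanisms.csv", index=False,
                              float_format="%.6g")
    print(f"wrote {OUT / 'mechanisms.csv'}")


if __name__ == "__main__":
    main()
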