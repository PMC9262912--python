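#!/usr/bin/env python
"""Run the full paired-experiment toy study and write its tables.

The dynamic-LAI run and the three seasonal controls (MAM/JJA/SON fixed to
climatology) are integrated as a 12-member seed-matched ensemble on a
16x16 northern grid over 1982-2014 (one discarded spin-up year).  The
study tables land in results/study/: intra-/inter-seasonal temperature
trends, the monthly response matrix, forcing-component trends, the SAT
series, phase-space marginals and ensemble sign agreement.
"""

from pathlib import Path

from greenfeedback.study import StudyConfig, run_study, write_tables

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    cfg = StudyConfig(nlat=16, nlon=16, years=(1981, 2014), members=12,
                      seed_base=2000, seasons=("MAM", "JJA", "SON"),
                      scenario={"seed": 0})
    result = run_study(cfg)
    write_tables(result, OUT)

    trends = result.tables["delta_ta_trends"]
    print("NH-mean LAI-induced T_a trends (degC decade-1):")
    for _, row in trends.iterrows():
        print(f"  {row.season} {row['kind']:5s}: "
              f"{row.slope_degC_per_decade:+.4f} +/- {row.se:.4f} "
              f"({row['class']})")
    sat = result.tables["sat_trends"]
    for _, row in sat.iterrows():
        print(f"SAT trend [{row.series}]: {row.slope_K_per_decade:+.4f} "
              f"K decade-1 ({row['class']})")
    print(f"wrote tables to {OUT} (summary hash "
          f"{result.summary_hash()[:12]})")


if __name__ == "__main__":
    main()
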