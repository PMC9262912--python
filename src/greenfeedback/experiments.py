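"""Paired seasonal-control experiment design and ensemble differencing.

One dynamic-LAI run (all seasons vary year to year) is paired with three
season-fixed control runs, in which the LAI of exactly one growing season
(MAM, JJA or SON) is replaced, per calendar month, by its multi-year
climatology.  Both members of a pair share the same initial-condition seed,
so their difference isolates the effect of that season's LAI variations —
both in the season itself (intra-seasonal) and in later seasons reached
through soil-moisture and circulation memory (inter-seasonal).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .grids import GriddedField, Season, season_of_month
from .simulator import Forcing, SimOutput, SimParams, simulate_run

__all__ = [
    "ExperimentSet",
    "DeltaField",
    "make_control_lai",
    "run_ensemble",
    "ensemble_mean",
    "delta_field",
    "split_intra_inter",
    "lagged_sum",
    "sign_agreement",
    "build_experiment_set",
]

logger = logging.getLogger(__name__)


def make_control_lai(lai: GriddedField, season: Season | str) -> GriddedField:
    """Fix one season's LAI to its per-calendar-month climatology.

    Months outside ``season`` pass through untouched; inside it, every
    occurrence of a calendar month is replaced by the multi-year mean map
    of that month, so the fixed season carries exactly zero LAI trend.
    """
    season = Season(season)
    if lai.months is None:
        raise ValueError("control construction needs the monthly record")
    vals = lai.values.copy()
    for month in range(1, 13):
        if season_of_month(month) is not season:
            continue
        idx = [i for i, (_, m) in enumerate(lai.months) if m == month]
        clim = np.nanmean(lai.values[idx], axis=0)
        vals[idx] = clim
    return lai.copy_with(values=vals, name=f"{lai.name}_ctl_{season.value}")


def run_ensemble(
    lai: GriddedField,
    forcing: Forcing,
    params: SimParams,
    seeds: list[int],
    discard_years: int = 1,
) -> list[SimOutput]:
    """One simulation per seed; member order follows the seed list."""
    if len(seeds) == 0:
        raise ValueError("need at least one seed")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate member seeds")
    return [
        simulate_run(lai, forcing, params, seed=s, discard_years=discard_years)
        for s in seeds
    ]


def ensemble_mean(members: list[SimOutput], variable: str) -> GriddedField:
    """Member-mean field of one output variable."""
    ref = members[0][variable]
    stack = np.mean([m[variable].values for m in members], axis=0)
    return ref.copy_with(values=stack, name=f"{variable}_ensmean")


@dataclass
class ExperimentSet:
    """The dynamic run and its three seasonal controls, seed-matched."""

    sce: list[SimOutput]
    controls: dict[Season, list[SimOutput]]
    lai: GriddedField
    seeds: list[int]

    def __post_init__(self) -> None:
        for season, members in self.controls.items():
            if len(members) != len(self.sce):
                raise ValueError(
                    f"control {season} has {len(members)} members, "
                    f"SCE has {len(self.sce)}"
                )

    def manifest(self) -> str:
        return json.dumps(
            {"members": len(self.sce), "seeds": list(self.seeds),
             "controls": sorted(s.value for s in self.controls)},
            sort_keys=True,
        )


@dataclass
class DeltaField:
    """SCE-minus-control ensemble-mean difference of one variable.

    ``months`` may be a non-contiguous subset after seasonal selection;
    ``control_season`` records which control the difference is against.
    """

    values: np.ndarray  # (ntime, nlat, nlon)
    lat: np.ndarray
    lon: np.ndarray
    months: list[tuple[int, int]]
    variable: str
    control_season: Season
    units: str = ""

    def select_months(self, keep: list[int]) -> "DeltaField":
        return DeltaField(
            values=self.values[keep], lat=self.lat, lon=self.lon,
            months=[self.months[i] for i in keep], variable=self.variable,
            control_season=self.control_season, units=self.units,
        )


def delta_field(
    exp: ExperimentSet, variable: str, control_season: Season | str
) -> DeltaField:
    """Ensemble-mean(SCE) minus ensemble-mean(control), per cell/month."""
    control_season = Season(control_season)
    ctl = exp.controls[control_season]
    if len(ctl) != len(exp.sce):
        raise ValueError("mismatched member counts")
    sce_mean = ensemble_mean(exp.sce, variable)
    ctl_mean = ensemble_mean(ctl, variable)
    return DeltaField(
        values=sce_mean.values - ctl_mean.values,
        lat=sce_mean.lat, lon=sce_mean.lon, months=list(sce_mean.months),
        variable=variable, control_season=control_season,
        units=sce_mean.units,
    )


def split_intra_inter(delta: DeltaField) -> dict[str, DeltaField]:
    """Partition Delta months into intra-seasonal and inter-seasonal parts.

    A month is *intra* when it falls in the control's fixed season (the
    response co-occurs with the LAI perturbation) and *inter* otherwise
    (the response is carried over by soil or atmosphere memory).
    """
    intra = [i for i, (_, m) in enumerate(delta.months)
             if season_of_month(m) is delta.control_season]
    inter = [i for i in range(len(delta.months)) if i not in set(intra)]
    return {"intra": delta.select_months(intra), "inter": delta.select_months(inter)}


def lagged_sum(
    deltas: dict[Season, DeltaField], target_season: Season | str
) -> DeltaField:
    """Total carried-over response in one season from the other seasons.

    For a growing-season target, sums the two other growing-season
    controls' responses evaluated in the target months; for DJF, sums all
    three (winter LAI is never perturbed, so every winter response is
    carried over).
    """
    target_season = Season(target_season)
    growing = [Season.MAM, Season.JJA, Season.SON]
    if target_season is Season.DJF:
        sources = growing
    else:
        sources = [s for s in growing if s is not target_season]
    missing = [s for s in sources if s not in deltas]
    if missing:
        raise ValueError(f"missing controls for {missing}")
    parts = []
    months_ref = None
    for s in sources:
        d = deltas[s]
        keep = [i for i, (_, m) in enumerate(d.months)
                if season_of_month(m) is target_season]
        sel = d.select_months(keep)
        if months_ref is None:
            months_ref = sel.months
        elif sel.months != months_ref:
            raise ValueError("controls cover different month subsets")
        parts.append(sel.values)
    total = np.sum(parts, axis=0)
    d0 = deltas[sources[0]]
    return DeltaField(
        values=total, lat=d0.lat, lon=d0.lon, months=months_ref,
        variable=d0.variable, control_season=target_season, units=d0.units,
    )


def sign_agreement(member_means: np.ndarray) -> tuple[int, float]:
    """How many members share the sign of the ensemble-mean response.

    ``member_means`` holds one regional/seasonal-mean Delta per member.
    Returns (count, fraction of members whose value has the same sign as
    the ensemble mean); zero-valued members never count as agreeing.
    """
    member_means = np.asarray(member_means, dtype=np.float64)
    if member_means.size == 0:
        raise ValueError("empty ensemble")
    ref = np.sign(member_means.mean())
    count = int(np.sum(np.sign(member_means) == ref)) if ref != 0 else 0
    return count, count / member_means.size


def build_experiment_set(
    lai: GriddedField,
    forcing: Forcing,
    params: SimParams,
    seeds: list[int],
    seasons: list[Season] | None = None,
    discard_years: int = 1,
) -> ExperimentSet:
    """Run the dynamic experiment and its seasonal controls, seed-matched."""
    seasons = seasons or [Season.MAM, Season.JJA, Season.SON]
    logger.info("running SCE ensemble: %d members", len(seeds))
    sce = run_ensemble(lai, forcing, params, seeds, discard_years)
    controls = {}
    for season in seasons:
        logger.info("running control ensemble for %s", season.value)
        ctl_lai = make_control_lai(lai, season)
        controls[Season(season)] = run_ensemble(
            ctl_lai, forcing, params, seeds, discard_years
        )
    return ExperimentSet(sce=sce, controls=controls, lai=lai, seeds=list(seeds))
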