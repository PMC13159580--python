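"""Scenario paths and coupled birth / preterm-birth projections.

A scenario pairs a general-fertility-rate target with a preterm-proportion
target at a horizon year. The engine builds a year-by-year value path for
each assumption (by default a straight line from the last observed value
to the target), then walks the cohort-component pyramid forward one year
at a time:

    W(t)   = sum of women aged 15-49 in the current pyramid
    B(t)   = GFR(t) * W(t) / 1000
    PTB(t) = B(t) * p(t)

after which the pyramid is advanced with survival, migration and — when
feedback is enabled — the female share of B(t) entering age 0 in t+1.

The three named scenarios bind the paired assumptions commonly used for
this kind of mid-century outlook: optimistic (GFR stabilises at 90 per
1,000, preterm share falls to 5.8%), baseline (GFR 80, preterm share
6.3%) and pessimistic (GFR 75, preterm share 7.2%). ``custom`` specs may
decouple the two assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    AgeStructuredPopulation,
    FertilityFeedbackSpec,
    MigrationSchedule,
    SurvivalSchedule,
    age_advance,
    women_of_reproductive_age,
)

#: (gfr_target per 1,000, preterm target %) for the named scenarios.
NAMED_SCENARIO_TARGETS: dict[str, tuple[float, float]] = {
    "optimistic": (90.0, 5.8),
    "baseline": (80.0, 6.3),
    "pessimistic": (75.0, 7.2),
}

PATH_RULES = ("constant", "linear_to_target")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named assumption set: targets, horizon and path shape."""

    name: str
    gfr_target: float
    ptb_pct_target: float
    start_year: int = 2024
    horizon_year: int = 2050
    path_rule: str = "linear_to_target"

    def __post_init__(self) -> None:
        if self.gfr_target <= 0 or self.ptb_pct_target <= 0:
            raise ValueError("scenario targets must be positive")
        if self.horizon_year < self.start_year:
            raise ValueError("horizon_year must not precede start_year")
        if self.path_rule not in PATH_RULES:
            raise ValueError(f"unknown path_rule {self.path_rule!r}")
        if self.name in NAMED_SCENARIO_TARGETS:
            expect = NAMED_SCENARIO_TARGETS[self.name]
            if (self.gfr_target, self.ptb_pct_target) != expect:
                raise ValueError(
                    f"named scenario {self.name!r} requires targets {expect}, "
                    f"got ({self.gfr_target}, {self.ptb_pct_target})"
                )
        elif self.name != "custom":
            raise ValueError(
                "scenario name must be optimistic|baseline|pessimistic|custom"
            )

    @classmethod
    def named(cls, name: str, *, start_year: int = 2024, horizon_year: int = 2050,
              path_rule: str = "linear_to_target") -> "ScenarioSpec":
        gfr, ptb = NAMED_SCENARIO_TARGETS[name]
        return cls(name=name, gfr_target=gfr, ptb_pct_target=ptb,
                   start_year=start_year, horizon_year=horizon_year,
                   path_rule=path_rule)


@dataclass(frozen=True)
class ScenarioPath:
    """Year-by-year values of one assumption (GFR or preterm percent)."""

    values: pd.Series

    def __post_init__(self) -> None:
        s = self.values.sort_index()
        years = s.index.to_numpy()
        if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
            raise ValueError("path must cover every year in its range")
        if (s <= 0).any():
            raise ValueError("path values must be positive")
        object.__setattr__(self, "values", s)

    def __getitem__(self, year: int) -> float:
        return float(self.values.loc[year])

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.values.index]


@dataclass(frozen=True)
class ProjectionResult:
    """One scenario's projected trajectory.

    ``frame`` is indexed by year with columns ``women_15_49``, ``gfr``,
    ``live_births``, ``ptb_pct``, ``preterm_births`` (fractional persons;
    rounding happens at report time). ``populations`` holds the underlying
    pyramid for every projected year.
    """

    scenario: str
    frame: pd.DataFrame
    populations: tuple[AgeStructuredPopulation, ...]


def build_path(start_value: float, spec: ScenarioSpec, quantity: str = "gfr") -> ScenarioPath:
    """Build the value path for ``quantity`` ("gfr" or "ptb_pct").

    ``linear_to_target``: straight line from ``start_value`` at
    ``spec.start_year`` to the target at ``spec.horizon_year``, endpoints
    inclusive (the endpoint hits the target exactly). ``constant``: the
    start value in the first year, the target in every later year.
    """
    if start_value <= 0:
        raise ValueError("start_value must be positive")
    if quantity == "gfr":
        target = spec.gfr_target
    elif quantity == "ptb_pct":
        target = spec.ptb_pct_target
    else:
        raise ValueError("quantity must be 'gfr' or 'ptb_pct'")
    years = np.arange(spec.start_year, spec.horizon_year + 1)
    if spec.path_rule == "linear_to_target":
        vals = np.linspace(start_value, target, years.size)
    else:  # constant
        vals = np.full(years.size, float(target))
        vals[0] = start_value
    return ScenarioPath(values=pd.Series(vals, index=years))


def project_live_births(women: float, gfr: float) -> float:
    """B = GFR * W / 1000, unrounded."""
    if women < 0 or gfr < 0:
        raise ValueError("women and gfr must be non-negative")
    return gfr * women / 1000.0


def project_preterm_births(births: float, ptb_pct: float) -> float:
    """PTB = B * p with p given in percent, unrounded."""
    if births < 0:
        raise ValueError("births must be non-negative")
    if not 0.0 <= ptb_pct <= 100.0:
        raise ValueError("ptb_pct must lie in [0, 100]")
    return births * ptb_pct / 100.0


def run_scenario(
    pop0: AgeStructuredPopulation,
    surv: SurvivalSchedule,
    mig: MigrationSchedule,
    feedback: FertilityFeedbackSpec,
    spec: ScenarioSpec,
    start_gfr: float,
    start_ptb_pct: float,
) -> ProjectionResult:
    """Project one scenario from ``spec.start_year`` to its horizon.

    Within each year W(t) is taken from the current pyramid BEFORE it is
    advanced, so year-t births use year-t women; newborn girls from B(t)
    enter age 0 the following year when feedback is enabled. Deterministic
    given its inputs.
    """
    if pop0.year != spec.start_year:
        raise ValueError(
            f"baseline pyramid is for {pop0.year}, scenario starts {spec.start_year}"
        )
    gfr_path = build_path(start_gfr, spec, "gfr")
    ptb_path = build_path(start_ptb_pct, spec, "ptb_pct")
    rows = []
    pops = [pop0]
    pop = pop0
    for t in range(spec.start_year, spec.horizon_year + 1):
        w = women_of_reproductive_age(pop)
        g = gfr_path[t]
        b = project_live_births(w, g)
        p = ptb_path[t]
        ptb = project_preterm_births(b, p)
        rows.append(
            {"year": t, "women_15_49": w, "gfr": g, "live_births": b,
             "ptb_pct": p, "preterm_births": ptb}
        )
        if t < spec.horizon_year:
            newborns = feedback.female_fraction_at_birth * b if feedback.enabled else 0.0
            pop = age_advance(pop, surv, mig, newborns)
            pops.append(pop)
    frame = pd.DataFrame(rows).set_index("year")
    return ProjectionResult(scenario=spec.name, frame=frame, populations=tuple(pops))


def run_scenario_suite(
    pop0: AgeStructuredPopulation,
    surv: SurvivalSchedule,
    mig: MigrationSchedule,
    feedback: FertilityFeedbackSpec,
    specs: list[ScenarioSpec],
    start_gfr: float,
    start_ptb_pct: float,
) -> list[ProjectionResult]:
    """Run several scenarios off the same demographic inputs, in order."""
    if not specs:
        raise ValueError("scenario suite needs at least one spec")
    return [
        run_scenario(pop0, surv, mig, feedback, spec, start_gfr, start_ptb_pct)
        for spec in specs
    ]


def write_projection_csv(results: list[ProjectionResult], path: str | Path) -> None:
    """Write suite output: one row per (scenario, year), counts rounded to
    whole persons at this reporting boundary."""
    frames = []
    for res in results:
        df = res.frame.reset_index()
        df.insert(0, "scenario", res.scenario)
        for col in ("women_15_49", "live_births", "preterm_births"):
            df[col] = df[col].round().astype(int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
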