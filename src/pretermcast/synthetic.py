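"""Seeded generation of self-contained synthetic study bundles.

National single-year pyramids, life-table survival columns and migration
schedules for this kind of analysis are not published alongside the vital
series, so every stage of the pipeline is exercised against synthetic
bundles instead: a smooth baseline pyramid, a survival schedule declining
with age, an optional net-migration profile, and an eleven-year vital
series produced by running the SAME cohort-component engine generatively,

    B(t) = GFR(t) * W(t) / 1000,   PTB(t) = p(t) * B(t),

with GFR and p trajectories inside the observed ranges (GFR ~ 82-95 per
1,000; preterm share ~ 5.3-6.9%) and magnitudes of a Kazakhstan-sized
population (W ~ 4-5 million women, B ~ 350-450 thousand births). With
``noise_sd = 0`` (the reference mode — registry counts are treated as
exact) the generating trajectories are recoverable from the recorded
counts up to integer rounding; multiplicative lognormal noise exists only
to stress the estimators. Noise enters as ``exp(noise_sd * z)`` with the
standard-normal draw ``z`` fixed by the seed, so at a fixed seed the
recovery error shrinks monotonically as ``noise_sd`` does.

Everything is a deterministic function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .demography import (
    DEFAULT_A_MAX,
    DEFAULT_FEMALE_FRACTION,
    AgeStructuredPopulation,
    FertilityFeedbackSpec,
    MigrationSchedule,
    SurvivalSchedule,
    age_advance,
    women_of_reproductive_age,
)
from .indicators import VitalSeries


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    a_max: int = DEFAULT_A_MAX
    history_start: int = 2013
    history_end: int = 2023
    total_females: float = 9_000_000.0
    pyramid_mean_age: float = 36.0
    pyramid_age_spread: float = 29.0
    #: (minimum at the top age, maximum at age 0) survival probabilities.
    survival_band: tuple[float, float] = (0.99, 0.9999)
    #: Total net migrants per year (spread over a young-adult age profile).
    migration_level: float = 0.0
    #: (first-year, last-year) GFR per 1,000; linear in between.
    gfr_range: tuple[float, float] = (95.0, 85.0)
    #: (first-year, last-year) preterm share in percent; linear in between.
    ptb_pct_range: tuple[float, float] = (5.4, 6.8)
    #: Explicit year->value overrides for the two trajectories.
    gfr_trajectory: dict[int, float] | None = None
    ptb_pct_trajectory: dict[int, float] | None = None
    noise_sd: float = 0.0
    female_fraction_at_birth: float = DEFAULT_FEMALE_FRACTION

    def __post_init__(self) -> None:
        if self.total_females <= 0:
            raise ValueError("total_females must be positive")
        lo, hi = self.survival_band
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("survival_band must lie within [0, 1]")
        if self.history_end < self.history_start:
            raise ValueError("history_end before history_start")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for traj, bound in (
            (self._resolve(self.gfr_trajectory, self.gfr_range), None),
            (self._resolve(self.ptb_pct_trajectory, self.ptb_pct_range), 100.0),
        ):
            vals = np.array(list(traj.values()))
            if np.any(vals <= 0) or (bound and np.any(vals >= bound)):
                raise ValueError("trajectory values out of range")

    @property
    def history_years(self) -> list[int]:
        return list(range(self.history_start, self.history_end + 1))

    @property
    def baseline_year(self) -> int:
        """First projection year: the year after the recorded history."""
        return self.history_end + 1

    def _resolve(self, explicit: dict[int, float] | None,
                 endpoints: tuple[float, float]) -> dict[int, float]:
        years = self.history_years
        vals = np.linspace(endpoints[0], endpoints[1], len(years))
        traj = dict(zip(years, vals))
        if explicit:
            traj.update({int(y): float(v) for y, v in explicit.items()})
            missing = set(years) - set(traj)
            if missing:
                raise ValueError(f"trajectory missing years {sorted(missing)}")
        return traj

    def resolved_gfr_trajectory(self) -> dict[int, float]:
        return self._resolve(self.gfr_trajectory, self.gfr_range)

    def resolved_ptb_pct_trajectory(self) -> dict[int, float]:
        return self._resolve(self.ptb_pct_trajectory, self.ptb_pct_range)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % 2**31, stream])


def generate_population_pyramid(config: SyntheticConfig) -> AgeStructuredPopulation:
    """Smooth baseline pyramid at the history start year.

    A Gaussian age profile (mean/spread from the config) with a small
    seeded multiplicative wiggle, rescaled to the configured total.
    """
    rng = _rng(config, 1)
    ages = np.arange(config.a_max + 1)
    shape = np.exp(-0.5 * ((ages - config.pyramid_mean_age) / config.pyramid_age_spread) ** 2)
    shape *= np.exp(rng.normal(0.0, 0.02, size=ages.size))
    counts = shape * (config.total_females / shape.sum())
    return AgeStructuredPopulation(year=config.history_start, counts=counts)


def generate_schedules(config: SyntheticConfig) -> tuple[SurvivalSchedule, MigrationSchedule]:
    """Survival declining smoothly with age inside the configured band,
    plus a year-invariant young-adult migration profile at the configured
    net level (all zeros when the level is 0)."""
    ages = np.arange(config.a_max + 1)
    lo, hi = config.survival_band
    surv = SurvivalSchedule(probabilities=hi - (hi - lo) * (ages / config.a_max) ** 3)
    if config.migration_level == 0:
        mig = MigrationSchedule.zeros(config.a_max)
    else:
        profile = np.exp(-0.5 * ((ages - 27.0) / 8.0) ** 2)
        mig = MigrationSchedule.from_vector(
            profile / profile.sum() * config.migration_level
        )
    return surv, mig


def generate_history(
    config: SyntheticConfig,
    pyramid: AgeStructuredPopulation,
    schedules: tuple[SurvivalSchedule, MigrationSchedule],
) -> tuple[list[AgeStructuredPopulation], VitalSeries]:
    """Run the cohort engine generatively over the history years.

    Returns the pyramid trajectory (history years plus the baseline
    projection year, one extra advance) and the recorded vital series
    including W(t). Recorded counts are rounded to whole persons; the
    engine itself advances on unrounded, noiseless values.
    """
    surv, mig = schedules
    if pyramid.year != config.history_start:
        raise ValueError("pyramid must be dated at the history start year")
    gfr = config.resolved_gfr_trajectory()
    ptb = config.resolved_ptb_pct_trajectory()
    years = config.history_years
    z_b = _rng(config, 2).standard_normal(len(years))
    z_p = _rng(config, 3).standard_normal(len(years))

    pops = [pyramid]
    rows = []
    pop = pyramid
    for i, t in enumerate(years):
        w = women_of_reproductive_age(pop)
        b = gfr[t] * w / 1000.0
        p = ptb[t] / 100.0 * b
        b_rec = round(b * np.exp(config.noise_sd * z_b[i]))
        p_rec = min(round(p * np.exp(config.noise_sd * z_p[i])), b_rec)
        rows.append(
            {"year": t, "live_births": int(b_rec), "preterm_births": int(p_rec),
             "women_15_49": int(round(w))}
        )
        newborns = config.female_fraction_at_birth * b
        pop = age_advance(pop, surv, mig, newborns)
        pops.append(pop)
    return pops, VitalSeries(frame=pd.DataFrame(rows))


def generate_vital_series(
    config: SyntheticConfig,
    pyramid: AgeStructuredPopulation,
    schedules: tuple[SurvivalSchedule, MigrationSchedule],
) -> VitalSeries:
    """The recorded vital series alone (see :func:`generate_history`)."""
    return generate_history(config, pyramid, schedules)[1]


@dataclass(frozen=True)
class StudyBundle:
    """Everything downstream stages consume, in memory."""

    config: SyntheticConfig
    baseline_population: AgeStructuredPopulation  # dated at config.baseline_year
    survival: SurvivalSchedule
    migration: MigrationSchedule
    vitals: VitalSeries
    populations: tuple[AgeStructuredPopulation, ...] = field(repr=False, default=())

    def feedback(self) -> FertilityFeedbackSpec:
        return FertilityFeedbackSpec(
            female_fraction_at_birth=self.config.female_fraction_at_birth
        )


def generate_study_bundle(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> StudyBundle:
    """Generate a full bundle; optionally write its CSV set plus manifest.

    Files written: ``pyramid.csv`` (baseline projection year),
    ``survival.csv``, ``migration.csv``, ``vitals.csv``,
    ``manifest.yaml`` (seed, config echo, generator version).
    """
    pyramid0 = generate_population_pyramid(config)
    schedules = generate_schedules(config)
    pops, vitals = generate_history(config, pyramid0, schedules)
    bundle = StudyBundle(
        config=config,
        baseline_population=pops[-1],
        survival=schedules[0],
        migration=schedules[1],
        vitals=vitals,
        populations=tuple(pops),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.baseline_population.to_csv(out / "pyramid.csv")
        bundle.survival.to_csv(out / "survival.csv")
        bundle.migration.to_csv(out / "migration.csv")
        bundle.vitals.to_csv(out / "vitals.csv")
        manifest = {
            "generator": f"pretermcast {__version__}",
            "seed": config.seed,
            "baseline_year": config.baseline_year,
            "config": _config_to_dict(config),
        }
        (out / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
        )
    return bundle


def _config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("survival_band", "gfr_range", "ptb_pct_range"):
        d[key] = list(d[key])
    return d


def load_study_bundle(in_dir: str | Path) -> StudyBundle:
    """Read a bundle previously written by :func:`generate_study_bundle`."""
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text(encoding="utf-8"))
    cfg_dict = dict(manifest["config"])
    for key in ("survival_band", "gfr_range", "ptb_pct_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    for key in ("gfr_trajectory", "ptb_pct_trajectory"):
        if cfg_dict.get(key):
            cfg_dict[key] = {int(y): float(v) for y, v in cfg_dict[key].items()}
    config = SyntheticConfig(**cfg_dict)
    return StudyBundle(
        config=config,
        baseline_population=AgeStructuredPopulation.from_csv(
            src / "pyramid.csv", year=int(manifest["baseline_year"])
        ),
        survival=SurvivalSchedule.from_csv(src / "survival.csv"),
        migration=MigrationSchedule.from_csv(src / "migration.csv"),
        vitals=VitalSeries.from_csv(src / "vitals.csv"),
    )
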