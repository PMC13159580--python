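"""Age-structured cohort-component projection of the female population.

The engine advances a single-year-of-age population pyramid one calendar
year at a time: each cohort is carried forward with an age-specific
survival probability, net migration is added at the arrival age, newborn
girls enter at age 0, and the top age category ("A_max and older") is an
open interval that retains its own survivors,

    N(a+1, t+1) = N(a, t) * s(a) + M(a+1, t+1)        for 0 <= a < A_max
    N(A_max, t+1) += N(A_max, t) * s(A_max)            (open interval)
    N(0, t+1) = newborn_females + M(0, t+1)

Summing ages 15-49 of any projected year gives W(t), the population of
women of reproductive age that drives the fertility model.

Counts are carried as real numbers throughout; rounding to whole persons
happens only when results are reported.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_A_MAX = 100
REPRODUCTIVE_AGE_LO = 15
REPRODUCTIVE_AGE_HI = 49
#: Share of live births that are girls for a sex ratio at birth of
#: 105.5 boys per 100 girls.
DEFAULT_FEMALE_FRACTION = 100.0 / 205.5


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class AgeStructuredPopulation:
    """Counts of women by single-year age for one calendar year.

    ``counts[a]`` is the number of women aged ``a``; the final entry is the
    open interval "A_max and older".
    """

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if not float(self.year).is_integer():
            raise TypeError(f"year must be an integer, got {self.year!r}")
        object.__setattr__(self, "year", int(self.year))
        arr = _as_float_array(self.counts, "counts")
        if arr.size < 2:
            raise ValueError("pyramid needs at least two age classes")
        if np.any(arr < 0):
            raise ValueError("population counts must be non-negative")
        arr.flags.writeable = False
        object.__setattr__(self, "counts", arr)

    @property
    def a_max(self) -> int:
        return self.counts.size - 1

    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_csv(cls, path, year: int) -> "AgeStructuredPopulation":
        df = pd.read_csv(path)
        _require_columns(df, ["age", "count"], path)
        df = df.sort_values("age")
        ages = df["age"].to_numpy()
        if not np.array_equal(ages, np.arange(ages.size)):
            raise ValueError(f"{path}: ages must be contiguous from 0")
        return cls(year=year, counts=df["count"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"age": np.arange(self.counts.size), "count": self.counts}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SurvivalSchedule:
    """Probabilities s(a) of surviving from age a to age a+1 one year later.

    Time-invariant: the same schedule applies to every projected year.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_float_array(self.probabilities, "probabilities")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        arr.flags.writeable = False
        object.__setattr__(self, "probabilities", arr)

    def __len__(self) -> int:
        return self.probabilities.size

    @classmethod
    def from_csv(cls, path) -> "SurvivalSchedule":
        df = pd.read_csv(path)
        _require_columns(df, ["age", "survival_probability"], path)
        df = df.sort_values("age")
        return cls(probabilities=df["survival_probability"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "age": np.arange(self.probabilities.size),
                "survival_probability": self.probabilities,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class MigrationSchedule:
    """Net migrant counts by age, optionally varying by calendar year.

    ``default`` is a year-invariant age vector applied to any year without
    an explicit override in ``by_year``. Negative entries mean net
    out-migration.
    """

    default: np.ndarray
    by_year: Mapping[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = _as_float_array(self.default, "net migration")
        arr.flags.writeable = False
        object.__setattr__(self, "default", arr)
        clean = {}
        for year, vec in dict(self.by_year).items():
            v = _as_float_array(vec, f"net migration for {year}")
            if v.size != arr.size:
                raise ValueError("per-year migration vectors must match default length")
            v.flags.writeable = False
            clean[int(year)] = v
        object.__setattr__(self, "by_year", clean)

    def __len__(self) -> int:
        return self.default.size

    def net_for(self, year: int) -> np.ndarray:
        """Net-migration age vector applied on arrival in ``year``."""
        return self.by_year.get(int(year), self.default)

    @classmethod
    def zeros(cls, a_max: int = DEFAULT_A_MAX) -> "MigrationSchedule":
        return cls(default=np.zeros(a_max + 1))

    @classmethod
    def from_vector(cls, net_counts: Sequence[float]) -> "MigrationSchedule":
        return cls(default=np.asarray(net_counts, dtype=float))

    @classmethod
    def from_csv(cls, path) -> "MigrationSchedule":
        """Read either CSV dialect: ``age,net_migration`` (year-invariant)
        or ``age,year,net_migration``."""
        df = pd.read_csv(path)
        if set(df.columns) >= {"age", "year", "net_migration"}:
            a_max = int(df["age"].max())
            by_year = {}
            for year, grp in df.groupby("year"):
                vec = np.zeros(a_max + 1)
                vec[grp["age"].to_numpy(dtype=int)] = grp["net_migration"].to_numpy(
                    dtype=float
                )
                by_year[int(year)] = vec
            return cls(default=np.zeros(a_max + 1), by_year=by_year)
        _require_columns(df, ["age", "net_migration"], path)
        df = df.sort_values("age")
        return cls(default=df["net_migration"].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        if self.by_year:
            frames = [
                pd.DataFrame(
                    {"age": np.arange(vec.size), "year": year, "net_migration": vec}
                )
                for year, vec in sorted(self.by_year.items())
            ]
            pd.concat(frames).to_csv(path, index=False)
        else:
            pd.DataFrame(
                {"age": np.arange(self.default.size), "net_migration": self.default}
            ).to_csv(path, index=False)


@dataclass(frozen=True)
class FertilityFeedbackSpec:
    """How projected births re-enter the pyramid as newborn girls.

    Girls born after the baseline year reach age 15 well before a
    mid-century horizon, so without feedback the reproductive-age
    population empties from below.
    """

    female_fraction_at_birth: float = DEFAULT_FEMALE_FRACTION
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.female_fraction_at_birth < 1.0:
            raise ValueError("female_fraction_at_birth must be in (0, 1)")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def _check_lengths(pop: AgeStructuredPopulation, surv: SurvivalSchedule,
                   mig_vec: np.ndarray) -> None:
    n = pop.counts.size
    if len(surv) != n:
        raise ValueError(
            f"survival schedule length {len(surv)} != pyramid length {n}"
        )
    if mig_vec.size != n:
        raise ValueError(
            f"migration vector length {mig_vec.size} != pyramid length {n}"
        )


def age_advance(
    pop: AgeStructuredPopulation,
    surv: SurvivalSchedule,
    mig: MigrationSchedule,
    newborn_females: float = 0.0,
) -> AgeStructuredPopulation:
    """Advance the pyramid one calendar year.

    Survivors of age ``a`` arrive at age ``a+1``; the open top interval
    additionally keeps its own survivors; net migration for the arrival
    year is added at each arrival age; ``newborn_females`` enter at age 0.
    Counts that would go negative after out-migration are floored at zero
    (a warning is logged): person counts cannot be negative.
    """
    if newborn_females < 0:
        raise ValueError("newborn_females must be non-negative")
    next_year = pop.year + 1
    m = mig.net_for(next_year)
    _check_lengths(pop, surv, m)

    survivors = pop.counts * surv.probabilities
    nxt = np.zeros_like(pop.counts)
    nxt[1:] = survivors[:-1]
    nxt[-1] += survivors[-1]  # open interval A_max+ keeps its survivors
    nxt[0] = newborn_females
    nxt = nxt + m
    negative = nxt < 0
    if negative.any():
        logger.warning(
            "net out-migration drove %d cohort(s) negative in %d; floored at 0",
            int(negative.sum()),
            next_year,
        )
        nxt[negative] = 0.0
    return AgeStructuredPopulation(year=next_year, counts=nxt)


def project_population(
    pop0: AgeStructuredPopulation,
    surv: SurvivalSchedule,
    mig: MigrationSchedule,
    feedback: FertilityFeedbackSpec | None = None,
    births_by_year: Mapping[int, float] | None = None,
    *,
    end_year: int,
) -> list[AgeStructuredPopulation]:
    """Project the pyramid from ``pop0.year`` to ``end_year`` inclusive.

    With feedback enabled, ``births_by_year[t]`` (total live births in year
    ``t``) must be supplied for every year ``pop0.year .. end_year - 1``;
    the female share of those births enters age 0 in year ``t + 1``. With
    feedback disabled no newborns enter.
    """
    if end_year <= pop0.year:
        raise ValueError("end_year must lie after the baseline year")
    use_feedback = feedback is not None and feedback.enabled
    trajectory = [pop0]
    for t in range(pop0.year, end_year):
        newborns = 0.0
        if use_feedback:
            if births_by_year is None or t not in births_by_year:
                raise KeyError(f"feedback enabled but no births supplied for year {t}")
            newborns = feedback.female_fraction_at_birth * float(births_by_year[t])
        trajectory.append(age_advance(trajectory[-1], surv, mig, newborns))
    return trajectory


def women_of_reproductive_age(
    pop: AgeStructuredPopulation,
    age_lo: int = REPRODUCTIVE_AGE_LO,
    age_hi: int = REPRODUCTIVE_AGE_HI,
) -> float:
    """W(t): inclusive sum of counts over ages [age_lo, age_hi]."""
    if not 0 <= age_lo <= age_hi <= pop.a_max:
        raise ValueError(
            f"age bounds [{age_lo}, {age_hi}] outside pyramid [0, {pop.a_max}]"
        )
    return float(pop.counts[age_lo : age_hi + 1].sum())
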