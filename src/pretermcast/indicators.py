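"""Historical fertility and preterm-birth indicators from annual vital series.

Given year-indexed counts of live births B(t), preterm births PTB(t) and
(optionally) women of reproductive age W(t), this module computes

* the general fertility rate  GFR(t) = B(t) / W(t) * 1000  (per 1,000 women
  aged 15-49),
* the preterm-birth proportion  p(t) = PTB(t) / B(t),
* annual percent change of any count series versus the preceding year.

Full precision is kept internally; display values are rounded
half-away-from-zero to two decimals, the convention of the national
statistical tables this package reproduces.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .util import round_half_away

VITALS_COLUMNS = ["year", "live_births", "preterm_births"]


@dataclass(frozen=True)
class VitalSeries:
    """Year-indexed live births, preterm births and (optional) W(t).

    Backed by a DataFrame indexed by calendar year with columns
    ``live_births``, ``preterm_births`` and optionally ``women_15_49``.
    Years must be strictly increasing and contiguous, counts non-negative
    integers, and PTB(t) <= B(t) every year.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "year" in df.columns:
            df = df.set_index("year")
        df.index = df.index.astype(int)
        df.index.name = "year"
        for col in ("live_births", "preterm_births"):
            if col not in df.columns:
                raise ValueError(f"vital series missing column {col!r}")
        years = df.index.to_numpy()
        if len(years) == 0:
            raise ValueError("vital series is empty")
        if not np.array_equal(years, np.arange(years[0], years[0] + len(years))):
            raise ValueError("years must be strictly increasing and contiguous")
        counts = df[[c for c in df.columns if c != "year"]]
        arr = counts.to_numpy(dtype=float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("counts must be finite and non-negative")
        if np.any(np.mod(arr, 1) != 0):
            raise ValueError("counts must be integers")
        if np.any(df["preterm_births"] > df["live_births"]):
            raise ValueError("preterm births cannot exceed live births")
        object.__setattr__(self, "frame", df.astype(int))

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame.index]

    @property
    def has_women(self) -> bool:
        return "women_15_49" in self.frame.columns

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "VitalSeries":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: empty or unreadable vitals CSV") from exc
        missing = [c for c in VITALS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
        for col in df.columns:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
                )
        return cls(frame=df)

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class IndicatorSeries:
    """Derived indicator table: one row per year.

    Columns: ``gfr`` (per 1,000 women; NaN when W(t) unavailable),
    ``ptb_pct``, ``live_birth_change_pct``, ``ptb_change_pct`` (the change
    columns are NaN for the first year, which has no predecessor).
    """

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IndicatorSeries":
        return cls(frame=pd.read_csv(path).set_index("year"))


def general_fertility_rate(births: float, women: float, year: int | None = None) -> float:
    """GFR = births per 1,000 women of reproductive age. Unrounded."""
    if births < 0:
        raise ValueError("births must be non-negative")
    if women <= 0:
        where = f" in year {year}" if year is not None else ""
        raise ZeroDivisionError(f"no women of reproductive age{where}: cannot form GFR")
    return births / women * 1000.0


def preterm_proportion(ptb: float, births: float) -> float:
    """p = PTB / B as a proportion in [0, 1] (multiply by 100 for percent)."""
    if births <= 0:
        raise ZeroDivisionError("no live births: preterm proportion undefined")
    if not 0 <= ptb <= births:
        raise ValueError("preterm births must lie in [0, live births]")
    return ptb / births


def annual_percent_change(series: Mapping[int, float] | pd.Series) -> pd.Series:
    """Percent change vs the immediately preceding year, unrounded.

    Defined for the second year onward; the first year has no value.
    Requires contiguous years and positive prior-year values.
    """
    s = pd.Series(dict(series)) if not isinstance(series, pd.Series) else series
    s = s.sort_index()
    years = s.index.to_numpy()
    if len(years) < 2:
        raise ValueError("need at least two consecutive years")
    if not np.array_equal(np.diff(years), np.ones(len(years) - 1)):
        raise ValueError("years must be contiguous")
    prior = s.shift(1)
    if (prior.iloc[1:] <= 0).any():
        bad = int(prior.iloc[1:][prior.iloc[1:] <= 0].index[0])
        raise ZeroDivisionError(f"non-positive prior-year value before {bad}")
    change = (s - prior) / prior * 100.0
    return change.iloc[1:]


def summarize_vitals(vitals: VitalSeries, *, rounded: bool = True) -> IndicatorSeries:
    """Build the full indicator table from a vital series.

    Reproduces the derived columns of an annual statistics table: preterm
    rate (%), annual percent change in live and preterm births, and GFR
    where W(t) is present. ``rounded=False`` returns full precision.
    """
    df = vitals.frame
    out = pd.DataFrame(index=df.index.copy())
    if vitals.has_women:
        out["gfr"] = [
            general_fertility_rate(b, w, year=y)
            for y, b, w in zip(df.index, df["live_births"], df["women_15_49"])
        ]
    else:
        out["gfr"] = np.nan
    out["ptb_pct"] = [
        preterm_proportion(p, b) * 100.0
        for p, b in zip(df["preterm_births"], df["live_births"])
    ]
    if len(df) >= 2:
        out["live_birth_change_pct"] = annual_percent_change(df["live_births"])
        out["ptb_change_pct"] = annual_percent_change(df["preterm_births"])
    else:
        out["live_birth_change_pct"] = np.nan
        out["ptb_change_pct"] = np.nan
    if rounded:
        for col in out.columns:
            out[col] = [
                round_half_away(v) if pd.notna(v) else np.nan for v in out[col]
            ]
    return IndicatorSeries(frame=out)
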