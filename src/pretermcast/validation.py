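"""Out-of-sample back-testing of preterm-birth predictions.

The model is calibrated on an early window of the vital series and scored
on a later, disjoint holdout window with mean absolute error and root
mean square error (both in units of preterm cases). The default predictor
carries the calibration-window mean rates forward: the mean preterm
proportion is applied either to observed live births in the holdout years
("proportion-only" mode, no demographic inputs needed) or to live births
projected from the cohort-component pyramid via the mean GFR.

The prediction rule is pluggable because published validation tables are
sometimes reported without the rule that produced them; such tables can
still be scored here by loading their observed/predicted pairs directly.
"""

from __future__ import annotations

import math
from collections.abc import Callable, Mapping
from dataclasses import dataclass

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
from .indicators import VitalSeries
from .scenarios import project_live_births

YearRange = tuple[int, int]


def _check_pairs(observed: Mapping[int, float], predicted: Mapping[int, float]) -> list[int]:
    if not observed:
        raise ValueError("need at least one observed/predicted pair")
    if set(observed) != set(predicted):
        raise ValueError("observed and predicted must cover identical years")
    return sorted(observed)


def mean_absolute_error(observed: Mapping[int, float], predicted: Mapping[int, float]) -> float:
    """Mean of |observed - predicted| over shared years."""
    years = _check_pairs(observed, predicted)
    return float(np.mean([abs(observed[y] - predicted[y]) for y in years]))


def root_mean_square_error(observed: Mapping[int, float], predicted: Mapping[int, float]) -> float:
    """Quadratic mean of the errors over shared years."""
    years = _check_pairs(observed, predicted)
    return float(
        math.sqrt(np.mean([(observed[y] - predicted[y]) ** 2 for y in years]))
    )


@dataclass(frozen=True)
class DemographicInputs:
    """Pyramid and schedules needed to project W(t) over the holdout."""

    pop0: AgeStructuredPopulation
    surv: SurvivalSchedule
    mig: MigrationSchedule
    feedback: FertilityFeedbackSpec


@dataclass(frozen=True)
class ValidationReport:
    """Per-year absolute errors plus MAE and RMSE for one back-test split."""

    frame: pd.DataFrame  # index year; observed, predicted, absolute_error
    mae: float
    rmse: float
    calibration_window: YearRange | None = None
    holdout_window: YearRange | None = None

    def __post_init__(self) -> None:
        if (self.frame["absolute_error"] < 0).any():
            raise ValueError("absolute errors must be non-negative")
        if self.rmse < self.mae - 1e-9:
            raise ValueError("RMSE cannot be smaller than MAE")
        if self.calibration_window and self.holdout_window:
            if self.calibration_window[1] >= self.holdout_window[0]:
                raise ValueError("calibration window must end before holdout begins")

    @classmethod
    def from_pairs(
        cls,
        observed: Mapping[int, float],
        predicted: Mapping[int, float],
        calibration_window: YearRange | None = None,
        holdout_window: YearRange | None = None,
    ) -> "ValidationReport":
        years = _check_pairs(observed, predicted)
        frame = pd.DataFrame(
            {
                "observed": [observed[y] for y in years],
                "predicted": [predicted[y] for y in years],
            },
            index=pd.Index(years, name="year"),
        )
        frame["absolute_error"] = (frame["observed"] - frame["predicted"]).abs()
        return cls(
            frame=frame,
            mae=mean_absolute_error(observed, predicted),
            rmse=root_mean_square_error(observed, predicted),
            calibration_window=calibration_window,
            holdout_window=holdout_window,
        )

    def to_csv(self, path) -> None:
        """Rows only; metrics are emitted separately (key-value lines)."""
        self.frame.reset_index().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        calibration_window: YearRange | None = None,
        holdout_window: YearRange | None = None,
    ) -> "ValidationReport":
        df = pd.read_csv(path)
        return cls.from_pairs(
            dict(zip(df["year"], df["observed"])),
            dict(zip(df["year"], df["predicted"])),
            calibration_window=calibration_window,
            holdout_window=holdout_window,
        )

    def metrics_lines(self) -> str:
        return f"mae={self.mae}\nrmse={self.rmse}"


def _validate_windows(vitals: VitalSeries, cal: YearRange, hold: YearRange) -> None:
    years = set(vitals.years)
    for name, (lo, hi) in (("calibration", cal), ("holdout", hold)):
        if lo > hi:
            raise ValueError(f"{name} window reversed: {lo} > {hi}")
        if not set(range(lo, hi + 1)) <= years:
            raise ValueError(f"{name} window {lo}-{hi} outside the vital series")
    if cal[1] >= hold[0]:
        raise ValueError("windows must be disjoint with calibration first")


PredictorRule = Callable[[pd.DataFrame, list[int]], Mapping[int, float]]


def backtest(
    vitals: VitalSeries,
    calibration_window: YearRange,
    holdout_window: YearRange,
    predictor_rule: str | PredictorRule = "carry_forward_means",
    demographic_inputs: DemographicInputs | None = None,
) -> ValidationReport:
    """Calibrate on the early window, predict PTB over the holdout, score.

    The built-in ``"carry_forward_means"`` rule averages the calibration
    preterm proportion and applies it to observed holdout live births, or
    — when ``demographic_inputs`` are given — to births projected from the
    pyramid under the calibration mean GFR (requires a ``women_15_49``
    column in the calibration window). A callable
    ``rule(calibration_frame, holdout_years) -> {year: predicted}`` may be
    supplied instead.
    """
    _validate_windows(vitals, calibration_window, holdout_window)
    df = vitals.frame
    cal = df.loc[calibration_window[0] : calibration_window[1]]
    holdout_years = list(range(holdout_window[0], holdout_window[1] + 1))
    observed = {y: float(df.loc[y, "preterm_births"]) for y in holdout_years}

    if callable(predictor_rule):
        predicted = dict(predictor_rule(cal, holdout_years))
    elif predictor_rule == "carry_forward_means":
        p_bar = float((cal["preterm_births"] / cal["live_births"]).mean())
        if demographic_inputs is None:
            predicted = {
                y: p_bar * float(df.loc[y, "live_births"]) for y in holdout_years
            }
        else:
            if "women_15_49" not in cal.columns:
                raise ValueError(
                    "demographic back-test needs women_15_49 in the calibration window"
                )
            gfr_bar = float(
                (cal["live_births"] / cal["women_15_49"] * 1000.0).mean()
            )
            dem = demographic_inputs
            if dem.pop0.year != holdout_window[0]:
                raise ValueError(
                    f"pyramid is for {dem.pop0.year}, holdout starts {holdout_window[0]}"
                )
            predicted = {}
            pop = dem.pop0
            for y in holdout_years:
                b = project_live_births(women_of_reproductive_age(pop), gfr_bar)
                predicted[y] = p_bar * b
                if y < holdout_window[1]:
                    newborns = (
                        dem.feedback.female_fraction_at_birth * b
                        if dem.feedback.enabled
                        else 0.0
                    )
                    pop = age_advance(pop, dem.surv, dem.mig, newborns)
    else:
        raise ValueError(f"unknown predictor_rule {predictor_rule!r}")

    return ValidationReport.from_pairs(
        observed, predicted, calibration_window, holdout_window
    )
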