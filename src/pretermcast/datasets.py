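"""Packaged reference datasets.

Small CSVs shipped with the package so the historical analysis and the
back-test metrics can be reproduced offline:

* Kazakhstan annual live births and preterm births, 2013-2023, from
  official national statistical publications;
* the derived indicator columns exactly as printed in those publications
  (kept as metadata: a handful of printed cells differ from recomputation
  by 0.01, consistent with truncation at the source);
* the published 2019-2023 back-test observed/predicted pairs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .indicators import VitalSeries
from .validation import ValidationReport

#: Calibration / holdout split used by the published back-test.
CALIBRATION_WINDOW = (2013, 2018)
HOLDOUT_WINDOW = (2019, 2023)


def _data_path(name: str):
    return resources.files("pretermcast.data") / name


def load_vital_series() -> VitalSeries:
    """Kazakhstan live and preterm birth counts, 2013-2023."""
    return VitalSeries.from_csv(_data_path("kazakhstan_vitals_2013_2023.csv"))


def load_printed_indicators() -> pd.DataFrame:
    """Derived indicator columns as printed at the source (metadata).

    Most cells agree with recomputation under half-away-from-zero
    rounding; six do not (the 2013 and 2020 preterm rates and four annual
    change cells), each by exactly 0.01.
    """
    return pd.read_csv(
        _data_path("kazakhstan_printed_indicators_2013_2023.csv")
    ).set_index("year")


def load_backtest_pairs() -> pd.DataFrame:
    """Published observed/predicted preterm births for 2019-2023."""
    return pd.read_csv(_data_path("kazakhstan_backtest_2019_2023.csv")).set_index(
        "year"
    )


def load_backtest_report() -> ValidationReport:
    """The published back-test pairs scored with this package's metrics."""
    df = load_backtest_pairs()
    return ValidationReport.from_pairs(
        dict(zip(df.index, df["observed"])),
        dict(zip(df.index, df["predicted"])),
        calibration_window=CALIBRATION_WINDOW,
        holdout_window=HOLDOUT_WINDOW,
    )
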