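"""Coordinate systems of the seasonal BNF analysis.

Two conversions underpin everything downstream:

* the **relative abundance of ureides** (RAU, %), a stem-tissue proxy for
  the fraction of plant nitrogen derived from symbiotic fixation, computed
  from ureide and nitrate concentrations as ``100 * 4U / (4U + N)``; and
* **cumulative thermal time** (degree-days, °Cd) above a base temperature
  (8 °C for soybean), the developmental clock on which seasonal RAU
  trajectories are expressed.  The clock origin is the V2 stage.

RAU is a ratio of like quantities, so any single consistent concentration
unit (e.g. µmol per g dry stem) is acceptable; readers enforce one unit
column-wide.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    StageOrderError,
    UndefinedRauError,
    WeatherGapError,
)

#: Soybean base temperature for degree-day accumulation, °C.
DEFAULT_BASE_TEMP = 8.0


class Treatment(str, Enum):
    """Nitrogen fertilization treatments of the multi-site trial."""

    control = "control"
    N_sowing = "N_sowing"
    N_V4 = "N_V4"
    N_R2 = "N_R2"


class Stage(str, Enum):
    """Sampling stages (Fehr & Caviness scale).

    The flowering-stage sample is labelled R2 even where sampling ran into
    early pod formation (R3); the pipeline does not distinguish the two.
    """

    V4 = "V4"
    R2 = "R2"
    R6 = "R6"
    R8 = "R8"


#: Canonical ordering of the sampled stages.
STAGE_ORDER = (Stage.V4, Stage.R2, Stage.R6, Stage.R8)


@dataclass(frozen=True)
class UreideAssay:
    """One stem-sample ureide/nitrate measurement at one stage.

    Concentrations must share a unit basis; RAU is unit-invariant.
    """

    site_id: str
    treatment: Treatment
    block: int
    stage: Stage
    ureide_conc: float
    nitrate_conc: float

    def rau(self) -> float:
        return compute_rau(self.ureide_conc, self.nitrate_conc)


@dataclass(frozen=True)
class WeatherRecord:
    """Daily maximum and minimum air temperature (°C) for one calendar day."""

    date: _dt.date
    t_max: float
    t_min: float

    def __post_init__(self):
        if self.t_max < self.t_min:
            raise DomainError(
                f"{self.date}: t_max ({self.t_max}) < t_min ({self.t_min})"
            )


def compute_rau(ureide_conc, nitrate_conc):
    """Relative abundance of ureides, %.

    RAU = 100 * 4U / (4U + N), the standard ureide index of biological
    N fixation in stem tissue.  Accepts scalars or numpy arrays on any
    single consistent concentration unit (the ratio is unit-invariant).

    Raises
    ------
    UndefinedRauError
        if ureide and nitrate are both zero (0/0).
    DomainError
        if either concentration is negative.
    """
    u = np.asarray(ureide_conc, dtype=float)
    n = np.asarray(nitrate_conc, dtype=float)
    if np.any(u < 0) or np.any(n < 0):
        raise DomainError("concentrations must be non-negative")
    denom = 4.0 * u + n
    if np.any(denom == 0):
        raise UndefinedRauError("ureide and nitrate are both zero; RAU undefined")
    out = 100.0 * 4.0 * u / denom
    return float(out) if out.ndim == 0 else out


def _weather_frame(weather) -> pd.DataFrame:
    """Normalize weather input (records, DataFrame) to a date-indexed frame."""
    if isinstance(weather, pd.DataFrame):
        df = weather.copy()
        cols = {c.lower(): c for c in df.columns}
        date_col = cols.get("date")
        tmax_col = cols.get("tmax_c") or cols.get("t_max")
        tmin_col = cols.get("tmin_c") or cols.get("t_min")
        if date_col is None or tmax_col is None or tmin_col is None:
            raise DomainError(
                "weather frame needs columns date, tmax_c, tmin_c"
            )
        df = df[[date_col, tmax_col, tmin_col]]
        df.columns = ["date", "t_max", "t_min"]
    else:
        df = pd.DataFrame(
            [(w.date, w.t_max, w.t_min) for w in weather],
            columns=["date", "t_max", "t_min"],
        )
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df = df.drop_duplicates(subset="date").set_index("date").sort_index()
    return df


def daily_thermal_increment(t_max, t_min, base_temp=DEFAULT_BASE_TEMP):
    """Degree-day contribution of one day: max(0, (Tmax+Tmin)/2 - Tb).

    Negative increments are clamped to zero — backward development is
    biologically meaningless and clamping is the standard degree-day
    convention.  No upper temperature cutoff is applied.
    """
    return np.maximum(0.0, (np.asarray(t_max) + np.asarray(t_min)) / 2.0 - base_temp)


def accumulate_thermal_time(
    weather,
    base_temp: float = DEFAULT_BASE_TEMP,
    start: _dt.date | None = None,
    end: _dt.date | None = None,
) -> float:
    """Cumulative thermal time (°Cd) over the inclusive day range [start, end].

    Sums the clamped daily increment over every calendar day of the range.
    The weather series must cover the whole range.

    Raises
    ------
    WeatherGapError
        listing the missing dates, if any day in [start, end] is absent.
    """
    df = _weather_frame(weather)
    if start is None:
        start = df.index.min()
    if end is None:
        end = df.index.max()
    start = pd.Timestamp(start).date()
    end = pd.Timestamp(end).date()
    if end < start:
        raise DomainError(f"end ({end}) precedes start ({start})")
    wanted = pd.date_range(start, end, freq="D").date
    missing = [d for d in wanted if d not in df.index]
    if missing:
        raise WeatherGapError(missing)
    sub = df.loc[list(wanted)]
    return float(
        daily_thermal_increment(sub["t_max"].to_numpy(), sub["t_min"].to_numpy(), base_temp).sum()
    )


@dataclass
class ThermalClock:
    """Cumulative degree-day clock anchored at a crop-stage origin (V2).

    The clock reads 0 at ``origin_date``; the increment of a later day d is
    accrued on d itself, i.e. ``at(d)`` sums increments over (origin, d].
    This half-open convention makes readings additive and pins the origin
    reading to exactly zero.
    """

    weather: pd.DataFrame
    origin_date: _dt.date
    base_temp: float = DEFAULT_BASE_TEMP
    cumulative: pd.Series = field(init=False, repr=False)

    def __post_init__(self):
        df = _weather_frame(self.weather)
        self.origin_date = pd.Timestamp(self.origin_date).date()
        if self.origin_date not in df.index:
            raise WeatherGapError([self.origin_date])
        df = df.loc[df.index >= self.origin_date]
        full = pd.date_range(df.index.min(), df.index.max(), freq="D").date
        missing = [d for d in full if d not in df.index]
        if missing:
            raise WeatherGapError(missing)
        inc = daily_thermal_increment(
            df["t_max"].to_numpy(), df["t_min"].to_numpy(), self.base_temp
        )
        cum = np.cumsum(inc)
        # shift so the origin day reads 0; day d carries the increment of d
        cum = cum - cum[0]
        self.weather = df
        self.cumulative = pd.Series(cum, index=df.index)

    def at(self, date: _dt.date) -> float:
        """Thermal time (°Cd) accumulated from the origin to ``date``."""
        date = pd.Timestamp(date).date()
        if date < self.origin_date:
            raise StageOrderError(
                f"date {date} precedes clock origin {self.origin_date}"
            )
        if date not in self.cumulative.index:
            raise WeatherGapError([date])
        return float(self.cumulative.loc[date])


def stage_thermal_times(
    weather,
    stage_dates: Mapping[Stage | str, _dt.date],
    clock: ThermalClock | None = None,
    *,
    origin_date: _dt.date | None = None,
    base_temp: float = DEFAULT_BASE_TEMP,
) -> dict[Stage, float]:
    """Map each phenological stage to its cumulative °Cd from the clock origin.

    Either pass a prebuilt ``clock`` or an ``origin_date`` from which one is
    constructed.  Stage dates before the origin raise ``StageOrderError``.
    """
    if clock is None:
        if origin_date is None:
            raise DomainError("provide a ThermalClock or an origin_date")
        clock = ThermalClock(weather, origin_date, base_temp)
    out: dict[Stage, float] = {}
    for stage, date in stage_dates.items():
        out[Stage(stage)] = clock.at(date)
    return out
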