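"""Phase-aware growing-degree-day (GDD) accumulation with cardinal temperatures.

Thermal time drives wheat development: each day contributes

    GDD = clamp(Tmean, T_base, T_opt) - T_base,        Tmean = (Tmax + Tmin)/2,

with the whole day zeroed when Tmax exceeds the phase's ceiling temperature —
development stalls under supra-ceiling heat.  Cardinal temperatures
(base/optimum/ceiling) differ by phase: vegetative growth tolerates more heat
than grain filling.  The default triplets are the wheat values of the
Porter & Gawith cardinal-temperature synthesis:

    vegetative (sowing → anthesis)    :  4.0 / 22.0 / 32.7 °C
    anthesis → grain filling          :  9.5 / 21.0 / 31.0 °C
    grain filling → maturity          :  9.2 / 20.7 / 35.4 °C

An optional trapezoidal response mode ramps the contribution back down
between optimum and ceiling instead of holding the optimum plateau; the
plateau ("clamp") rule is the default.

Days with Tmax above ``heat_zero_threshold`` (default 35 °C, the terminal
heat-stress threshold for grain filling) are counted separately as
``n_days_above_35``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import WeatherSeries, add_days_inclusive, day_count_inclusive

__all__ = [
    "CardinalTemps",
    "Phase",
    "PhaseSchedule",
    "GDDResult",
    "NonAttainment",
    "VEGETATIVE",
    "ANTHESIS_TO_GRAINFILL",
    "GRAINFILL_TO_MATURITY",
    "daily_gdd",
    "season_gdd",
    "days_to_reach",
    "default_schedule",
]


@dataclass(frozen=True)
class CardinalTemps:
    """Base / optimum / ceiling temperatures (°C) of one development phase."""

    t_base: float
    t_opt: float
    t_ceil: float

    def __post_init__(self):
        if not self.t_base < self.t_opt < self.t_ceil:
            raise ValueError(
                f"cardinal temperatures must satisfy base < opt < ceil, got "
                f"{self.t_base} / {self.t_opt} / {self.t_ceil}"
            )


VEGETATIVE = CardinalTemps(4.0, 22.0, 32.7)
ANTHESIS_TO_GRAINFILL = CardinalTemps(9.5, 21.0, 31.0)
GRAINFILL_TO_MATURITY = CardinalTemps(9.2, 20.7, 35.4)


@dataclass(frozen=True)
class Phase:
    label: str
    start_day: int  # day-after-sowing (inclusive convention: sowing = day 1)
    cardinals: CardinalTemps


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered development phases, each starting at a day-after-sowing.

    The first phase must start at day 1 and starts must strictly increase.
    """

    phases: tuple[Phase, ...]
    heat_zero_threshold: float = 35.0
    response: str = "clamp"  # or "trapezoid"

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        starts = [p.start_day for p in self.phases]
        if starts[0] != 1:
            raise ValueError("first phase must start at day 1")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("phase start days must strictly increase")
        if self.response not in ("clamp", "trapezoid"):
            raise ValueError(f"unknown response mode {self.response!r}")

    def cardinals_for_day(self, day_after_sowing: int) -> CardinalTemps:
        chosen = self.phases[0].cardinals
        for p in self.phases:
            if day_after_sowing >= p.start_day:
                chosen = p.cardinals
        return chosen


def default_schedule(
    dta_days: int,
    flowering_duration: int = 10,
    heat_zero_threshold: float = 35.0,
    response: str = "clamp",
) -> PhaseSchedule:
    """Three-phase schedule from a known days-to-anthesis.

    Vegetative covers days 1..dta; the anthesis→grain-fill phase the next
    ``flowering_duration`` days; grain-fill→maturity the remainder.
    """
    if dta_days < 1:
        raise ValueError("dta_days must be >= 1")
    return PhaseSchedule(
        (
            Phase("vegetative", 1, VEGETATIVE),
            Phase("anthesis_to_grainfill", dta_days + 1, ANTHESIS_TO_GRAINFILL),
            Phase("grainfill_to_maturity", dta_days + 1 + flowering_duration,
                  GRAINFILL_TO_MATURITY),
        ),
        heat_zero_threshold=heat_zero_threshold,
        response=response,
    )


def daily_gdd(
    tmax: float, tmin: float, cardinals: CardinalTemps, response: str = "clamp"
) -> float:
    """One day's thermal-time contribution (°C·day).

    ``clamp`` (default): Tmean is clamped to [t_base, t_opt] before
    subtracting t_base, and the day is zeroed when Tmax exceeds t_ceil.
    ``trapezoid``: between optimum and ceiling the contribution declines
    linearly from (t_opt - t_base) to zero at the ceiling.
    """
    if tmax < tmin:
        raise ValueError(f"tmax {tmax} < tmin {tmin}")
    if tmax > cardinals.t_ceil:
        return 0.0
    tmean = 0.5 * (tmax + tmin)
    if response == "trapezoid" and tmean > cardinals.t_opt:
        span = cardinals.t_ceil - cardinals.t_opt
        frac = max(0.0, (cardinals.t_ceil - tmean) / span)
        return (cardinals.t_opt - cardinals.t_base) * frac
    tmean = min(max(tmean, cardinals.t_base), cardinals.t_opt)
    return tmean - cardinals.t_base


@dataclass
class GDDResult:
    """Seasonal accumulation: daily and cumulative GDD plus heat-day counts."""

    dates: pd.Series
    daily_gdd: np.ndarray
    n_ceiling_days: int
    n_days_above_35: int

    @property
    def cumulative_gdd(self) -> np.ndarray:
        return np.cumsum(self.daily_gdd)

    @property
    def total_gdd(self) -> float:
        return float(self.daily_gdd.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.values,
                "daily_gdd": self.daily_gdd,
                "cumulative_gdd": self.cumulative_gdd,
            }
        )


def season_gdd(
    series: WeatherSeries,
    sowing: dt.date,
    schedule: PhaseSchedule,
    end: dt.date,
) -> GDDResult:
    """Accumulate GDD from *sowing* to *end* (both inclusive), choosing each
    day's cardinal temperatures by its day-after-sowing phase.

    Also counts days whose Tmax exceeds the active phase ceiling
    (``n_ceiling_days``) and days above ``schedule.heat_zero_threshold``
    (``n_days_above_35``)."""
    sub = series.slice(sowing, end)
    n = len(sub)
    tmax = sub.data["tmax"].to_numpy()
    tmin = sub.data["tmin"].to_numpy()
    daily = np.empty(n)
    n_ceiling = 0
    for i in range(n):
        cards = schedule.cardinals_for_day(i + 1)
        daily[i] = daily_gdd(tmax[i], tmin[i], cards, schedule.response)
        if tmax[i] > cards.t_ceil:
            n_ceiling += 1
    n_above = int((tmax > schedule.heat_zero_threshold).sum())
    return GDDResult(sub.dates, daily, n_ceiling, n_above)


class NonAttainment:
    """Distinguished result: the GDD target was not reached before the series
    (or the accumulation window) ended."""

    def __init__(self, target: float, achieved: float, n_days: int):
        self.target = target
        self.achieved = achieved
        self.n_days = n_days

    def __repr__(self):
        return (
            f"NonAttainment(target={self.target}, achieved={self.achieved:.1f} "
            f"over {self.n_days} days)"
        )

    def __bool__(self):  # allows `if result: ...` on the day number
        return False


def days_to_reach(
    series: WeatherSeries,
    sowing: dt.date,
    target_gdd: float,
    schedule: PhaseSchedule,
    end: dt.date | None = None,
) -> int | NonAttainment:
    """Smallest day-after-sowing (sowing = day 1) at which cumulative GDD
    reaches *target_gdd*; a :class:`NonAttainment` if the series ends first.
    """
    if target_gdd <= 0:
        raise ValueError("target_gdd must be > 0")
    if end is None:
        end = series.end_date
    result = season_gdd(series, sowing, schedule, end)
    cum = result.cumulative_gdd
    hits = np.nonzero(cum >= target_gdd)[0]
    if len(hits) == 0:
        return NonAttainment(target_gdd, float(cum[-1]), len(cum))
    return int(hits[0]) + 1
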