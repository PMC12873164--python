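"""Sowing-date scenario analysis, stage-partitioned rainfall, and farm-gate
economics.

The scenario machinery answers the core adaptation question: how much warmer
is the flowering window when sowing is delayed?  Each scenario fixes a sowing
(month, day) and a site-typical days-to-anthesis; the anthesis date follows by
inclusive day arithmetic (sowing day = day 1), and the flowering-window
temperature is the long-term mean of daily Tmean over the
``flowering_duration``-day window starting at anthesis, averaged over every
season present in the weather series.

The relative temperature rise between the earliest and a later sowing is
reported as (T_k − T_first) / T_k × 100 — the denominator is the *later*
sowing's temperature, the convention under which the canonical scenario
tables are internally consistent.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .weather import (
    WHEAT_SEASON,
    CoverageError,
    SeasonWindow,
    WeatherSeries,
    add_days_inclusive,
    extract_season,
    season_bounds,
)

__all__ = [
    "SowingScenario",
    "ScenarioResult",
    "EconResult",
    "DEFAULT_SOWING_DATES",
    "standard_scenarios",
    "anthesis_date",
    "flowering_window_temp",
    "relative_rise",
    "scenario_table",
    "stage_rainfall",
    "econ_value",
]

#: The five canonical sowing dates, 15 Oct (SD1) .. 24 Nov (SD5) in 10-day steps.
DEFAULT_SOWING_DATES = [
    ("SD1", (10, 15)),
    ("SD2", (10, 25)),
    ("SD3", (11, 4)),
    ("SD4", (11, 14)),
    ("SD5", (11, 24)),
]

#: Site-typical long-term mean days to anthesis.
SITE_DTA = {"islamabad": 105, "chakwal": 100}

#: Non-leap reference year used for scenario date arithmetic (dates quoted in
#: scenario tables follow non-leap counting).
REFERENCE_YEAR = 2001


@dataclass(frozen=True)
class SowingScenario:
    label: str
    sowing: tuple[int, int]  # (month, day)
    dta_days: int
    flowering_duration: int = 10

    def __post_init__(self):
        if self.dta_days < 1:
            raise ValueError("dta_days must be >= 1")
        if self.flowering_duration < 1:
            raise ValueError("flowering_duration must be >= 1")


def standard_scenarios(dta_days: int, flowering_duration: int = 10) -> list[SowingScenario]:
    """The five standard sowing-date scenarios with a fixed site DTA."""
    return [
        SowingScenario(label, sowing, dta_days, flowering_duration)
        for label, sowing in DEFAULT_SOWING_DATES
    ]


@dataclass
class ScenarioResult:
    scenario: SowingScenario
    anthesis: dt.date
    window_start: dt.date
    window_end: dt.date
    window_tmean: float
    relative_rise_vs_first: float
    yield_loss_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.scenario.label,
            "sowing": f"{self.scenario.sowing[1]:02d}-{_MON[self.scenario.sowing[0]]}",
            "dta_days": self.scenario.dta_days,
            "anthesis": f"{self.anthesis.day:02d}-{_MON[self.anthesis.month]}",
            "flowering_duration": f"{self.scenario.flowering_duration} Days",
            "window_tmean_C": round(self.window_tmean, 2),
            "relative_rise_pct": round(self.relative_rise_vs_first, 2),
            "yield_loss_pct": self.yield_loss_pct,
        }


_MON = {i: m for i, m in enumerate(
    ["", "Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"], start=0)}


def anthesis_date(scenario: SowingScenario, reference_year: int = REFERENCE_YEAR) -> dt.date:
    """Anthesis date: day ``dta_days`` counted inclusively from sowing.

    The sowing falls in ``reference_year`` (non-leap by default) and anthesis
    rolls into the following calendar year when the count crosses 31 December.
    """
    sowing = dt.date(reference_year, *scenario.sowing)
    return add_days_inclusive(sowing, scenario.dta_days)


def flowering_window_temp(
    series: WeatherSeries,
    anthesis: dt.date | tuple[int, int],
    duration: int = 10,
) -> float:
    """Long-term mean daily Tmean (°C) over the *duration*-day window starting
    at the anthesis (month, day), averaged across every year of the series
    that fully covers the window."""
    if duration < 1:
        raise ValueError("duration must be >= 1")
    if isinstance(anthesis, tuple):
        month, day = anthesis
    else:
        month, day = anthesis.month, anthesis.day
    means = []
    for year in range(series.start_date.year, series.end_date.year + 1):
        try:
            start = dt.date(year, month, day)
        except ValueError:  # 29 Feb in a non-leap year
            continue
        end = start + dt.timedelta(days=duration - 1)
        try:
            sub = series.slice(start, end)
        except CoverageError:
            continue
        means.append(float(sub.tmean.mean()))
    if not means:
        raise CoverageError(
            f"flowering window {month:02d}-{day:02d} (+{duration - 1} d) never "
            "fully covered by the series"
        )
    return float(np.mean(means))


def relative_rise(t_first: float, t_k: float) -> float:
    """Relative rise (%) of the later sowing's flowering temperature over the
    earliest sowing's: (t_k − t_first) / t_k × 100.

    The later value is the denominator; positive iff t_k > t_first.
    """
    if t_k == 0:
        raise ZeroDivisionError("later-scenario temperature is zero")
    return (t_k - t_first) / t_k * 100.0


def scenario_table(
    series: WeatherSeries,
    scenarios: list[SowingScenario],
    yield_losses: list[float] | None = None,
    reference_year: int = REFERENCE_YEAR,
) -> list[ScenarioResult]:
    """Assemble one :class:`ScenarioResult` row per sowing scenario.

    ``yield_losses`` (percent, one per scenario, e.g. from external crop-model
    runs) are carried through verbatim; otherwise the column is left None (the
    sensitivity module's surrogate can fill it in demo mode).
    """
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate scenario labels: {labels}")
    if yield_losses is not None and len(yield_losses) != len(scenarios):
        raise ValueError("yield_losses length must match scenarios")
    results = []
    t_first = None
    for i, scen in enumerate(scenarios):
        anth = anthesis_date(scen, reference_year)
        w_end = add_days_inclusive(anth, scen.flowering_duration)
        tmean = flowering_window_temp(
            series, (anth.month, anth.day), scen.flowering_duration
        )
        if t_first is None:
            t_first = tmean
            rise = 0.0
        else:
            rise = relative_rise(t_first, tmean)
        results.append(
            ScenarioResult(
                scenario=scen,
                anthesis=anth,
                window_start=anth,
                window_end=w_end - dt.timedelta(days=1),
                window_tmean=tmean,
                relative_rise_vs_first=rise,
                yield_loss_pct=None if yield_losses is None else yield_losses[i],
            )
        )
    return results


def stage_rainfall(
    series: WeatherSeries,
    dta_days: int,
    decades: list[tuple[int, int]] | None = None,
    window: SeasonWindow = WHEAT_SEASON,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Seasonal rainfall partitioned at anthesis, summarised by decade.

    For each fully covered season the vegetative stage is days 1..``dta_days``
    after sowing and the reproductive stage the remainder of the season; their
    rain sums conserve the season total exactly.  ``aggregate`` selects decade
    means or sums (the canonical tables do not state which; no default is
    asserted as theirs).
    """
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    rows = []
    for year in range(series.start_date.year, series.end_date.year + 1):
        try:
            season = extract_season(series, year, window)
        except CoverageError:
            continue
        rain = season.data["rain"].to_numpy()
        cut = min(dta_days, len(rain))
        rows.append(
            {
                "harvest_year": year,
                "vegetative_mm": float(rain[:cut].sum()),
                "reproductive_mm": float(rain[cut:].sum()),
            }
        )
    if not rows:
        raise CoverageError("series contains no complete season")
    per_season = pd.DataFrame(rows)
    if decades is None:
        return per_season
    out = []
    for start, end in decades:
        mask = per_season["harvest_year"].between(start, end)
        sub = per_season.loc[mask, ["vegetative_mm", "reproductive_mm"]]
        agg = sub.mean() if aggregate == "mean" else sub.sum()
        out.append(
            {
                "decade": f"{start}–{end}",
                "vegetative_mm": float(agg["vegetative_mm"]) if len(sub) else np.nan,
                "reproductive_mm": float(agg["reproductive_mm"]) if len(sub) else np.nan,
                "n_seasons": int(mask.sum()),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------

#: Pakistani wheat trades in maunds of 40 kg.
KG_PER_MAUND = 40.0

#: Government support price used in the worked examples, PKR per 40-kg maund.
DEFAULT_PRICE_PKR_PER_MAUND = 3100.0


@dataclass(frozen=True)
class EconResult:
    yield_kg: float
    maunds: float
    revenue_pkr: float
    revenue_usd: float

    def to_dict(self) -> dict:
        return {
            "yield_kg_per_ha": self.yield_kg,
            "maunds_per_ha": self.maunds,
            "revenue_pkr_per_ha": self.revenue_pkr,
            "revenue_usd_per_ha": self.revenue_usd,
        }


def econ_value(
    yield_t_ha: float,
    price_pkr_per_40kg: float = DEFAULT_PRICE_PKR_PER_MAUND,
    pkr_per_usd: float = 278.5,
) -> EconResult:
    """Farm-gate value of a grain yield.

    kg = t × 1000; maunds = kg / 40; PKR = maunds × price; USD = PKR / fx.
    The PKR/USD rate is an explicit input (≈278.5 default, a 2023-era market
    rate) since quoted dollar figures depend entirely on it.
    """
    if yield_t_ha < 0:
        raise ValueError("negative yield")
    if price_pkr_per_40kg <= 0:
        raise ValueError("price must be > 0")
    if pkr_per_usd <= 0:
        raise ValueError("exchange rate must be > 0")
    kg = yield_t_ha * 1000.0
    maunds = kg / KG_PER_MAUND
    pkr = maunds * price_pkr_per_40kg
    return EconResult(kg, maunds, pkr, pkr / pkr_per_usd)
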