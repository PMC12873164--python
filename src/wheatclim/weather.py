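"""Daily weather series: domain types, calendar arithmetic, and file I/O.

Everything downstream — growing-degree-day accumulation, seasonal trend
statistics, sowing-date scenarios — operates on a :class:`WeatherSeries`, an
ordered table of daily (Tmax, Tmin, rain) records for one station.

Day counting follows the agronomic convention that the sowing day is day 1
("inclusive" counting): sowing on 15 October with 100 days to anthesis puts
anthesis on 22 January of a non-leap winter.  All calendar arithmetic uses
the real proleptic Gregorian calendar, so leap years are respected.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WeatherValidationError",
    "CoverageError",
    "DailyWeather",
    "SeasonWindow",
    "WeatherSeries",
    "day_count_inclusive",
    "add_days_inclusive",
    "season_bounds",
    "extract_season",
    "seasonal_table",
    "read_weather_table",
    "write_weather_table",
    "write_wth",
    "read_wth",
    "WHEAT_SEASON",
    "NOMINAL_SEASON_LENGTH_DAYS",
]

#: Nominal wheat-season length sometimes quoted for the 15 Oct–30 Apr window.
#: Calendar counting of that window gives 198 days (199 in leap Februaries);
#: the constant is recorded for documentation only and is never used in
#: computation.
NOMINAL_SEASON_LENGTH_DAYS = 196


class WeatherValidationError(ValueError):
    """A weather record or series violates a physical/structural invariant."""


class CoverageError(ValueError):
    """A requested date window is not fully covered by the series."""


# ---------------------------------------------------------------------------
# calendar arithmetic
# ---------------------------------------------------------------------------

def day_count_inclusive(start: dt.date, end: dt.date) -> int:
    """Number of calendar days from *start* to *end*, counting *start* as day 1.

    >>> day_count_inclusive(dt.date(2001, 10, 15), dt.date(2002, 1, 27))
    105
    """
    start, end = _as_date(start), _as_date(end)
    if end < start:
        raise ValueError(f"reversed interval: end {end} precedes start {start}")
    return (end - start).days + 1


def add_days_inclusive(start: dt.date, n: int) -> dt.date:
    """The date that is day *n* when *start* is day 1 (inverse of
    :func:`day_count_inclusive`).
    """
    if n < 1:
        raise ValueError(f"day number must be >= 1 under inclusive counting, got {n}")
    return _as_date(start) + dt.timedelta(days=n - 1)


def _as_date(d) -> dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    raise TypeError(f"expected a date, got {type(d).__name__}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DailyWeather:
    """One day's record: maximum/minimum temperature (°C) and rainfall (mm)."""

    date: dt.date
    tmax: float
    tmin: float
    rain: float = 0.0

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise WeatherValidationError(
                f"{self.date}: tmax {self.tmax} < tmin {self.tmin}"
            )
        if self.rain < 0:
            raise WeatherValidationError(f"{self.date}: negative rainfall {self.rain}")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


@dataclass(frozen=True)
class SeasonWindow:
    """A (month, day)–(month, day) window, possibly spanning a year boundary."""

    start: tuple[int, int] = (10, 15)
    end: tuple[int, int] = (4, 30)
    label: str = "wheat"

    @property
    def crosses_year(self) -> bool:
        return self.start > self.end


#: The default rainfed-wheat growing season, 15 October – 30 April.
WHEAT_SEASON = SeasonWindow((10, 15), (4, 30), "wheat")


def season_bounds(window: SeasonWindow, harvest_year: int) -> tuple[dt.date, dt.date]:
    """Start/end dates of *window* for the season harvested in *harvest_year*."""
    start_year = harvest_year - 1 if window.crosses_year else harvest_year
    return (
        dt.date(start_year, *window.start),
        dt.date(harvest_year, *window.end),
    )


@dataclass
class WeatherSeries:
    """Ordered daily weather records for one site.

    Parameters
    ----------
    data
        DataFrame with columns ``date`` (datetime-like), ``tmax``, ``tmin``
        (°C) and ``rain`` (mm).  Dates must be strictly increasing and, unless
        ``allow_gaps`` is set, consecutive.
    site_id, latitude, longitude
        Station metadata; coordinates are required only for the .WTH writer.
    """

    data: pd.DataFrame
    site_id: str = ""
    latitude: float | None = None
    longitude: float | None = None
    allow_gaps: bool = False

    REQUIRED = ("date", "tmax", "tmin", "rain")

    def __post_init__(self):
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise WeatherValidationError(f"missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df = df.reset_index(drop=True)
        if len(df) == 0:
            raise WeatherValidationError("empty weather series")
        diffs = df["date"].diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            raise WeatherValidationError("dates not strictly increasing / not unique")
        if not self.allow_gaps and (diffs > pd.Timedelta(days=1)).any():
            first = df["date"][diffs.gt(pd.Timedelta(days=1)).reindex(df.index, fill_value=False)].iloc[0]
            raise WeatherValidationError(
                f"gap in daily record before {first.date()}; "
                "pass allow_gaps=True to accept flagged gaps"
            )
        bad = df.index[df["tmax"] < df["tmin"]]
        if len(bad):
            d = df.loc[bad[0], "date"].date()
            raise WeatherValidationError(f"tmax < tmin on {d} (row {bad[0]})")
        if (df["rain"] < 0).any():
            raise WeatherValidationError("negative rainfall present")
        self.data = df

    # -- convenience accessors ------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def tmean(self) -> pd.Series:
        return 0.5 * (self.data["tmax"] + self.data["tmin"])

    @property
    def start_date(self) -> dt.date:
        return self.data["date"].iloc[0].date()

    @property
    def end_date(self) -> dt.date:
        return self.data["date"].iloc[-1].date()

    def slice(self, start: dt.date, end: dt.date) -> "WeatherSeries":
        """Sub-series covering [start, end]; raises :class:`CoverageError`
        if any day in the window is absent."""
        start, end = _as_date(start), _as_date(end)
        mask = (self.data["date"] >= pd.Timestamp(start)) & (
            self.data["date"] <= pd.Timestamp(end)
        )
        sub = self.data.loc[mask]
        expected = day_count_inclusive(start, end)
        if len(sub) != expected:
            have = set(sub["date"].dt.date)
            missing = [
                d.date()
                for d in pd.date_range(start, end)
                if d.date() not in have
            ]
            raise CoverageError(
                f"window {start}..{end} not covered: missing "
                f"{missing[0]}..{missing[-1]} ({len(missing)} days)"
            )
        return WeatherSeries(
            sub.reset_index(drop=True),
            site_id=self.site_id,
            latitude=self.latitude,
            longitude=self.longitude,
        )

    def covers(self, start: dt.date, end: dt.date) -> bool:
        try:
            self.slice(start, end)
            return True
        except CoverageError:
            return False

    def with_offset(self, delta_t: float) -> "WeatherSeries":
        """Copy with *delta_t* added to both Tmax and Tmin (rain untouched)."""
        df = self.data.copy()
        df["tmax"] = df["tmax"] + delta_t
        df["tmin"] = df["tmin"] + delta_t
        return replace(self, data=df)

    def iter_records(self):
        for row in self.data.itertuples(index=False):
            yield DailyWeather(row.date.date(), row.tmax, row.tmin, row.rain)


def extract_season(
    series: WeatherSeries,
    harvest_year: int,
    window: SeasonWindow = WHEAT_SEASON,
) -> WeatherSeries:
    """Sub-series for one growing season.

    With the default window this runs 15 October of ``harvest_year - 1``
    through 30 April of ``harvest_year`` — 198 daily records when February is
    non-leap, 199 otherwise.
    """
    start, end = season_bounds(window, harvest_year)
    return series.slice(start, end)


def seasonal_table(
    series: WeatherSeries,
    window: SeasonWindow = WHEAT_SEASON,
    harvest_years: list[int] | None = None,
) -> pd.DataFrame:
    """Per-season climate summary across every fully covered season.

    Returns a DataFrame indexed by harvest year with columns ``tmean``,
    ``tmax``, ``tmin`` (seasonal means, °C), ``rain`` (seasonal total, mm) and
    ``n_days``.
    """
    if harvest_years is None:
        harvest_years = range(series.start_date.year, series.end_date.year + 1)
    rows = {}
    for year in harvest_years:
        try:
            sub = extract_season(series, year, window)
        except CoverageError:
            continue
        rows[year] = {
            "tmean": float(sub.tmean.mean()),
            "tmax": float(sub.data["tmax"].mean()),
            "tmin": float(sub.data["tmin"].mean()),
            "rain": float(sub.data["rain"].sum()),
            "n_days": len(sub),
        }
    if not rows:
        raise CoverageError("no fully covered season in series")
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "harvest_year"
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"date": "date", "tmax": "tmax", "tmin": "tmin", "rain": "rain"}


def read_weather_table(
    path,
    columns: dict[str, str] | None = None,
    date_format: str | None = None,
    dayfirst: bool = False,
    strict: bool = True,
    site_id: str = "",
    latitude: float | None = None,
    longitude: float | None = None,
    sep: str = ",",
) -> WeatherSeries:
    """Read a delimited daily-weather table.

    ``columns`` maps the roles ``date``/``tmax``/``tmin``/``rain`` to the
    header names actually present.  Rows violating ``tmax >= tmin`` raise (in
    strict mode, naming the offending file line) or are dropped with gaps
    allowed otherwise.
    """
    colmap = dict(_DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep=sep)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise WeatherValidationError(
            f"{path}: missing column(s) {missing}; found {list(raw.columns)}"
        )
    df = pd.DataFrame({role: raw[name] for role, name in colmap.items()})
    try:
        df["date"] = pd.to_datetime(df["date"], format=date_format, dayfirst=dayfirst)
    except (ValueError, TypeError) as exc:
        raise WeatherValidationError(f"{path}: unparseable date ({exc})") from exc
    bad = df.index[df["tmax"] < df["tmin"]]
    if len(bad):
        line = int(bad[0]) + 2  # header is line 1
        if strict:
            raise WeatherValidationError(
                f"{path}: tmax < tmin on line {line} "
                f"(date {pd.Timestamp(df.loc[bad[0], 'date']).date()})"
            )
        df = df.drop(index=bad)
    return WeatherSeries(
        df,
        site_id=site_id,
        latitude=latitude,
        longitude=longitude,
        allow_gaps=not strict,
    )


def write_weather_table(series: WeatherSeries, path, float_format: str = "%.2f") -> None:
    """Write the series as CSV (ISO dates); round-trips with
    :func:`read_weather_table` at the written precision."""
    df = series.data.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format=float_format)


#: Placeholder daily solar radiation (MJ m⁻² d⁻¹) used when the series carries
#: no radiation observations; a mid-range winter value for ~33° N.
SRAD_PLACEHOLDER = 15.0


def write_wth(series: WeatherSeries, path, srad: float = SRAD_PLACEHOLDER) -> None:
    """Write a DSSAT-style fixed-width daily weather (.WTH) file.

    Columns DATE (YYDDD), SRAD, TMAX, TMIN, RAIN; the station header carries
    latitude/longitude plus the long-term mean temperature (TAV) and half the
    annual monthly-mean temperature range (AMP).  SRAD is filled with a
    documented placeholder since the series carries no radiation.
    """
    if len(series) == 0:
        raise WeatherValidationError("cannot write empty series")
    if series.latitude is None or series.longitude is None:
        raise WeatherValidationError("site latitude/longitude required for .WTH output")
    insi = (series.site_id or "SITE")[:4].upper().ljust(4)
    tmean = series.tmean
    tav = float(tmean.mean())
    monthly = tmean.groupby(series.data["date"].dt.month).mean()
    amp = float(monthly.max() - monthly.min()) / 2.0 if len(monthly) > 1 else -99.0
    lines = [
        f"*WEATHER DATA : {series.site_id or 'unnamed site'}",
        "",
        "@ INSI      LAT     LONG  ELEV   TAV   AMP REFHT WNDHT",
        f"  {insi} {series.latitude:8.3f} {series.longitude:8.3f}   -99 {tav:5.1f} {amp:5.1f}   -99   -99",
        "@DATE  SRAD  TMAX  TMIN  RAIN",
    ]
    for row in series.data.itertuples(index=False):
        d = row.date
        lines.append(
            f"{d.year % 100:02d}{d.dayofyear:03d} {srad:5.1f} "
            f"{row.tmax:5.1f} {row.tmin:5.1f} {row.rain:5.1f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_wth(path, century_pivot: int = 50, **meta) -> WeatherSeries:
    """Read a .WTH file written by :func:`write_wth`.

    DSSAT's YYDDD dates are century-ambiguous; two-digit years >= *century_pivot*
    are mapped to 1900s, the rest to 2000s.
    """
    records = []
    lat = lon = None
    site_id = meta.pop("site_id", "")
    with open(path) as fh:
        lines = fh.read().splitlines()
    in_data = False
    header_next = False
    for line in lines:
        if line.startswith("*WEATHER DATA"):
            site_id = site_id or line.split(":", 1)[-1].strip()
            continue
        if line.startswith("@ INSI"):
            header_next = True
            continue
        if header_next:
            parts = line.split()
            lat, lon = float(parts[1]), float(parts[2])
            header_next = False
            continue
        if line.startswith("@DATE"):
            in_data = True
            continue
        if in_data and line.strip():
            parts = line.split()
            yyddd = parts[0]
            yy, doy = int(yyddd[:2]), int(yyddd[2:])
            year = 1900 + yy if yy >= century_pivot else 2000 + yy
            date = dt.date(year, 1, 1) + dt.timedelta(days=doy - 1)
            records.append(
                {"date": date, "tmax": float(parts[2]), "tmin": float(parts[3]),
                 "rain": float(parts[4])}
            )
    if not records:
        raise WeatherValidationError(f"{path}: no data rows")
    return WeatherSeries(pd.DataFrame(records), site_id=site_id,
                         latitude=lat, longitude=lon, **meta)
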