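"""Calendar arithmetic, series validation, season extraction, and file I/O."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheatclim.weather import (
    CoverageError,
    SeasonWindow,
    WeatherSeries,
    WeatherValidationError,
    add_days_inclusive,
    day_count_inclusive,
    extract_season,
    read_weather_table,
    read_wth,
    seasonal_table,
    write_weather_table,
    write_wth,
)

from conftest import build_series


class TestDayArithmetic:
    @pytest.mark.parametrize(
        "start, end, expected",
        [
            # sowing-to-anthesis intervals of the canonical scenario table
            (dt.date(2001, 10, 15), dt.date(2002, 1, 27), 105),
            (dt.date(2001, 10, 15), dt.date(2002, 1, 22), 100),
            (dt.date(2001, 11, 24), dt.date(2002, 3, 3), 100),
            (dt.date(2001, 11, 4), dt.date(2002, 2, 11), 100),
            (dt.date(2001, 6, 1), dt.date(2001, 6, 1), 1),  # same-day = day 1
            (dt.date(2019, 12, 31), dt.date(2020, 3, 1), 62),  # leap February
        ],
    )
    def test_inclusive_count(self, start, end, expected):
        assert day_count_inclusive(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError, match="reversed"):
            day_count_inclusive(dt.date(2001, 2, 1), dt.date(2001, 1, 1))

    @pytest.mark.parametrize(
        "start, n, expected",
        [
            (dt.date(2001, 10, 15), 100, dt.date(2002, 1, 22)),
            (dt.date(2001, 11, 4), 100, dt.date(2002, 2, 11)),
            (dt.date(2001, 3, 7), 1, dt.date(2001, 3, 7)),
        ],
    )
    def test_add_days(self, start, n, expected):
        assert add_days_inclusive(start, n) == expected

    def test_day_zero_rejected(self):
        with pytest.raises(ValueError):
            add_days_inclusive(dt.date(2001, 1, 1), 0)

    @given(
        start=st.dates(dt.date(1950, 1, 1), dt.date(2050, 1, 1)),
        n=st.integers(1, 1000),
    )
    @settings(max_examples=200, deadline=None)
    def test_count_inverts_add(self, start, n):
        assert day_count_inclusive(start, add_days_inclusive(start, n)) == n


class TestSeriesValidation:
    def test_tmax_below_tmin_rejected(self):
        df = pd.DataFrame(
            {"date": pd.date_range("2001-01-01", periods=2),
             "tmax": [10.0, 5.0], "tmin": [5.0, 8.0], "rain": [0.0, 0.0]}
        )
        with pytest.raises(WeatherValidationError, match="tmax < tmin"):
            WeatherSeries(df)

    def test_gap_rejected_unless_allowed(self):
        df = pd.DataFrame(
            {"date": [pd.Timestamp("2001-01-01"), pd.Timestamp("2001-01-03")],
             "tmax": [10.0, 10.0], "tmin": [5.0, 5.0], "rain": [0.0, 0.0]}
        )
        with pytest.raises(WeatherValidationError, match="gap"):
            WeatherSeries(df)
        assert len(WeatherSeries(df, allow_gaps=True)) == 2

    def test_duplicate_dates_rejected(self):
        df = pd.DataFrame(
            {"date": [pd.Timestamp("2001-01-01")] * 2,
             "tmax": [10.0, 10.0], "tmin": [5.0, 5.0], "rain": [0.0, 0.0]}
        )
        with pytest.raises(WeatherValidationError):
            WeatherSeries(df)


class TestExtractSeason:
    def test_default_window_nonleap_is_198_days(self, make_series):
        series = make_series(dt.date(2000, 10, 1), 250)
        season = extract_season(series, 2001)
        assert len(season) == 198
        assert season.start_date == dt.date(2000, 10, 15)
        assert season.end_date == dt.date(2001, 4, 30)

    def test_leap_february_gives_199(self, make_series):
        series = make_series(dt.date(2019, 10, 1), 250)
        assert len(extract_season(series, 2020)) == 199

    def test_length_matches_day_count(self, make_series):
        series = make_series(dt.date(2000, 10, 1), 250)
        season = extract_season(series, 2001)
        assert len(season) == day_count_inclusive(season.start_date, season.end_date)

    def test_within_year_window(self, make_series):
        series = make_series(dt.date(2001, 1, 1), 60)
        window = SeasonWindow((1, 1), (1, 31), "january")
        assert len(extract_season(series, 2001, window)) == 31

    def test_uncovered_window_errors_with_span(self, make_series):
        series = make_series(dt.date(2000, 11, 1), 250)
        with pytest.raises(CoverageError, match="missing 2000-10-15"):
            extract_season(series, 2001)

    def test_seasonal_table_skips_partial_seasons(self, make_series):
        series = make_series(dt.date(2000, 10, 1), 400, tmax=20, tmin=10, rain=1.0)
        tab = seasonal_table(series)
        assert list(tab.index) == [2001]
        assert tab.loc[2001, "tmean"] == pytest.approx(15.0)
        assert tab.loc[2001, "rain"] == pytest.approx(198.0)


class TestFileIO:
    def test_csv_round_trip(self, tmp_path, rng):
        n = 40
        tmin = rng.normal(8, 3, n)
        series = build_series(
            dt.date(2001, 3, 1), n,
            tmax=tmin + rng.uniform(1, 12, n), tmin=tmin,
            rain=rng.gamma(0.5, 8, n),
        )
        path = tmp_path / "w.csv"
        write_weather_table(series, path)
        back = read_weather_table(path)
        for col in ("tmax", "tmin", "rain"):
            np.testing.assert_allclose(
                back.data[col], series.data[col], atol=0.005 + 1e-12
            )
        assert (back.dates == series.dates).all()

    def test_three_line_file(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "date,tmax,tmin,rain\n"
            "2001-01-01,10,2,0\n2001-01-02,11,3,5\n2001-01-03,12,4,0\n"
        )
        assert len(read_weather_table(path)) == 3

    def test_strict_mode_names_bad_line(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text(
            "date,tmax,tmin,rain\n2001-01-01,10,2,0\n2001-01-02,1,3,0\n"
        )
        with pytest.raises(WeatherValidationError, match="line 3"):
            read_weather_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("date,tmax,tmin\n2001-01-01,10,2\n")
        with pytest.raises(WeatherValidationError, match="rain"):
            read_weather_table(path)

    def test_custom_column_map_and_dayfirst(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("DAY,TX,TN,PP\n15-10-2001,25,12,0\n16-10-2001,26,13,2\n")
        s = read_weather_table(
            path, columns={"date": "DAY", "tmax": "TX", "tmin": "TN", "rain": "PP"},
            dayfirst=True,
        )
        assert s.start_date == dt.date(2001, 10, 15)

    def test_wth_round_trip_365_days(self, tmp_path, rng):
        n = 365
        tmin = rng.normal(10, 5, n)
        series = build_series(
            dt.date(2001, 1, 1), n,
            tmax=tmin + rng.uniform(2, 15, n), tmin=tmin,
            rain=rng.gamma(0.4, 10, n),
            site_id="isla", latitude=33.67, longitude=73.13,
        )
        path = tmp_path / "w.wth"
        write_wth(series, path)
        back = read_wth(path)
        assert len(back) == n
        assert (back.dates == series.dates).all()
        for col in ("tmax", "tmin", "rain"):
            np.testing.assert_allclose(back.data[col], series.data[col], atol=0.05001)
        assert back.latitude == pytest.approx(33.67)

    def test_wth_single_day(self, tmp_path):
        series = build_series(dt.date(2001, 6, 1), 1)
        path = tmp_path / "one.wth"
        write_wth(series, path)
        assert len(read_wth(path)) == 1

    def test_wth_requires_coordinates(self, tmp_path):
        series = build_series(dt.date(2001, 6, 1), 3, latitude=None, longitude=None)
        with pytest.raises(WeatherValidationError, match="latitude"):
            write_wth(series, tmp_path / "x.wth")
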