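"""Growing-degree-day engine: daily rule, seasonal accumulation, inversion."""

import datetime as dt

import numpy as np
import pytest

from wheatclim.gdd import (
    ANTHESIS_TO_GRAINFILL,
    GRAINFILL_TO_MATURITY,
    VEGETATIVE,
    CardinalTemps,
    NonAttainment,
    Phase,
    PhaseSchedule,
    daily_gdd,
    days_to_reach,
    default_schedule,
    season_gdd,
)

from conftest import build_series

VEG_ONLY = PhaseSchedule((Phase("vegetative", 1, VEGETATIVE),))


def brute_force_season_gdd(tmax, tmin, schedule):
    """Independent day-by-day re-computation of the accumulation rule."""
    total = 0.0
    for i, (hi, lo) in enumerate(zip(tmax, tmin)):
        day = i + 1
        cards = None
        for p in schedule.phases:
            if day >= p.start_day:
                cards = p.cardinals
        if hi > cards.t_ceil:
            continue
        tmean = (hi + lo) / 2.0
        tmean = min(max(tmean, cards.t_base), cards.t_opt)
        total += tmean - cards.t_base
    return total


class TestDailyGDD:
    @pytest.mark.parametrize(
        "tmax, tmin, cards, expected",
        [
            (20, 10, VEGETATIVE, 11.0),            # (20+10)/2 - 4
            (8, 0, VEGETATIVE, 0.0),               # Tmean at base
            (36, 30, GRAINFILL_TO_MATURITY, 0.0),  # above the 35.4 ceiling
            (30, 20, VEGETATIVE, 18.0),            # Tmean 25 clamped at opt 22
            (2, -4, VEGETATIVE, 0.0),              # below base clamps to zero
        ],
    )
    def test_clamp_rule(self, tmax, tmin, cards, expected):
        assert daily_gdd(tmax, tmin, cards) == pytest.approx(expected)

    def test_reversed_temps_rejected(self):
        with pytest.raises(ValueError):
            daily_gdd(5, 10, VEGETATIVE)

    def test_invalid_cardinals_rejected(self):
        with pytest.raises(ValueError, match="base < opt < ceil"):
            CardinalTemps(10, 8, 20)

    def test_trapezoid_declines_between_opt_and_ceiling(self):
        cards = CardinalTemps(4.0, 22.0, 32.7)
        # Tmean midway between opt and ceiling -> about half the plateau value
        tmean = (22.0 + 32.7) / 2
        got = daily_gdd(tmean + 2, tmean - 2, cards, response="trapezoid")
        assert got == pytest.approx(0.5 * (22.0 - 4.0))
        # plateau rule would give the full 18.0
        assert daily_gdd(tmean + 2, tmean - 2, cards) == pytest.approx(18.0)

    def test_bounded_by_opt_minus_base(self, rng):
        for _ in range(200):
            lo = rng.uniform(-10, 30)
            hi = lo + rng.uniform(0, 15)
            g = daily_gdd(hi, lo, VEGETATIVE)
            assert 0.0 <= g <= VEGETATIVE.t_opt - VEGETATIVE.t_base


class TestSeasonGDD:
    def test_constant_100_days(self, make_series):
        s = make_series(dt.date(2001, 1, 1), 120, tmax=20, tmin=10)
        res = season_gdd(s, dt.date(2001, 1, 1), VEG_ONLY, dt.date(2001, 4, 10))
        assert res.total_gdd == pytest.approx(100 * 11.0)
        assert res.n_ceiling_days == 0

    def test_all_days_above_ceiling_give_zero(self, make_series):
        s = make_series(dt.date(2001, 6, 1), 30, tmax=40, tmin=25)
        res = season_gdd(s, dt.date(2001, 6, 1), VEG_ONLY, dt.date(2001, 6, 30))
        assert res.total_gdd == 0.0
        assert res.n_ceiling_days == 30
        assert res.n_days_above_35 == 30

    def test_phase_boundary_hand_sum(self, make_series):
        # 10 vegetative days at (20,10) then 10 grain-fill days at (20,10):
        # 10*11 + 10*(15 - 9.2) = 168.0
        sched = PhaseSchedule(
            (Phase("vegetative", 1, VEGETATIVE),
             Phase("grainfill_to_maturity", 11, GRAINFILL_TO_MATURITY))
        )
        s = make_series(dt.date(2001, 1, 1), 20, tmax=20, tmin=10)
        res = season_gdd(s, dt.date(2001, 1, 1), sched, dt.date(2001, 1, 20))
        assert res.total_gdd == pytest.approx(168.0)

    def test_matches_brute_force_on_random_series(self, rng):
        """Oracle equivalence on 100 random 30-day series across a 3-phase
        schedule with adversarial temperatures straddling every cardinal."""
        sched = default_schedule(dta_days=12, flowering_duration=6)
        for _ in range(100):
            tmin = rng.uniform(-5, 30, 30)
            tmax = tmin + rng.uniform(0, 15, 30)
            s = build_series(dt.date(2001, 1, 1), 30, tmax=tmax, tmin=tmin)
            res = season_gdd(s, dt.date(2001, 1, 1), sched, dt.date(2001, 1, 30))
            assert res.total_gdd == pytest.approx(
                brute_force_season_gdd(tmax, tmin, sched), abs=1e-9
            )

    def test_cumulative_non_decreasing_and_total_is_last(self, rng):
        tmin = rng.uniform(0, 20, 30)
        s = build_series(dt.date(2001, 1, 1), 30, tmax=tmin + 8, tmin=tmin)
        res = season_gdd(s, dt.date(2001, 1, 1), VEG_ONLY, dt.date(2001, 1, 30))
        cum = res.cumulative_gdd
        assert (np.diff(cum) >= 0).all()
        assert res.total_gdd == pytest.approx(cum[-1])

    def test_warming_monotonicity_below_cardinals(self, make_series):
        """Raising Tmean (staying under opt and ceiling) never lowers the total."""
        cool = make_series(dt.date(2001, 1, 1), 30, tmax=18, tmin=8)
        warm = make_series(dt.date(2001, 1, 1), 30, tmax=20, tmin=10)
        args = (dt.date(2001, 1, 1), VEG_ONLY, dt.date(2001, 1, 30))
        assert season_gdd(warm, *args).total_gdd >= season_gdd(cool, *args).total_gdd

    def test_total_bounded_by_loosest_phase(self, rng):
        tmin = rng.uniform(-5, 35, 50)
        s = build_series(dt.date(2001, 1, 1), 50, tmax=tmin + rng.uniform(0, 12, 50),
                         tmin=tmin)
        sched = default_schedule(dta_days=20, flowering_duration=10)
        res = season_gdd(s, dt.date(2001, 1, 1), sched, dt.date(2001, 2, 19))
        loosest = max(p.cardinals.t_opt - p.cardinals.t_base for p in sched.phases)
        assert res.total_gdd <= 50 * loosest + 1e-12


class TestDaysToReach:
    def test_constant_rate_inversion(self, make_series):
        s = make_series(dt.date(2001, 1, 1), 30, tmax=20, tmin=10)  # 11 GDD/day
        assert days_to_reach(s, dt.date(2001, 1, 1), 110.0, VEG_ONLY) == 10

    def test_target_within_first_day(self, make_series):
        s = make_series(dt.date(2001, 1, 1), 5, tmax=20, tmin=10)
        assert days_to_reach(s, dt.date(2001, 1, 1), 5.0, VEG_ONLY) == 1

    def test_unreachable_target_signals_non_attainment(self, make_series):
        s = make_series(dt.date(2001, 1, 1), 10, tmax=20, tmin=10)
        res = days_to_reach(s, dt.date(2001, 1, 1), 1e6, VEG_ONLY)
        assert isinstance(res, NonAttainment)
        assert res.achieved == pytest.approx(110.0)
        assert not res

    def test_nonpositive_target_rejected(self, make_series):
        s = make_series(dt.date(2001, 1, 1), 10)
        with pytest.raises(ValueError):
            days_to_reach(s, dt.date(2001, 1, 1), 0.0, VEG_ONLY)

    def test_warmer_series_reaches_target_no_later(self, make_series):
        """Thermal-time phenology: warming (below cardinals) shortens the
        days-to-anthesis, mirroring observed DTA decline."""
        cool = make_series(dt.date(2001, 1, 1), 60, tmax=16, tmin=6)
        warm = make_series(dt.date(2001, 1, 1), 60, tmax=19, tmin=9)
        d_cool = days_to_reach(cool, dt.date(2001, 1, 1), 300.0, VEG_ONLY)
        d_warm = days_to_reach(warm, dt.date(2001, 1, 1), 300.0, VEG_ONLY)
        assert d_warm <= d_cool


class TestScheduleValidation:
    def test_first_phase_must_start_day_one(self):
        with pytest.raises(ValueError, match="day 1"):
            PhaseSchedule((Phase("vegetative", 2, VEGETATIVE),))

    def test_phase_starts_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increase"):
            PhaseSchedule(
                (Phase("a", 1, VEGETATIVE), Phase("b", 1, ANTHESIS_TO_GRAINFILL))
            )

    def test_default_schedule_phase_layout(self):
        sched = default_schedule(dta_days=105, flowering_duration=10)
        starts = [p.start_day for p in sched.phases]
        assert starts == [1, 106, 116]
        assert sched.cardinals_for_day(105) == VEGETATIVE
        assert sched.cardinals_for_day(106) == ANTHESIS_TO_GRAINFILL
        assert sched.cardinals_for_day(116) == GRAINFILL_TO_MATURITY
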