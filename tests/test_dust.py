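"""Dust-day classification, gridding, and monthly frequency rules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gefa
from gefa.dust import (
    StationRecord,
    cell_index,
    classify_dust_day,
    classify_station_days,
    grid_regional_dust_day,
    map_raw_codes,
    monthly_dust_frequency,
    read_station_csv,
    write_station_csv,
)
from gefa._util import GEFAError


def _obs(hour_codes, day=dt.date(2000, 6, 1)):
    return [(dt.datetime.combine(day, dt.time(h)), c) for h, c in hour_codes]


class TestClassifyDustDay:
    def test_storm_at_night_forces_dust_day(self):
        obs = _obs([(2, "severe_dust_storm")])
        assert classify_dust_day(obs, lon=0.0) is True

    def test_quarter_rule_boundary_is_inclusive(self):
        # 12 daytime obs, exactly 3 suspensions: 3 >= 12/4 -> dusty
        codes = ["dust_suspension"] * 3 + ["none"] * 9
        obs = _obs([(6 + h, c) for h, c in enumerate(codes)])
        assert classify_dust_day(obs, lon=0.0) is True

    def test_below_quarter_not_flagged(self):
        codes = ["dust_suspension"] * 2 + ["none"] * 10
        obs = _obs([(6 + h, c) for h, c in enumerate(codes)])
        assert classify_dust_day(obs, lon=0.0) is False

    def test_one_of_eight_daytime_suspensions_not_flagged(self):
        codes = ["dust_suspension"] + ["none"] * 7
        obs = _obs([(6 + h, c) for h, c in enumerate(codes)])
        assert classify_dust_day(obs, lon=0.0) is False

    def test_night_only_record_without_storm_is_missing(self):
        obs = _obs([(1, "dust_suspension"), (3, "none")])
        assert classify_dust_day(obs, lon=0.0) is None

    def test_daytime_window_uses_local_solar_time(self):
        # 10:00 UTC at lon=-150 is 00:00 local solar -> not daytime
        obs = _obs([(10, "dust_suspension")])
        assert classify_dust_day(obs, lon=-150.0) is None
        assert classify_dust_day(obs, lon=0.0) is True

    def test_order_invariance(self):
        codes = [(6, "none"), (9, "dust_suspension"), (12, "none"), (15, "dust_suspension")]
        a = classify_dust_day(_obs(codes), lon=0.0)
        b = classify_dust_day(_obs(codes[::-1]), lon=0.0)
        assert a == b

    def test_empty_day_rejected(self):
        with pytest.raises(GEFAError, match="observation"):
            classify_dust_day([], lon=0.0)

    @given(n_susp=st.integers(0, 12), n_none=st.integers(0, 12))
    @settings(max_examples=60, deadline=None)
    def test_quarter_rule_matches_exact_rational_comparison(self, n_susp, n_none):
        total = n_susp + n_none
        if total == 0 or total > 12:
            return
        codes = ["dust_suspension"] * n_susp + ["none"] * n_none
        obs = _obs([(6 + h, c) for h, c in enumerate(codes)])
        assert classify_dust_day(obs, lon=0.0) is (4 * n_susp >= total)


class TestGridding:
    def _days(self, rows):
        return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "date", "dust_day"])

    def test_any_dusty_station_makes_cell_day_dusty(self):
        d = dt.date(2000, 1, 1)
        df = self._days([("a", 14.1, 0.1, d, True), ("b", 14.2, 0.15, d, False)])
        cells = grid_regional_dust_day(df)
        assert len(cells) == 1 and bool(cells["dust_day"].iloc[0]) is True

    def test_all_clear_stations_make_cell_day_clear(self):
        d = dt.date(2000, 1, 1)
        df = self._days([("a", 14.1, 0.1, d, False), ("b", 14.2, 0.15, d, False)])
        cells = grid_regional_dust_day(df)
        assert bool(cells["dust_day"].iloc[0]) is False

    def test_unobserved_cell_day_is_absent(self):
        d1, d2 = dt.date(2000, 1, 1), dt.date(2000, 1, 2)
        df = self._days([("a", 14.1, 0.1, d1, True), ("a", 14.1, 0.1, d2, np.nan)])
        cells = grid_regional_dust_day(df)
        assert cells["date"].tolist() == [d1]

    def test_half_open_cell_convention(self):
        assert cell_index(14.25, 0.25) == (14.25, 0.25)
        assert cell_index(14.2499, 0.2499) == (14.0, 0.0)
        assert cell_index(-0.1, -0.1) == (-0.25, -0.25)

    def test_gridding_conserves_dusty_day_counts(self):
        d = dt.date(2000, 1, 1)
        rows = [(f"s{i}", 14.0 + 0.3 * i, 0.0, d, i % 2 == 0) for i in range(6)]
        df = self._days(rows)
        cells = grid_regional_dust_day(df)
        assert cells["dust_day"].sum() <= df["dust_day"].sum()


class TestMonthlyFrequency:
    def _flags(self, year, month, spec):
        return {dt.date(year, month, d): v for d, v in spec.items()}

    def test_sixteen_observed_of_thirty_yields_quarter(self):
        spec = {d: (d <= 4) for d in range(1, 17)}        # 4 dusty of 16 observed
        f = monthly_dust_frequency(self._flags(2001, 6, spec), 2001, 6)
        assert f == pytest.approx(0.25)

    def test_exactly_half_coverage_is_missing(self):
        spec = {d: False for d in range(1, 16)}           # 15 of 30: not > half
        assert monthly_dust_frequency(self._flags(2001, 6, spec), 2001, 6) is None

    def test_full_coverage_no_dust_is_zero(self):
        spec = {d: False for d in range(1, 32)}
        assert monthly_dust_frequency(self._flags(2001, 7, spec), 2001, 7) == 0.0

    def test_adding_a_dusty_day_never_decreases_frequency(self):
        spec = {d: (d <= 3) for d in range(1, 21)}
        base = monthly_dust_frequency(self._flags(2001, 6, spec), 2001, 6)
        spec[4] = True
        more = monthly_dust_frequency(self._flags(2001, 6, spec), 2001, 6)
        assert more >= base


class TestEndToEnd:
    def test_scripted_scenario_through_full_chain(self):
        scen = gefa.DustScenario(scripted={
            # station lons are -10 and -9.5, so local solar time lags UTC by
            # ~40 min; hours 7..14 UTC all fall inside the 06-18 daytime window
            (0, 0): [(12, "dust_storm")],                       # dusty day
            (0, 1): [(7 + h, "none") for h in range(8)],        # clear day
            (1, 0): [(7 + h, "dust_suspension" if h < 2 else "none") for h in range(8)],
        })
        stations = gefa.generate_station_weather(2, 2, scen, seed=0)
        days = classify_station_days(stations)
        flags = {(r.station_id, r.date.day): r.dust_day for r in days.itertuples()}
        assert flags[("ST000", 1)] is True
        assert flags[("ST000", 2)] is False
        assert flags[("ST001", 1)] is True                      # 2 of 8 = 1/4 boundary

    def test_station_csv_round_trip(self, tmp_path):
        stations = gefa.generate_station_weather(2, 2, seed=1)
        path = tmp_path / "stations.csv"
        write_station_csv(stations, path)
        back = read_station_csv(path)
        assert [s.station_id for s in back] == [s.station_id for s in stations]
        assert back[0].observations == stations[0].observations

    def test_wmo_code_mapping(self):
        assert map_raw_codes([6, 9, 33, 99, "dust_storm"]) == [
            "dust_suspension", "dust_storm", "severe_dust_storm", "none", "dust_storm"]

    def test_nonmonotonic_timestamps_rejected(self):
        t0 = dt.datetime(2000, 1, 1, 12)
        with pytest.raises(GEFAError, match="increasing"):
            StationRecord("x", 0, 0, [(t0, "none"), (t0, "none")])
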