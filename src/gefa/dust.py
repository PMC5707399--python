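"""Station dust-day metrics.

Hourly present-weather reports are reduced to a binary station dust day,
gridded to 0.25 deg cells, and aggregated to a monthly dust frequency:

* a station dust day occurs when any dust/sand storm or severe dust/sand
  storm code is reported during the day (any hour), or when dust suspension
  is reported in at least a quarter of the daytime observations;
* a grid cell has a regional dust day when at least one member station
  reports a dust day; a cell with no reporting station that day is missing;
* a cell-month gets a dust frequency only when observations cover more than
  half of the days of that month, otherwise it is left missing.

"Daytime" is not standardized for these archives; the default window is
06:00-18:00 local solar time, derived from the station longitude as
UTC + lon/15 hours, and is configurable everywhere it is used.
"""

from __future__ import annotations

import calendar
import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import GEFAError

#: canonical weather classes
DUST_CODES = ("none", "dust_suspension", "dust_storm", "severe_dust_storm", "other")
STORM_CODES = frozenset({"dust_storm", "severe_dust_storm"})

#: default mapping from WMO present-weather code numbers to canonical classes.
#: Editable: pass any raw->class mapping to `map_raw_codes`.
WMO_PRESENT_WEATHER_MAP: dict[int, str] = {
    6: "dust_suspension",   # widespread dust in suspension, not raised at station
    7: "dust_suspension",   # dust or sand raised by wind
    8: "dust_suspension",   # well-developed dust/sand whirls
    9: "dust_storm",        # dust/sand storm within sight or during preceding hour
    30: "dust_storm",
    31: "dust_storm",
    32: "dust_storm",
    33: "severe_dust_storm",
    34: "severe_dust_storm",
    35: "severe_dust_storm",
}

DEFAULT_DAYTIME_WINDOW = (6.0, 18.0)
CELL_SIZE = 0.25


@dataclass
class StationRecord:
    """Hourly present-weather observations for one station.

    Timestamps are UTC and must be strictly increasing; codes are canonical
    class names from `DUST_CODES`.
    """

    station_id: str
    lat: float
    lon: float
    observations: list[tuple[_dt.datetime, str]] = field(default_factory=list)

    def __post_init__(self):
        times = [t for t, _ in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise GEFAError(f"station {self.station_id}: timestamps must be strictly increasing")


def map_raw_codes(raw_codes: Iterable, mapping: Mapping | None = None) -> list[str]:
    """Translate raw present-weather codes to canonical classes.

    Codes absent from the mapping become "none" (no dust phenomenon).
    """
    mapping = WMO_PRESENT_WEATHER_MAP if mapping is None else mapping
    out = []
    for code in raw_codes:
        if code in DUST_CODES:
            out.append(code)
        else:
            out.append(mapping.get(code, "none"))
    return out


def local_solar_hour(timestamp: _dt.datetime, lon: float) -> float:
    """Local solar hour of a UTC timestamp at longitude lon (offset lon/15 h)."""
    utc_hour = timestamp.hour + timestamp.minute / 60.0 + timestamp.second / 3600.0
    return (utc_hour + lon / 15.0) % 24.0


def classify_dust_day(
    day_obs: Iterable[tuple[_dt.datetime, str]],
    lon: float = 0.0,
    daytime_window: tuple[float, float] = DEFAULT_DAYTIME_WINDOW,
) -> bool | None:
    """Classify one station-day of hourly observations as a dust day.

    True when any storm or severe-storm code appears (any hour of the day), or
    when dust-suspension reports make up at least a quarter of all daytime
    observations (exact rational comparison: 4 * n_suspension >= n_daytime).
    Returns None (missing) when there are no daytime observations and no storm
    code, since the suspension clause is then undefined.
    """
    start, end = daytime_window
    if not (0 <= start < end <= 24):
        raise GEFAError(f"empty or invalid daytime window {daytime_window!r}")
    obs = list(day_obs)
    if not obs:
        raise GEFAError("classify_dust_day needs at least one observation")
    if any(code in STORM_CODES for _, code in obs):
        return True
    daytime = [code for ts, code in obs if start <= local_solar_hour(ts, lon) < end]
    if not daytime:
        return None
    n_susp = sum(code == "dust_suspension" for code in daytime)
    return 4 * n_susp >= len(daytime)


def classify_station_days(
    stations: Iterable[StationRecord],
    daytime_window: tuple[float, float] = DEFAULT_DAYTIME_WINDOW,
) -> pd.DataFrame:
    """Classify every station-day in a station collection.

    Returns a DataFrame with columns station_id, lat, lon, date, dust_day
    (boolean, NaN where the day is missing).
    """
    rows = []
    for st in stations:
        by_day: dict[_dt.date, list] = {}
        for ts, code in st.observations:
            by_day.setdefault(ts.date(), []).append((ts, code))
        for day, obs in sorted(by_day.items()):
            flag = classify_dust_day(obs, lon=st.lon, daytime_window=daytime_window)
            rows.append((st.station_id, st.lat, st.lon, day, flag))
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "date", "dust_day"])


def cell_index(lat: float, lon: float) -> tuple[float, float]:
    """Lower-left corner of the half-open 0.25 deg cell containing a point.

    Cells are [lat0, lat0+0.25) x [lon0, lon0+0.25), anchored at integer
    degrees, so boundary stations belong to the cell whose corner they sit on.
    """
    return (np.floor(lat / CELL_SIZE) * CELL_SIZE, np.floor(lon / CELL_SIZE) * CELL_SIZE)


def grid_regional_dust_day(station_days: pd.DataFrame) -> pd.DataFrame:
    """Aggregate station dust days to per-cell daily regional dust days.

    A cell-day is True if at least one member station reports a dust day,
    False if all member station-days are present and False, and missing
    (absent row / NaN) when no station observed that day in the cell.
    """
    df = station_days.dropna(subset=["dust_day"]).copy()
    if df.empty:
        return pd.DataFrame(columns=["cell_lat", "cell_lon", "date", "dust_day"])
    cells = [cell_index(la, lo) for la, lo in zip(df["lat"], df["lon"])]
    df["cell_lat"] = [c[0] for c in cells]
    df["cell_lon"] = [c[1] for c in cells]
    out = (
        df.groupby(["cell_lat", "cell_lon", "date"])["dust_day"]
        .any()
        .reset_index()
    )
    return out


def monthly_dust_frequency(daily_flags: Mapping[_dt.date, bool | None], year: int, month: int) -> float | None:
    """Monthly dust frequency for one cell, or None when coverage is too low.

    Frequency = dusty days / observed days, defined only when observed days
    exceed half the calendar days of the month (strict inequality).
    """
    n_days = calendar.monthrange(year, month)[1]
    observed = [
        bool(v)
        for d, v in daily_flags.items()
        if d.year == year and d.month == month and v is not None and not (isinstance(v, float) and np.isnan(v))
    ]
    if len(observed) <= n_days / 2:
        return None
    return sum(observed) / len(observed)


def monthly_frequency_grid(cell_days: pd.DataFrame) -> pd.DataFrame:
    """Monthly dust frequency for every (cell, year, month) with any coverage.

    Rows failing the >half-month coverage rule carry NaN frequency.
    """
    if cell_days.empty:
        return pd.DataFrame(columns=["cell_lat", "cell_lon", "year", "month", "frequency"])
    df = cell_days.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month
    rows = []
    for (clat, clon, yr, mo), grp in df.groupby(["cell_lat", "cell_lon", "year", "month"]):
        n_days = calendar.monthrange(int(yr), int(mo))[1]
        n_obs = len(grp)
        freq = grp["dust_day"].sum() / n_obs if n_obs > n_days / 2 else np.nan
        rows.append((clat, clon, int(yr), int(mo), freq))
    return pd.DataFrame(rows, columns=["cell_lat", "cell_lon", "year", "month", "frequency"])


def read_station_csv(path, mapping: Mapping | None = None) -> list[StationRecord]:
    """Read station observations from CSV.

    Expected columns: station_id, lat, lon, timestamp (ISO 8601 UTC),
    weather_code (canonical class or raw code translated via `mapping`).
    """
    df = pd.read_csv(path)
    records = []
    for sid, grp in df.groupby("station_id", sort=True):
        grp = grp.sort_values("timestamp")
        codes = map_raw_codes(grp["weather_code"].tolist(), mapping)
        obs = [
            (pd.Timestamp(ts).to_pydatetime().replace(tzinfo=None), code)
            for ts, code in zip(grp["timestamp"], codes)
        ]
        records.append(
            StationRecord(str(sid), float(grp["lat"].iloc[0]), float(grp["lon"].iloc[0]), obs)
        )
    return records


def write_station_csv(stations: Iterable[StationRecord], path) -> None:
    rows = [
        (st.station_id, st.lat, st.lon, ts.isoformat() + "Z", code)
        for st in stations
        for ts, code in st.observations
    ]
    pd.DataFrame(rows, columns=["station_id", "lat", "lon", "timestamp", "weather_code"]).to_csv(
        path, index=False
    )
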