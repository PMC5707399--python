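"""Station dust-day metrics: classification, gridding, monthly frequency.

Generates three months of hourly present-weather reports for four stations,
classifies station dust days (any storm code, or dust suspension in at least
a quarter of daytime observations), grids them to 0.25-degree cells, and
computes monthly dust frequencies where coverage exceeds half the month.
"""

import gefa
from gefa.dust import classify_station_days, grid_regional_dust_day, monthly_frequency_grid

scenario = gefa.DustScenario(
    code_probs={"none": 0.85, "dust_suspension": 0.10,
                "dust_storm": 0.04, "severe_dust_storm": 0.01},
    obs_hours=tuple(range(0, 24, 3)),
)
stations = gefa.generate_station_weather(4, 92, scenario, seed=2)

station_days = classify_station_days(stations)
n_dusty = int(station_days["dust_day"].sum())
print(f"{len(station_days)} station-days, {n_dusty} classified dusty")

cells = grid_regional_dust_day(station_days)
monthly = monthly_frequency_grid(cells)
print(monthly.to_string(index=False))
# frequency = dusty days / observed days per cell-month; rows would show NaN
# wherever fewer than half the month's days had any observation.
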