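"""Annotate the fleet with a synthetic reanalysis-style weather grid.

Builds an hourly 0.25-degree grid over the fleet's extent with a Bora-like
northeasterly flow (blowing toward the southwest), a zonal temperature
contrast between the warmer sea surface and cooler air, and attaches
bilinear wind / nearest-neighbour thermal fields to every fix.  Derived
columns: wind support (tailwind), |side wind| and delta-T.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from soarflight.io_formats import read_track
from soarflight.synthetic import make_weather_grid
from soarflight.weather import annotate, hourly_average

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    track = read_track(OUT / "tracks.csv", dialect="simple")
    t0 = track["timestamp"].min().floor("h")
    t1 = track["timestamp"].max().ceil("h")
    times = pd.date_range(t0, t1, freq="h")
    lats = np.arange(np.floor(track["lat"].min() * 4) / 4 - 0.5,
                     np.ceil(track["lat"].max() * 4) / 4 + 0.51, 0.25)
    lons = np.arange(np.floor(track["lon"].min() * 4) / 4 - 0.5,
                     np.ceil(track["lon"].max() * 4) / 4 + 0.51, 0.25)
    grid = make_weather_grid(
        times, lats, lons,
        u_fn=lambda t, lev, la, lo: np.full_like(la, -4.0),   # Bora: toward SW
        v_fn=lambda t, lev, la, lo: np.full_like(la, -3.0),
        t_air_fn=lambda t, lev, la, lo: 18.0 - 0.5 * (la - la.mean()),
        t_surface_fn=lambda t, la, lo: 19.1 - 0.5 * (la - la.mean()) + 0.2 * np.sin(t / 4),
    )
    annotated = annotate(track, grid)
    annotated.to_csv(OUT / "annotated.csv", index=False)
    hourly = hourly_average(annotated)
    hourly.to_csv(OUT / "hourly_weather.csv", index=False)
    print(f"annotated {len(annotated)} fixes; {len(hourly)} bird-hours")
    print(annotated[["tailwind", "sidewind", "delta_T"]].describe().round(2).to_string())


if __name__ == "__main__":
    main()
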