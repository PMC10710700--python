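"""Weather annotation: wind support, side wind, ΔT and grid interpolation.

Wind support (tailwind) is the component of the horizontal wind parallel to
the direction of travel, ``|w| * cos(alpha)`` where ``alpha`` is the angle
between the wind vector and the travel azimuth; negative values are headwind.
Side wind is the perpendicular component, reported as a magnitude.  ΔT is
surface temperature minus air temperature at flight level — a positive ΔT
(surface warmer than air) is the standard proxy for thermal uplift, negative
values indicate sinking air.

Convention note: u, v follow the meteorological reanalysis convention of the
wind vector the air *moves toward* (u eastward, v northward), so the compass
azimuth of the flow is ``atan2(u, v)``.  Getting this backwards is the
classic to/from sign bug; all code in this package goes through
:func:`wind_components` for the decomposition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import azimuth_deg

# International Standard Atmosphere constants
ISA_P0_HPA = 1013.25
ISA_T0_K = 288.15
ISA_LAPSE_K_PER_M = 0.0065
ISA_GAS_R = 8.3144598  # J / (mol K)
ISA_G = 9.80665  # m / s^2
ISA_MOLAR_MASS = 0.0289644  # kg / mol

__all__ = [
    "wind_components",
    "delta_T",
    "isa_altitude_m",
    "annotate",
    "hourly_average",
]


def wind_components(u, v, travel_azimuth_deg):
    """Decompose wind (u east, v north, m/s) along a travel azimuth.

    Returns ``(tailwind, sidewind)``: tailwind signed (negative = headwind),
    sidewind as a non-negative magnitude.  ``tailwind**2 + sidewind**2``
    equals the squared wind speed.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    flow_az = np.degrees(np.arctan2(u, v))  # compass azimuth the air moves toward
    alpha = np.radians(flow_az - np.asarray(travel_azimuth_deg, dtype=float))
    tailwind = speed * np.cos(alpha)
    sidewind = np.abs(speed * np.sin(alpha))
    return tailwind, sidewind


def delta_T(t_surface_c, t_air_c):
    """Surface minus air temperature, °C.  Positive = uplift-favourable."""
    return np.asarray(t_surface_c, dtype=float) - np.asarray(t_air_c, dtype=float)


def isa_altitude_m(pressure_hpa):
    """International Standard Atmosphere altitude for a pressure level.

    h = (T0/L) * (1 - (p/p0)^(R*L/(g*M))).  925 hPa sits near 760 m,
    the nominal flight level used for over-land annotation.
    """
    p = np.asarray(pressure_hpa, dtype=float)
    expo = ISA_GAS_R * ISA_LAPSE_K_PER_M / (ISA_G * ISA_MOLAR_MASS)
    return (ISA_T0_K / ISA_LAPSE_K_PER_M) * (1.0 - (p / ISA_P0_HPA) ** expo)


def _interp_level(da, level_hpa):
    if "level" in da.dims:
        return da.sel(level=level_hpa)
    return da


def _choose_levels(track, over_land=None, altitude_threshold_m=400.0, override=None):
    """Pressure-level rule: 925 hPa over land or for high-flying birds, else 1000.

    ``override`` maps bird_id -> level for individuals that need a manual
    choice (e.g. one bird crossing the sea unusually high).
    """
    levels = np.full(len(track), 1000.0)
    if over_land is not None:
        levels[np.asarray(over_land, dtype=bool)] = 925.0
    mean_alt = track.groupby("bird_id")["altitude_msl"].transform("mean")
    levels[(mean_alt > altitude_threshold_m).to_numpy()] = 925.0
    if override:
        for bird, lev in override.items():
            levels[(track["bird_id"] == bird).to_numpy()] = float(lev)
    return levels


def annotate(
    track,
    grid,
    travel_azimuth_deg=None,
    over_land=None,
    level_override=None,
    altitude_threshold_m=400.0,
):
    """Attach weather to each fix and derive tailwind, side wind and ΔT.

    Wind components are interpolated bilinearly in lon/lat and linearly
    between the two bracketing hours; temperature, cloud cover and
    precipitation use nearest-neighbour in space and time.  The pressure
    level per fix is 925 hPa over land / high flight and 1000 hPa otherwise,
    with a per-bird override.

    Parameters
    ----------
    track : DataFrame with canonical fix columns (see ``io_formats``).
    grid : WeatherGrid
    travel_azimuth_deg : scalar, per-fix array, or None.  None derives the
        azimuth from the track's first to last fix per bird (the route-level
        direction of travel used for crossing legs).
    over_land : optional boolean array (True where the fix is over land).

    Raises ``ValueError`` when a fix falls outside the grid in space or time.
    """
    import xarray as xr

    track = track.reset_index(drop=True)
    ds = grid.ds
    lon = xr.DataArray(track["lon"].to_numpy(), dims="fix")
    lat = xr.DataArray(track["lat"].to_numpy(), dims="fix")
    time = xr.DataArray(track["timestamp"].to_numpy().astype("datetime64[ns]"), dims="fix")

    _check_bounds(track, ds)

    levels = _choose_levels(track, over_land, altitude_threshold_m, level_override)

    out = track.copy()
    for name, col, how in (
        ("u_wind", "u", "linear"),
        ("v_wind", "v", "linear"),
        ("t_air", "t_air", "nearest"),
    ):
        vals = np.empty(len(track))
        for lev in np.unique(levels):
            sel = np.flatnonzero(levels == lev)
            da = ds[name]
            if "level" in da.dims:
                da = da.sel(level=lev, method="nearest")
            idx = dict(lon=lon.isel(fix=sel), lat=lat.isel(fix=sel), time=time.isel(fix=sel))
            if how == "linear":
                vals[sel] = da.interp(**idx, method="linear").to_numpy()
            else:
                vals[sel] = da.sel(**idx, method="nearest").to_numpy()
        out[col] = vals
    for name, col in (("t_surface", "t_surface"), ("cloud_cover", "cloud"), ("precipitation", "precip")):
        out[col] = ds[name].sel(lon=lon, lat=lat, time=time, method="nearest").to_numpy()

    if travel_azimuth_deg is None:
        travel_azimuth_deg = _route_azimuth(track)
    tail, side = wind_components(out["u"], out["v"], travel_azimuth_deg)
    out["tailwind"] = tail
    out["sidewind"] = side
    out["delta_T"] = delta_T(out["t_surface"], out["t_air"])
    out["pressure_level"] = levels
    return out


def _route_azimuth(track):
    """Per-fix azimuth of the bird's overall route (first fix -> last fix)."""
    az = np.empty(len(track))
    for _, idx in track.groupby("bird_id").indices.items():
        first, last = idx[0], idx[-1]
        az[idx] = azimuth_deg(
            track["lon"].iloc[first], track["lat"].iloc[first],
            track["lon"].iloc[last], track["lat"].iloc[last],
        )
    return az


def _check_bounds(track, ds):
    for axis, col in (("lon", "lon"), ("lat", "lat")):
        vals = track[col].to_numpy()
        lo, hi = float(ds[axis].min()), float(ds[axis].max())
        bad = (vals < lo) | (vals > hi)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} fixes outside the weather grid on {axis} "
                f"(first at row {int(np.argmax(bad))})"
            )
    t = track["timestamp"].to_numpy().astype("datetime64[ns]")
    tlo, thi = ds["time"].min().to_numpy(), ds["time"].max().to_numpy()
    bad = (t < tlo) | (t > thi)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} fixes outside the weather grid in time")


WEATHER_COLS = ("u", "v", "t_air", "t_surface", "cloud", "precip", "tailwind", "sidewind", "delta_T")


def hourly_average(annotated, weather_cols=WEATHER_COLS):
    """Collapse annotated fixes to one record per bird-hour.

    Weather variables are arithmetic means over the hour; position and
    timestamp come from the temporal-midpoint fix of the hour.
    """
    df = annotated.copy()
    df["_hour"] = df["timestamp"].dt.floor("h")
    rows = []
    for (bird, hour), g in df.groupby(["bird_id", "_hour"], sort=True):
        g = g.sort_values("timestamp")
        mid = g.iloc[len(g) // 2]
        rec = {
            "bird_id": bird,
            "hour": hour,
            "timestamp": mid["timestamp"],
            "lon": mid["lon"],
            "lat": mid["lat"],
            "n_fixes": len(g),
        }
        for c in weather_cols:
            if c in g.columns:
                rec[c] = g[c].mean()
        rows.append(rec)
    return pd.DataFrame(rows)
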