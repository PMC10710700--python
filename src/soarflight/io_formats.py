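"""Reading and writing tracks, weather grids, segment tables and land/sea masks.

The canonical in-memory track is a pandas DataFrame with columns

    bird_id, timestamp, lon, lat, altitude_msl, ground_speed[, acc_z, mag_x]

sorted by bird and time.  Coordinates are WGS84 decimal degrees, altitude is
metres above mean sea level, speed km/h, acc_z milli-g and mag_x milliGauss.
Two CSV dialects are accepted: the Movebank export dialect and this
"simple" canonical form.  Sensor columns are optional — classification will
refuse later with a clear error if they are absent, rather than guess.

Timestamps are parsed as UTC (naive).  Local-time windows used downstream
(e.g. the 06:00-13:00 departure window) apply a configurable UTC offset.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .geometry import haversine_m
from .types import FlightSegment

logger = logging.getLogger(__name__)


class TrackFormatError(ValueError):
    """A tracking file does not match the declared dialect."""


# Movebank export column -> canonical column
MOVEBANK_MAP = {
    "timestamp": "timestamp",
    "location-long": "lon",
    "location-lat": "lat",
    "height-above-msl": "altitude_msl",
    "ground-speed": "ground_speed",
    "acceleration-raw-z": "acc_z",
    "magnetic-field-raw-x": "mag_x",
}
MOVEBANK_ID_COLS = ("individual-local-identifier", "tag-local-identifier")
MOVEBANK_REQUIRED = ("timestamp", "location-long", "location-lat", "height-above-msl", "ground-speed")

SIMPLE_MAP = {
    "bird_id": "bird_id",
    "timestamp": "timestamp",
    "lon": "lon",
    "lat": "lat",
    "alt": "altitude_msl",
    "speed": "ground_speed",
    "acc_z": "acc_z",
    "mag_x": "mag_x",
}
SIMPLE_REQUIRED = ("bird_id", "timestamp", "lon", "lat", "alt", "speed")

CANONICAL_COLS = ["bird_id", "timestamp", "lon", "lat", "altitude_msl", "ground_speed"]


def read_track(path, dialect="movebank") -> pd.DataFrame:
    """Read a tracking CSV into the canonical per-bird, time-sorted frame.

    Rows with missing coordinates are dropped (count logged).  Unknown extra
    columns are carried through untouched.

    Raises
    ------
    TrackFormatError
        If a required column for the dialect is absent (the message names
        it), or a timestamp cannot be parsed (the message gives the file
        line number).
    """
    raw = pd.read_csv(path)
    if dialect == "movebank":
        colmap, required = dict(MOVEBANK_MAP), list(MOVEBANK_REQUIRED)
        id_col = next((c for c in MOVEBANK_ID_COLS if c in raw.columns), None)
        if id_col is None:
            raise TrackFormatError(
                f"missing required column: one of {MOVEBANK_ID_COLS}"
            )
        colmap[id_col] = "bird_id"
    elif dialect == "simple":
        colmap, required = dict(SIMPLE_MAP), list(SIMPLE_REQUIRED)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    for col in required:
        if col not in raw.columns:
            raise TrackFormatError(f"missing required column: {col!r}")

    df = raw.rename(columns={k: v for k, v in colmap.items() if k in raw.columns})

    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        line = int(np.argmax(bad.to_numpy())) + 2  # +1 header, +1 one-based
        raise TrackFormatError(
            f"unparseable timestamp {df['timestamp'][bad].iloc[0]!r} at line {line}"
        )
    df["timestamp"] = ts.dt.tz_localize(None)  # naive UTC

    n0 = len(df)
    df = df.dropna(subset=["lon", "lat"])
    if len(df) < n0:
        logger.warning("dropped %d rows with missing coordinates", n0 - len(df))

    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        v = df[col].astype(float)
        if ((v < lo) | (v > hi)).any():
            raise TrackFormatError(f"{col} outside [{lo}, {hi}]")

    df = df.sort_values(["bird_id", "timestamp"], kind="stable").reset_index(drop=True)
    ordered = CANONICAL_COLS + [c for c in df.columns if c not in CANONICAL_COLS]
    return df[ordered]


def write_track(track: pd.DataFrame, path, dialect="simple"):
    """Write a canonical track frame back to CSV (simple dialect)."""
    if dialect != "simple":
        raise ValueError("only the simple dialect is written")
    inv = {v: k for k, v in SIMPLE_MAP.items()}
    out = track.rename(columns=inv)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Weather grids
# ---------------------------------------------------------------------------

LEVEL_FIELDS = ("u_wind", "v_wind", "t_air")
SURFACE_FIELDS = ("t_surface", "cloud_cover", "precipitation")


@dataclass
class WeatherGrid:
    """Hourly rectilinear weather grid (0.25-degree reanalysis layout).

    ``ds`` is an xarray Dataset with coords ``time``, ``lat``, ``lon`` and
    optionally ``level`` (hPa); variables ``u_wind``, ``v_wind``, ``t_air``
    (per level, m/s and °C) and ``t_surface``, ``cloud_cover``,
    ``precipitation`` at the surface.
    """

    ds: "object"

    def validate(self):
        ds = self.ds
        for name in LEVEL_FIELDS + SURFACE_FIELDS:
            if name not in ds:
                raise TrackFormatError(f"weather grid missing field {name!r}")
        for axis in ("time", "lat", "lon"):
            if axis not in ds.coords:
                raise TrackFormatError(f"weather grid missing coordinate {axis!r}")
            if ds[axis].ndim != 1:
                raise TrackFormatError(f"weather grid axis {axis!r} is not rectilinear")
        # sort axes ascending, permuting fields consistently
        for axis in ("time", "lat", "lon"):
            vals = ds[axis].to_numpy()
            if not np.all(np.diff(vals.astype("float64") if vals.dtype.kind != "M" else vals.astype("int64")) >= 0):
                ds = ds.sortby(axis)
        cc = ds["cloud_cover"].to_numpy()
        if np.nanmin(cc) < 0 or np.nanmax(cc) > 1:
            raise ValueError("cloud_cover outside [0, 1]")
        for name in ("u_wind", "v_wind"):
            if not np.all(np.isfinite(ds[name].to_numpy())):
                raise ValueError(f"{name} contains non-finite values")
        self.ds = ds
        return self


def _kelvin_to_c(ds):
    for name in ("t_air", "t_surface"):
        if name in ds:
            units = str(ds[name].attrs.get("units", "")).lower()
            if units.startswith("k") or float(ds[name].max()) > 150.0:
                ds[name] = ds[name] - 273.15
                ds[name].attrs["units"] = "degC"
    return ds


def read_weather_grid(path) -> WeatherGrid:
    """Read a weather grid from NetCDF or long-format CSV.

    The CSV layout has one row per (time, level, lat, lon) cell with columns
    ``time, level, lat, lon, u_wind, v_wind, t_air, t_surface, cloud_cover,
    precipitation`` (``level`` optional).  Temperatures in Kelvin are
    converted to °C on read.
    """
    import xarray as xr

    p = str(path)
    if p.endswith(".nc"):
        ds = xr.open_dataset(p, engine="scipy").load()
    else:
        df = pd.read_csv(p, parse_dates=["time"])
        index = ["time"] + (["level"] if "level" in df.columns else []) + ["lat", "lon"]
        missing = [c for c in index + list(LEVEL_FIELDS + SURFACE_FIELDS) if c not in df.columns]
        if missing:
            raise TrackFormatError(f"weather CSV missing columns: {missing}")
        ds = df.set_index(index).to_xarray()
        for name in SURFACE_FIELDS:
            if "level" in ds[name].dims:
                ds[name] = ds[name].isel(level=0)
        for name in LEVEL_FIELDS + SURFACE_FIELDS:
            if ds[name].isnull().any():
                raise TrackFormatError(
                    f"weather CSV field {name!r} does not fill a rectilinear grid"
                )
    ds = _kelvin_to_c(ds)
    return WeatherGrid(ds).validate()


def write_weather_grid_csv(grid: WeatherGrid, path):
    """Long-format CSV dual of :func:`read_weather_grid`."""
    df = grid.ds.to_dataframe().reset_index()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

SEGMENT_COLS = [
    "segment_id", "bird_id", "timestamp", "lon", "lat", "altitude_msl",
    "behavior", "pattern", "climb_rate", "n_turns", "median_diameter_m",
]


def write_segments(segments, path, geojson_path=None):
    """Write labeled segments as a per-fix CSV (one row per fix).

    Optionally also emits a GeoJSON FeatureCollection with one LineString
    per segment, carrying the labels as properties.
    """
    rows = []
    for seg in segments:
        for _, fix in seg.fixes.iterrows():
            rows.append(
                {
                    "segment_id": seg.segment_id,
                    "bird_id": seg.bird_id,
                    "timestamp": fix["timestamp"],
                    "lon": fix["lon"],
                    "lat": fix["lat"],
                    "altitude_msl": fix["altitude_msl"],
                    "behavior": seg.behavior,
                    "pattern": seg.pattern,
                    "climb_rate": seg.climb_rate,
                    "n_turns": seg.n_turns,
                    "median_diameter_m": seg.median_diameter_m,
                }
            )
    pd.DataFrame(rows, columns=SEGMENT_COLS).to_csv(path, index=False)
    if geojson_path is not None:
        features = []
        for seg in segments:
            coords = [[round(x, 6), round(y, 6)] for x, y in zip(seg.fixes["lon"], seg.fixes["lat"])]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": coords},
                    "properties": {
                        "segment_id": seg.segment_id,
                        "bird_id": str(seg.bird_id),
                        "behavior": seg.behavior,
                        "pattern": seg.pattern,
                    },
                }
            )
        with open(geojson_path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_segments(path) -> pd.DataFrame:
    """Read the per-fix segment CSV written by :func:`write_segments`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in SEGMENT_COLS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"segment CSV missing columns: {missing}")
    return df


def segments_from_frame(df) -> list:
    """Rebuild FlightSegment objects from the per-fix segment table."""
    out = []
    for seg_id, g in df.groupby("segment_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        first = g.iloc[0]
        out.append(
            FlightSegment(
                segment_id=int(seg_id),
                bird_id=first["bird_id"],
                fixes=g[["timestamp", "lon", "lat", "altitude_msl"]].copy(),
                behavior=first["behavior"],
                pattern=first["pattern"],
                climb_rate=float(first["climb_rate"]),
                mean_altitude=float(g["altitude_msl"].mean()),
                n_turns=int(first["n_turns"]),
                median_diameter_m=float(first["median_diameter_m"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Land / sea mask
# ---------------------------------------------------------------------------


class LandSeaMask:
    """Land polygons in WGS84 with point-in-polygon and distance-to-shore.

    Distance to shore is the great-circle distance to the nearest point of
    the land boundary, evaluated against a densified boundary vertex set
    (default spacing 0.002 deg, ~200 m), which bounds the error well below
    the 10 km offshore threshold it supports.
    """

    def __init__(self, polygons, densify_deg=0.002):
        geom = unary_union([shapely.make_valid(p) for p in polygons])
        if geom.is_empty:
            raise ValueError("land/sea mask has no polygons")
        self.land = geom
        boundary = shapely.segmentize(geom.boundary, densify_deg)
        self._boundary_xy = shapely.get_coordinates(boundary)

    @classmethod
    def from_geojson(cls, path, **kw):
        with open(path) as fh:
            gj = json.load(fh)
        polys = []
        feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
        for f in feats:
            polys.append(shape(f["geometry"] if "geometry" in f else f))
        return cls(polys, **kw)

    def to_geojson(self, path):
        with open(path, "w") as fh:
            json.dump(
                {
                    "type": "FeatureCollection",
                    "features": [
                        {"type": "Feature", "geometry": mapping(self.land), "properties": {}}
                    ],
                },
                fh,
            )

    def is_land(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        return shapely.contains_xy(self.land, lon, lat)

    def distance_to_shore_m(self, lon, lat, chunk=512):
        """Great-circle distance (m) from each point to the nearest shoreline."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        bx = self._boundary_xy[:, 0]
        by = self._boundary_xy[:, 1]
        out = np.empty(lon.size)
        for i0 in range(0, lon.size, chunk):
            sl = slice(i0, min(i0 + chunk, lon.size))
            d = haversine_m(lon[sl, None], lat[sl, None], bx[None, :], by[None, :])
            out[sl] = d.min(axis=1)
        return out
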