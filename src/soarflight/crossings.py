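"""Sea-crossing detection and the resting-vs-departure decision dataset.

A crossing is the period between the first and the last fix over the water
body.  Route length is the sum of great-circle legs between consecutive
over-water fixes, mean speed is route length over duration.  Short
over-water excursions (coastal loops) are excluded with a configurable
minimum over-water run distance.

The departure dataset contrasts the mornings (06:00-13:00 local) that a
staging bird spent resting by the shore against the morning it actually set
out: resting-day hourly records are labeled 0, and crossing-day records —
from 06:00 until the bird first exceeded 10 km from the nearest shore — are
labeled 1.  Birds occasionally venture a few kilometres offshore without
departing, hence the 10 km threshold rather than the coastline itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import haversine_m
from .io_formats import LandSeaMask
from .types import CrossingEvent
from .weather import hourly_average

logger = logging.getLogger(__name__)

MIN_OVERWATER_KM = 20.0
OFFSHORE_KM = 10.0
LOCAL_UTC_OFFSET_H = 2  # CEST; the logger time basis is configurable
DEPARTURE_WINDOW_H = (6, 13)
MIN_REST_DAYS = 2

__all__ = ["detect_crossings", "build_departure_dataset"]


def detect_crossings(
    track: pd.DataFrame,
    mask: LandSeaMask,
    min_overwater_km: float = MIN_OVERWATER_KM,
) -> list[CrossingEvent]:
    """Find sea crossings: maximal over-water runs longer than a minimum length.

    Returns one CrossingEvent per qualifying run, per bird; an all-land
    track yields an empty list.
    """
    events = []
    for bird, g in track.groupby("bird_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        over_water = ~mask.is_land(g["lon"].to_numpy(), g["lat"].to_numpy())
        if not over_water.any():
            continue
        padded = np.concatenate([[False], over_water, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            run = g.iloc[s:e]
            if len(run) < 2:
                continue
            legs = haversine_m(
                run["lon"].to_numpy()[:-1], run["lat"].to_numpy()[:-1],
                run["lon"].to_numpy()[1:], run["lat"].to_numpy()[1:],
            )
            length_km = float(legs.sum()) / 1000.0
            if length_km < min_overwater_km:
                continue
            events.append(
                CrossingEvent(
                    bird_id=bird,
                    departure_time=run["timestamp"].iloc[0],
                    arrival_time=run["timestamp"].iloc[-1],
                    route_length_km=length_km,
                    n_fixes=len(run),
                )
            )
    return events


def build_departure_dataset(
    track: pd.DataFrame,
    mask: LandSeaMask,
    utc_offset_h: int = LOCAL_UTC_OFFSET_H,
    window_h=DEPARTURE_WINDOW_H,
    offshore_km: float = OFFSHORE_KM,
    min_rest_days: int = MIN_REST_DAYS,
    min_overwater_km: float = MIN_OVERWATER_KM,
    weather_cols=("tailwind", "sidewind", "cloud", "precip"),
) -> pd.DataFrame:
    """Hourly resting/departure records around each detected crossing.

    ``track`` must already carry weather covariate columns (an annotated
    track).  For every crossing preceded by at least ``min_rest_days`` days
    of coastal staging: staging-day fixes inside the local-morning window
    become hourly-averaged records with departed=0; crossing-day fixes from
    06:00 local until the bird first passed ``offshore_km`` from the nearest
    shore become records with departed=1.

    Returns a DataFrame (possibly empty, with a logged warning) of
    DepartureRecord rows: bird_id, date, hour, covariates, departed.
    """
    missing = [c for c in weather_cols if c not in track.columns]
    if missing:
        raise ValueError(f"track lacks weather columns {missing}; annotate it first")
    lo_h, hi_h = window_h
    records = []
    events = detect_crossings(track, mask, min_overwater_km)
    for event in events:
        g = track[track["bird_id"] == event.bird_id].sort_values("timestamp")
        local = g["timestamp"] + pd.Timedelta(hours=utc_offset_h)
        dep_date = (event.departure_time + pd.Timedelta(hours=utc_offset_h)).normalize()

        # staging days: consecutive calendar days with data right before departure
        pre = g[local.dt.normalize() < dep_date]
        rest_dates = sorted(set((pre["timestamp"] + pd.Timedelta(hours=utc_offset_h)).dt.normalize()))
        staging = []
        expect = dep_date - pd.Timedelta(days=1)
        for d in reversed(rest_dates):
            if d == expect:
                staging.append(d)
                expect -= pd.Timedelta(days=1)
            else:
                break
        if len(staging) < min_rest_days:
            continue

        def window_rows(date, departed, until=None):
            sel = g[(local.dt.normalize() == date) & (local.dt.hour >= lo_h) & (local.dt.hour <= hi_h)]
            if until is not None:
                sel = sel[sel["timestamp"] <= until]
            if sel.empty:
                return
            hourly = hourly_average(sel, weather_cols)
            for _, row in hourly.iterrows():
                rec = {
                    "bird_id": event.bird_id,
                    "date": date,
                    "hour": int((row["hour"] + pd.Timedelta(hours=utc_offset_h)).hour),
                    "departed": departed,
                }
                for c in weather_cols:
                    rec[c] = row[c]
                records.append(rec)

        for d in staging:
            window_rows(d, departed=0)

        # crossing day: records until the bird first exceeded the offshore threshold
        day = g[local.dt.normalize() == dep_date]
        dist = mask.distance_to_shore_m(day["lon"].to_numpy(), day["lat"].to_numpy())
        over = ~mask.is_land(day["lon"].to_numpy(), day["lat"].to_numpy())
        beyond = np.flatnonzero(over & (dist > offshore_km * 1000.0))
        cutoff = day["timestamp"].iloc[beyond[0]] if beyond.size else day["timestamp"].iloc[-1]
        window_rows(dep_date, departed=1, until=cutoff)

    if not records:
        logger.warning("no coastal staging found; departure dataset is empty")
        return pd.DataFrame(
            columns=["bird_id", "date", "hour", "departed", *weather_cols]
        )
    return pd.DataFrame(records)
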