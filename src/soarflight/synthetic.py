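"""Synthetic trajectories, sensor streams and decision datasets with known truth.

The generator emulates the duty-cycled biologger regime used on migrating
raptors: 5-minute bursts of 1 Hz GPS + accelerometer + magnetometer samples
separated by 10-15 minute pauses.  Each burst is simulated in one of five
flight modes with the sensor signatures that the classifier keys on:

* ``flapping``  — near-straight powered flight; the 1 Hz accelerometer
  z-channel shows high-variance samples (wingbeats aliased into noise).
* ``gliding``   — straight descending flight, smooth acc_z inside the
  800-1400 mG passive band, smooth magnetometer x-channel.
* ``spiral``    — tight circling (ground-track turn diameter < 10 m) with a
  wind-drifting centre, steady climb, sinusoidal mag_x at the turn period.
* ``staircase`` — wider circles (diameter > 10 m) alternating with straight
  runs, climbing while circling.
* ``s_shape``   — heading oscillation of amplitude < 180 deg with net climb
  and no cumulative full turn.

The generator works in kinematic space (local tangent plane, back-projected
to lon/lat); the classifier works in sensor space, so ground-truth labels
and classifier features stay decoupled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from .geometry import EARTH_RADIUS_M, xy_to_lonlat, haversine_m
from .io_formats import LandSeaMask

MODES = ("flapping", "gliding", "spiral", "staircase", "s_shape")

#: mode -> (behavior, pattern) ground-truth labels
MODE_LABELS = {
    "flapping": ("flapping", "none"),
    "gliding": ("gliding", "none"),
    "spiral": ("soaring", "spiral"),
    "staircase": ("soaring", "staircase"),
    "s_shape": ("soaring", "s_shape"),
}

# Table-2-style standardized logistic coefficients for soaring over sea:
# (intercept, wind support, |side wind|, delta-T, wind support x delta-T)
DEFAULT_SOARING_LOGIT = (0.01, 1.51, 1.65, 1.97, 1.65)
#: standardized wind-support effect on the decision to depart over the sea
DEFAULT_DEPARTURE_BETA = 0.99


@dataclass
class SimConfig:
    """Study conditions for the synthetic fleet.

    Defaults mirror the tracked-kite regime: 4 sensor birds, 300 s bursts at
    1 Hz with 10-15 min gaps, metre-level GPS noise, passive acc_z around
    1100 mG, and magnetometer amplitude ±400 mGauss.  Airspeeds (soaring
    8-12, gliding 12-18, flapping 10-14 m/s) are free parameters plausible
    for a ~950 g kite.
    """

    seed: int = 0
    n_birds: int = 4
    n_bursts_per_bird: int = 10
    burst_s: int = 300
    gap_min: tuple = (10.0, 15.0)
    # winds (m/s); per-burst winds are base + N(0, wind_sigma)
    wind_u: float = 0.0
    wind_v: float = 0.0
    wind_sigma: float = 0.0
    # per-burst delta-T draw (deg C): sea-crossing soaring conditions
    delta_T_mean: float = 1.1
    delta_T_sigma: float = 0.5
    pattern_mix: dict = field(
        default_factory=lambda: {
            "flapping": 0.3, "gliding": 0.2, "spiral": 0.25, "staircase": 0.15, "s_shape": 0.1,
        }
    )
    # standardized-scale logistic coefficients for P(soaring)
    soaring_logit: tuple = DEFAULT_SOARING_LOGIT
    re_sd: float = 0.5  # per-bird random-intercept SD on the logit scale
    # sensor noise
    gps_sigma_m: float = 1.0
    alt_sigma_m: float = 1.0
    acc_sigma_mg: float = 30.0
    mag_sigma_mgauss: float = 20.0
    # flight-mode kinematics
    airspeed: dict = field(
        default_factory=lambda: {"soaring": (8.0, 12.0), "gliding": (12.0, 18.0), "flapping": (10.0, 14.0)}
    )
    spiral_radius_m: tuple = (2.5, 4.0)
    spiral_period_s: tuple = (5.0, 8.0)
    staircase_radius_m: tuple = (8.0, 18.0)
    s_shape_amp_deg: tuple = (50.0, 80.0)
    s_shape_period_s: tuple = (15.0, 25.0)
    climb_ms: tuple = (0.3, 1.5)
    glide_sink_ms: tuple = (0.8, 1.3)
    acc_passive_mean_mg: float = 1100.0
    acc_flap_sd_mg: float = 300.0
    mag_amp_mgauss: float = 400.0
    # fleet geography
    lon0: float = 15.0
    lat0: float = 44.0
    start_time: str = "2020-10-01T06:00:00"

    def validate(self):
        total = sum(self.pattern_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"pattern_mix probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.pattern_mix.values()):
            raise ValueError("pattern_mix probabilities must be non-negative")
        if self.burst_s < 11:
            raise ValueError("burst_s must be at least 11 (a classifiable burst)")
        for name in ("gps_sigma_m", "alt_sigma_m", "acc_sigma_mg", "mag_sigma_mgauss", "wind_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("gap_min", "soaring_logit", "spiral_radius_m", "spiral_period_s",
                    "staircase_radius_m", "s_shape_amp_deg", "s_shape_period_s",
                    "climb_ms", "glide_sink_ms"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "airspeed" in data:
            data["airspeed"] = {k: tuple(v) for k, v in data["airspeed"].items()}
        return cls(**data).validate()

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class LabeledTrack:
    """A simulated track plus its per-fix ground truth and the config used."""

    track: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _heading_from_xy(x, y):
    """Ground-track compass heading per fix (deg), from consecutive positions."""
    dx = np.diff(x)
    dy = np.diff(y)
    h = np.degrees(np.arctan2(dx, dy)) % 360.0
    return np.concatenate([h[:1], h])


def _mag_x(heading_deg, rng, cfg):
    phase = rng.uniform(0, 2 * np.pi)
    return cfg.mag_amp_mgauss * np.cos(np.radians(heading_deg) + phase) + rng.normal(
        0, cfg.mag_sigma_mgauss, heading_deg.size
    )


def _passive_acc(n, rng, cfg):
    return cfg.acc_passive_mean_mg + rng.normal(0, cfg.acc_sigma_mg, n)


def _gen_burst(mode, n, rng, wind, cfg):
    """Simulate one burst; returns x, y (m), altitude (m), acc_z, mag_x."""
    t = np.arange(n, dtype=float)
    wu, wv = wind

    if mode == "flapping":
        h = rng.uniform(0, 360) + np.cumsum(rng.normal(0, 2.0, n))
        v = rng.uniform(*cfg.airspeed["flapping"])
        vx = v * np.sin(np.radians(h)) + wu
        vy = v * np.cos(np.radians(h)) + wv
        x = np.concatenate([[0.0], np.cumsum(vx)[:-1]])
        y = np.concatenate([[0.0], np.cumsum(vy)[:-1]])
        alt = rng.uniform(50, 300) + rng.normal(0, 0.5, n)
        acc = cfg.acc_passive_mean_mg + rng.normal(0, cfg.acc_flap_sd_mg, n)

    elif mode == "gliding":
        h = rng.uniform(0, 360) + np.cumsum(rng.normal(0, 0.3, n))
        v = rng.uniform(*cfg.airspeed["gliding"])
        vx = v * np.sin(np.radians(h)) + wu
        vy = v * np.cos(np.radians(h)) + wv
        x = np.concatenate([[0.0], np.cumsum(vx)[:-1]])
        y = np.concatenate([[0.0], np.cumsum(vy)[:-1]])
        sink = rng.uniform(*cfg.glide_sink_ms)
        alt = rng.uniform(400, 900) - sink * t
        acc = _passive_acc(n, rng, cfg)

    elif mode == "spiral":
        r = rng.uniform(*cfg.spiral_radius_m)
        period = rng.uniform(*cfg.spiral_period_s)
        sgn = rng.choice([-1.0, 1.0])
        omega = sgn * 2 * np.pi / period
        phi0 = rng.uniform(0, 2 * np.pi)
        vc = 2 * np.pi * r / period  # circling ground speed
        drift = np.array([wu, wv])
        dn = np.hypot(*drift)
        if dn > 0.2 * vc:  # keep the ground-track loops closed
            drift = drift * (0.2 * vc / dn)
        x = drift[0] * t + r * np.sin(phi0 + omega * t)
        y = drift[1] * t + r * np.cos(phi0 + omega * t)
        climb = rng.uniform(*cfg.climb_ms)
        alt = rng.uniform(50, 300) + climb * t
        acc = _passive_acc(n, rng, cfg)

    elif mode == "staircase":
        r = rng.uniform(*cfg.staircase_radius_m)
        v = rng.uniform(*cfg.airspeed["soaring"])
        period = 2 * np.pi * r / v
        base = rng.uniform(0, 360)
        sgn = rng.choice([-1.0, 1.0])
        h = np.empty(n)
        climb_mask = np.zeros(n, dtype=bool)
        i = 0
        heading = base
        while i < n:
            n_circ = min(n - i, int(round(period * rng.integers(2, 4))))
            h[i : i + n_circ] = heading + sgn * (360.0 / period) * np.arange(n_circ)
            climb_mask[i : i + n_circ] = True
            heading = base  # exit the circle on the migration heading
            i += n_circ
            n_run = min(n - i, int(rng.uniform(8, 15)))
            h[i : i + n_run] = heading + rng.normal(0, 1.0, n_run)
            i += n_run
        drift = np.array([wu, wv])
        dn = np.hypot(*drift)
        if dn > 0.6 * v:
            drift = drift * (0.6 * v / dn)
        vx = v * np.sin(np.radians(h)) + drift[0]
        vy = v * np.cos(np.radians(h)) + drift[1]
        x = np.concatenate([[0.0], np.cumsum(vx)[:-1]])
        y = np.concatenate([[0.0], np.cumsum(vy)[:-1]])
        climb = rng.uniform(*cfg.climb_ms)
        dalt = np.where(climb_mask, climb, -0.3)
        alt = rng.uniform(50, 300) + np.concatenate([[0.0], np.cumsum(dalt)[:-1]])
        acc = _passive_acc(n, rng, cfg)

    elif mode == "s_shape":
        base = rng.uniform(0, 360)
        amp = rng.uniform(*cfg.s_shape_amp_deg)
        period = rng.uniform(*cfg.s_shape_period_s)
        v = rng.uniform(*cfg.airspeed["soaring"])
        h = base + amp * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        drift = np.array([wu, wv])
        dn = np.hypot(*drift)
        if dn > 0.5 * v:  # keep the ground heading oscillatory, not rotary
            drift = drift * (0.5 * v / dn)
        vx = v * np.sin(np.radians(h)) + drift[0]
        vy = v * np.cos(np.radians(h)) + drift[1]
        x = np.concatenate([[0.0], np.cumsum(vx)[:-1]])
        y = np.concatenate([[0.0], np.cumsum(vy)[:-1]])
        climb = rng.uniform(cfg.climb_ms[0], min(1.0, cfg.climb_ms[1]))
        alt = rng.uniform(50, 300) + climb * t
        acc = _passive_acc(n, rng, cfg)

    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode!r}")

    # magnetometer follows the true body heading (pre-noise kinematics);
    # GPS noise is then added to the reported positions only
    mag = _mag_x(_heading_from_xy(x, y), rng, cfg)
    x = x + rng.normal(0, cfg.gps_sigma_m, n)
    y = y + rng.normal(0, cfg.gps_sigma_m, n)
    alt = alt + rng.normal(0, cfg.alt_sigma_m, n)
    return x, y, alt, acc, mag


def simulate_flight(config: SimConfig) -> LabeledTrack:
    """Simulate the duty-cycled fleet; returns the track with per-fix truth.

    Deterministic in ``config.seed``: identical seeds give bit-identical
    labels and coordinates.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    modes = list(cfg.pattern_mix.keys())
    probs = np.array([cfg.pattern_mix[m] for m in modes], dtype=float)
    probs = probs / probs.sum()

    rows = []
    truth_rows = []
    burst_id = 0
    t0 = pd.Timestamp(cfg.start_time)
    for b in range(cfg.n_birds):
        bird = f"bird_{b:02d}"
        cur_time = t0 + pd.Timedelta(hours=float(b))
        cur_lon, cur_lat = cfg.lon0 + 0.05 * b, cfg.lat0
        for _ in range(cfg.n_bursts_per_bird):
            mode = modes[rng.choice(len(modes), p=probs)]
            wind = (
                cfg.wind_u + rng.normal(0, cfg.wind_sigma) if cfg.wind_sigma else cfg.wind_u,
                cfg.wind_v + rng.normal(0, cfg.wind_sigma) if cfg.wind_sigma else cfg.wind_v,
            )
            n = cfg.burst_s
            x, y, alt, acc, mag = _gen_burst(mode, n, rng, wind, cfg)
            lon, lat = xy_to_lonlat(x, y, cur_lon, cur_lat)
            times = cur_time + pd.to_timedelta(np.arange(n), unit="s")
            speed_kmh = np.hypot(np.diff(x), np.diff(y)) * 3.6
            speed_kmh = np.concatenate([speed_kmh[:1], speed_kmh])
            behavior, pattern = MODE_LABELS[mode]
            rows.append(
                pd.DataFrame(
                    {
                        "bird_id": bird,
                        "timestamp": times,
                        "lon": lon,
                        "lat": lat,
                        "altitude_msl": alt,
                        "ground_speed": speed_kmh,
                        "acc_z": acc,
                        "mag_x": mag,
                        "burst_id": burst_id,
                    }
                )
            )
            truth_rows.append(
                pd.DataFrame(
                    {"burst_id": burst_id, "mode": mode, "behavior": behavior, "pattern": pattern},
                    index=np.arange(n),
                )
            )
            # advance through the duty-cycle gap, drifting along the route
            gap_s = rng.uniform(cfg.gap_min[0] * 60, cfg.gap_min[1] * 60)
            cur_time = times[-1] + pd.Timedelta(seconds=round(gap_s))
            gx = x[-1] + 5.0 * np.sin(np.radians(225.0)) * gap_s
            gy = y[-1] + 5.0 * np.cos(np.radians(225.0)) * gap_s
            cur_lon, cur_lat = xy_to_lonlat(gx, gy, cur_lon, cur_lat)
            cur_lon, cur_lat = float(cur_lon), float(cur_lat)
            burst_id += 1
    track = pd.concat(rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return LabeledTrack(track=track, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Decision datasets with known logistic structure
# ---------------------------------------------------------------------------


def simulate_soaring_dataset(config: SimConfig, n_points: int, n_birds: int = 10) -> pd.DataFrame:
    """Binary soaring/flapping table with known standardized-logit structure.

    Covariates (wind support, |side wind|, delta-T) are drawn standard
    normal — i.e. already on the standardized scale the coefficients refer
    to — the interaction is their product, and each bird gets a normal
    random intercept of SD ``config.re_sd``.
    """
    if n_points < 50:
        raise ValueError("n_points < 50 cannot support a stable logistic fit")
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    b0, bt, bs, bd, bi = cfg.soaring_logit
    tail = rng.standard_normal(n_points)
    side = rng.standard_normal(n_points)
    dT = rng.standard_normal(n_points)
    birds = rng.integers(0, n_birds, n_points)
    re = rng.normal(0, cfg.re_sd, n_birds)
    eta = b0 + bt * tail + bs * side + bd * dT + bi * tail * dT + re[birds]
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n_points) < p).astype(int)
    return pd.DataFrame(
        {
            "bird_id": [f"bird_{i:02d}" for i in birds],
            "tailwind": tail,
            "sidewind": side,
            "delta_T": dT,
            "soaring": y,
        }
    )


def simulate_departure_dataset(
    config: SimConfig,
    n_days: int,
    n_birds: int = 19,
    beta_wind: float = DEFAULT_DEPARTURE_BETA,
    intercept: float = -1.5,
) -> pd.DataFrame:
    """Hourly resting-vs-departure records with a logistic departure rule.

    Each bird waits by the coast; every morning (records on the hour from
    6:00 to 13:00 local) it departs with probability
    ``logistic(intercept + beta_wind * wind_support_z)`` given that day's
    (standardized) wind support.  At most one departure day per bird; resting
    days are labeled 0, the departure day 1.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for b in range(n_birds):
        bird = f"bird_{b:02d}"
        re = rng.normal(0, cfg.re_sd)
        for day in range(n_days):
            ws = rng.standard_normal()
            sw = np.abs(rng.standard_normal())
            cloud = rng.uniform(0, 1)
            precip = np.abs(rng.normal(0, 0.2))
            p_dep = 1.0 / (1.0 + np.exp(-(intercept + beta_wind * ws + re)))
            departed = int(rng.random() < p_dep)
            last_hour = int(rng.integers(8, 12)) if departed else 13
            for hour in range(6, last_hour + 1):
                rows.append(
                    {
                        "bird_id": bird,
                        "date": pd.Timestamp("2020-09-15") + pd.Timedelta(days=day),
                        "hour": hour,
                        "tailwind": ws + rng.normal(0, 0.1),
                        "sidewind": sw + np.abs(rng.normal(0, 0.1)),
                        "cloud": np.clip(cloud + rng.normal(0, 0.05), 0, 1),
                        "precip": precip,
                        "departed": departed,
                    }
                )
            if departed:
                break
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sea-crossing scenery: corridor mask and staging/crossing tracks
# ---------------------------------------------------------------------------


def make_corridor_mask(
    lat=43.0, coast_east_lon=15.2, sea_width_km=200.0, land_depth_deg=3.0, lat_span_deg=3.0
) -> LandSeaMask:
    """Two rectangular land blocks separated by a sea corridor of given width.

    The eastern block's west edge sits at ``coast_east_lon`` (the departure
    coast); the western block (the arrival coast) lies ``sea_width_km``
    further west at the reference latitude.
    """
    deg_per_km = 1.0 / (111.195 * np.cos(np.radians(lat)))
    coast_west_lon = coast_east_lon - sea_width_km * deg_per_km
    east = box(coast_east_lon, lat - lat_span_deg, coast_east_lon + land_depth_deg, lat + lat_span_deg)
    west = box(coast_west_lon - land_depth_deg, lat - lat_span_deg, coast_west_lon, lat + lat_span_deg)
    return LandSeaMask([east, west])


def straight_transit_track(
    start_lon,
    start_lat,
    azimuth_deg_: float,
    distance_km: float,
    speed_kmh: float,
    fix_interval_s: float = 60.0,
    start_time="2020-10-03T08:10:00",
    bird_id="bird_00",
    altitude_m: float = 150.0,
) -> pd.DataFrame:
    """A constant-speed straight track (equirectangular about the start).

    Convenience constructor for crossing-detection checks: the along-track
    length of the returned fixes telescopes to ``distance_km``.
    """
    duration_s = distance_km / speed_kmh * 3600.0
    t = np.arange(0, duration_s + fix_interval_s / 2, fix_interval_s)
    d = np.minimum(t * speed_kmh / 3.6, distance_km * 1000.0)
    x = d * np.sin(np.radians(azimuth_deg_))
    y = d * np.cos(np.radians(azimuth_deg_))
    lon, lat = xy_to_lonlat(x, y, start_lon, start_lat)
    return pd.DataFrame(
        {
            "bird_id": bird_id,
            "timestamp": pd.Timestamp(start_time) + pd.to_timedelta(t, unit="s"),
            "lon": lon,
            "lat": lat,
            "altitude_msl": altitude_m,
            "ground_speed": speed_kmh,
        }
    )


def simulate_staging_and_crossing(
    config: SimConfig,
    n_birds: int = 6,
    max_rest_days: int = 8,
    beta_wind: float = DEFAULT_DEPARTURE_BETA,
    intercept: float = -1.0,
    utc_offset_h: int = 2,
    sea_width_km: float = 200.0,
):
    """Track-level staging + crossing scenario with weather columns attached.

    Birds sit on the departure coast; each morning they sample hourly fixes
    (6:00-13:00 local) just inland, then depart with a wind-dependent
    logistic probability, crossing westward at ~58 km/h.  Returns
    ``(track, mask, truth)`` where ``track`` already carries
    tailwind/sidewind/cloud/precip columns (as an annotated track would) and
    ``truth`` maps bird -> departure date (or None).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed + 7)
    mask = make_corridor_mask(coast_east_lon=15.2, sea_width_km=sea_width_km)
    rows = []
    truth = {}
    base_day = pd.Timestamp("2020-10-01")
    coast_lon, coast_lat = 15.25, 43.0  # just inland of the 15.2 coast
    for b in range(n_birds):
        bird = f"bird_{b:02d}"
        re = rng.normal(0, cfg.re_sd)
        truth[bird] = None
        lat_b = coast_lat + 0.1 * (b - n_birds / 2)
        for day in range(max_rest_days):
            date = base_day + pd.Timedelta(days=day)
            ws = rng.standard_normal()
            sw = abs(rng.standard_normal())
            cloud = rng.uniform(0, 1)
            precip = abs(rng.normal(0, 0.1))
            p_dep = 1.0 / (1.0 + np.exp(-(intercept + beta_wind * ws + re)))
            departs = day >= 2 and rng.random() < p_dep  # rests >= 2 days first
            dep_hour = int(rng.integers(8, 12))
            for hour in range(6, 14):
                if departs and hour >= dep_hour:
                    break
                ts = date + pd.Timedelta(hours=hour - utc_offset_h)
                rows.append(
                    {
                        "bird_id": bird, "timestamp": ts,
                        "lon": coast_lon + rng.normal(0, 0.005),
                        "lat": lat_b + rng.normal(0, 0.005),
                        "altitude_msl": 120.0, "ground_speed": 5.0,
                        "tailwind": ws + rng.normal(0, 0.1),
                        "sidewind": sw + abs(rng.normal(0, 0.1)),
                        "cloud": cloud, "precip": precip,
                    }
                )
            if departs:
                truth[bird] = date
                t0 = date + pd.Timedelta(hours=dep_hour - utc_offset_h)
                transit = straight_transit_track(
                    15.19, lat_b, 270.0, sea_width_km - 6.0, 58.0,
                    fix_interval_s=120.0, start_time=t0, bird_id=bird,
                )
                transit["tailwind"] = ws + rng.normal(0, 0.1, len(transit))
                transit["sidewind"] = sw + np.abs(rng.normal(0, 0.1, len(transit)))
                transit["cloud"] = cloud
                transit["precip"] = precip
                rows.extend(transit.to_dict("records"))
                break
    track = pd.DataFrame(rows).sort_values(["bird_id", "timestamp"]).reset_index(drop=True)
    return track, mask, truth


# ---------------------------------------------------------------------------
# Synthetic weather grids
# ---------------------------------------------------------------------------


def make_weather_grid(
    times,
    lats,
    lons,
    levels=(1000.0, 925.0),
    u_fn=lambda t, lev, la, lo: np.full_like(la, 5.0),
    v_fn=lambda t, lev, la, lo: np.zeros_like(la),
    t_air_fn=lambda t, lev, la, lo: np.full_like(la, 18.0),
    t_surface_fn=lambda t, la, lo: np.full_like(la, 19.1),
    cloud_fn=lambda t, la, lo: np.full_like(la, 0.2),
    precip_fn=lambda t, la, lo: np.zeros_like(la),
):
    """Build a WeatherGrid from callables of (time index, [level,] lat, lon)."""
    import xarray as xr
    from .io_formats import WeatherGrid

    times = pd.DatetimeIndex(times)
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    levels = np.asarray(levels, dtype=float)
    la, lo = np.meshgrid(lats, lons, indexing="ij")

    def stack_level(fn):
        return np.stack(
            [np.stack([fn(ti, lev, la, lo) for lev in levels]) for ti in range(len(times))]
        )

    def stack_surface(fn):
        return np.stack([fn(ti, la, lo) for ti in range(len(times))])

    ds = xr.Dataset(
        {
            "u_wind": (("time", "level", "lat", "lon"), stack_level(u_fn)),
            "v_wind": (("time", "level", "lat", "lon"), stack_level(v_fn)),
            "t_air": (("time", "level", "lat", "lon"), stack_level(t_air_fn)),
            "t_surface": (("time", "lat", "lon"), stack_surface(t_surface_fn)),
            "cloud_cover": (("time", "lat", "lon"), stack_surface(cloud_fn)),
            "precipitation": (("time", "lat", "lon"), stack_surface(precip_fn)),
        },
        coords={"time": times, "level": levels, "lat": lats, "lon": lons},
    )
    return WeatherGrid(ds).validate()
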