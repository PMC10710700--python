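"""Sensor-based flight-mode classification for duty-cycled 1 Hz bursts.

The sorting mirrors the standard accelerometer/magnetometer workflow for
soaring raptors:

1. drop roosting points (ground speed below 1 km/h);
2. cut the track into bursts of consecutive 1-second fixes, keeping only
   bursts longer than 10 points;
3. split active (flapping) from passive flight on the accelerometer
   z-channel — passive flight is smooth and sits in the 800-1400 mG band;
4. split passive flight into thermal soaring (periodic oscillation of the
   magnetometer x-channel as the bird circles) and gliding (smooth mag_x);
5. for soaring bursts, call the three-way trajectory pattern
   (spiral / staircase / s_shape) from the turn geometry.

"Strong oscillation" and "smooth" are operationalized per-burst: passive
flight needs >= 90% of acc_z samples inside the passive band and a median
10 s windowed peak-to-peak under 300 mG; mag_x counts as oscillating when
its high-passed periodicity score (max normalized autocorrelation over
circling-period lags) reaches 0.3 and the signal crosses zero at least
twice per minute.  All thresholds are keyword-configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import classify_pattern
from .types import FlightSegment

PASSIVE_BAND_MG = (800.0, 1400.0)
SMOOTH_PTP_MG = 300.0
MIN_SPEED_KMH = 1.0
MIN_BURST_LEN = 11  # "more than 10 points"

__all__ = [
    "filter_roosting",
    "segment_bursts",
    "classify_activity",
    "classify_passive",
    "climb_rate",
    "classify_track",
]


def filter_roosting(track: pd.DataFrame, min_speed_kmh: float = MIN_SPEED_KMH) -> pd.DataFrame:
    """Drop fixes slower than ``min_speed_kmh`` (roosting/perched points).

    The boundary is kept: a fix at exactly the threshold speed survives.
    """
    if "ground_speed" not in track.columns:
        raise ValueError("track has no ground_speed column; cannot filter roosting")
    return track[track["ground_speed"] >= min_speed_kmh].reset_index(drop=True)


def segment_bursts(track: pd.DataFrame, min_len: int = MIN_BURST_LEN) -> list[pd.DataFrame]:
    """Maximal runs of consecutive 1-second fixes per bird.

    Runs shorter than ``min_len`` fixes are dropped (a classifiable burst
    needs more than 10 points at 1 Hz).
    """
    bursts = []
    for _, g in track.groupby("bird_id", sort=True):
        g = g.sort_values("timestamp").reset_index(drop=True)
        dt = g["timestamp"].diff().dt.total_seconds().to_numpy()
        breaks = np.flatnonzero(np.nan_to_num(dt, nan=9e9) != 1.0)
        edges = np.concatenate([breaks, [len(g)]])
        start = 0
        for end in edges:
            if end - start >= min_len:
                bursts.append(g.iloc[start:end].reset_index(drop=True))
            start = end
    return bursts


def _window_view(a: np.ndarray, w: int) -> np.ndarray:
    if a.size <= w:
        return a[None, :]
    return np.lib.stride_tricks.sliding_window_view(a, w)


def classify_activity(
    burst: pd.DataFrame,
    passive_band=PASSIVE_BAND_MG,
    smooth_ptp: float = SMOOTH_PTP_MG,
    window_s: int = 10,
) -> str:
    """Active (flapping) vs passive (soaring/gliding) from the acc z-channel.

    Passive requires both smoothness conditions to hold burst-wide: at least
    90% of samples inside the passive band, and a median 10 s windowed
    peak-to-peak below ``smooth_ptp``.  Anything else is active flight.
    """
    if "acc_z" not in burst.columns or burst["acc_z"].isna().any():
        raise ValueError("burst has no complete acc_z channel; cannot classify activity")
    az = burst["acc_z"].to_numpy(dtype=float)
    lo, hi = passive_band
    frac_in_band = np.mean((az >= lo) & (az <= hi))
    wins = _window_view(az, window_s)
    ptp = np.median(wins.max(axis=1) - wins.min(axis=1))
    return "passive" if (frac_in_band >= 0.9 and ptp < smooth_ptp) else "active"


def classify_passive(
    burst: pd.DataFrame,
    osc_threshold: float = 0.3,
    min_crossings_per_min: float = 2.0,
    max_lag_s: int = 40,
    highpass_s: int = 31,
) -> str:
    """Thermal soaring vs gliding from the magnetometer x-channel.

    Soaring shows periodic mag_x oscillation as the heading rotates (one
    cycle per turn, intermittently for circle-and-run flight).  The burst is
    high-passed by subtracting a centred ``highpass_s`` moving average
    (removing slow heading wander), then scored by the maximum normalized
    autocorrelation over lags of 2..``max_lag_s`` seconds — the range of
    plausible circling periods.  Soaring requires that periodicity score
    >= ``osc_threshold`` and at least ``min_crossings_per_min`` zero
    crossings per minute; anything smoother is gliding.
    """
    if "mag_x" not in burst.columns or burst["mag_x"].isna().any():
        raise ValueError("burst has no complete mag_x channel; cannot classify passive flight")
    mx = burst["mag_x"].to_numpy(dtype=float)
    n = mx.size
    w = min(highpass_s, n if n % 2 else n - 1)
    pad = w // 2
    padded = np.pad(mx, pad, mode="reflect")
    baseline = np.convolve(padded, np.ones(w) / w, mode="valid")
    resid = mx - baseline

    var = float(np.dot(resid, resid))
    periodicity = 0.0
    if var > 0:
        for lag in range(2, min(max_lag_s, n - 2) + 1):
            c = float(np.dot(resid[:-lag], resid[lag:])) / var
            periodicity = max(periodicity, c)

    crossings = int(np.count_nonzero(np.diff(np.signbit(resid))))
    needed = max(2.0, min_crossings_per_min * n / 60.0)
    return "soaring" if (periodicity >= osc_threshold and crossings >= needed) else "gliding"


def climb_rate(segment: pd.DataFrame) -> float:
    """Vertical rate from the altitude extremes of a burst, m/s.

    (max altitude - min altitude) divided by the elapsed seconds between the
    two extremes; positive when the maximum occurs after the minimum,
    negative when the burst descends, 0 for flat altitude.
    """
    if len(segment) < 2:
        raise ValueError("climb rate needs at least 2 fixes")
    alt = segment["altitude_msl"].to_numpy(dtype=float)
    ts = segment["timestamp"].to_numpy().astype("datetime64[s]").astype(np.int64)
    i_max = int(np.argmax(alt))
    i_min = int(np.argmin(alt))
    dt = ts[i_max] - ts[i_min]
    if dt == 0:
        return 0.0
    return float((alt[i_max] - alt[i_min]) / abs(dt) * np.sign(dt))


def classify_track(
    track: pd.DataFrame,
    min_speed_kmh: float = MIN_SPEED_KMH,
    min_len: int = MIN_BURST_LEN,
    passive_band=PASSIVE_BAND_MG,
    smooth_ptp: float = SMOOTH_PTP_MG,
    osc_threshold: float = 0.3,
) -> list[FlightSegment]:
    """Full per-burst pipeline: roost filter, burst cut, two-stage sort, pattern.

    Returns one FlightSegment per retained burst with behavior, soaring
    pattern, climb rate and turn summary filled in.
    """
    moving = filter_roosting(track, min_speed_kmh)
    segments = []
    for seg_id, burst in enumerate(segment_bursts(moving, min_len)):
        activity = classify_activity(burst, passive_band, smooth_ptp)
        if activity == "active":
            behavior, pattern = "flapping", "none"
            n_turns, med_diam = 0, float("nan")
        else:
            behavior = classify_passive(burst, osc_threshold)
            if behavior == "soaring":
                pattern, turns, med_diam = classify_pattern(
                    burst["lon"].to_numpy(), burst["lat"].to_numpy()
                )
                n_turns = len(turns)
            else:
                pattern, n_turns, med_diam = "none", 0, float("nan")
        segments.append(
            FlightSegment(
                segment_id=seg_id,
                bird_id=burst["bird_id"].iloc[0],
                fixes=burst,
                behavior=behavior,
                pattern=pattern,
                climb_rate=climb_rate(burst),
                mean_altitude=float(burst["altitude_msl"].mean()),
                n_turns=n_turns,
                median_diameter_m=med_diam,
            )
        )
    return segments
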