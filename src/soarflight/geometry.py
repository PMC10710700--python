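"""Trajectory geometry: great-circle utilities, turn detection and soaring-pattern rules.

Soaring bursts are classified into three shapes by their turning behaviour:

* ``spiral``    — full turns with fitted circle diameter < 10 m,
* ``staircase`` — full turns with diameter >= 10 m, typically separated by
  straight runs,
* ``s_shape``   — heading oscillates but never accumulates a full 360 deg turn.

Turn diameters are estimated with an algebraic circle fit in a local tangent
plane.  Bursts span at most a few kilometres, so tangent-plane distortion is
far below the GPS noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

EARTH_RADIUS_M = 6_371_008.8

SPIRAL_DIAMETER_MAX_M = 10.0  # turns tighter than this are "spiral"
FULL_TURN_DEG = 360.0

__all__ = [
    "EARTH_RADIUS_M",
    "SPIRAL_DIAMETER_MAX_M",
    "Turn",
    "haversine_m",
    "azimuth_deg",
    "local_tangent_xy",
    "heading_series",
    "signed_angle_diff",
    "fit_circle",
    "detect_full_turns",
    "turn_diameter_m",
    "classify_pattern",
]


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def azimuth_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360).

    0 deg = geographic North, increasing clockwise (90 deg = East).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(x, y)) % 360.0


def local_tangent_xy(lon, lat, lon0=None, lat0=None):
    """Project lon/lat to a local equirectangular tangent plane in metres.

    x is east, y is north, origin at (lon0, lat0) (default: the centroid).
    Adequate for bursts spanning a few kilometres.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x = np.radians(lon - lon0) * np.cos(np.radians(lat0)) * EARTH_RADIUS_M
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def xy_to_lonlat(x, y, lon0, lat0):
    """Inverse of :func:`local_tangent_xy`."""
    lon = lon0 + np.degrees(np.asarray(x, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat0))))
    lat = lat0 + np.degrees(np.asarray(y, dtype=float) / EARTH_RADIUS_M)
    return lon, lat


def signed_angle_diff(a_deg, b_deg):
    """Signed minimal angle b - a, wrapped to (-180, 180]."""
    d = (np.asarray(b_deg, dtype=float) - np.asarray(a_deg, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def heading_series(lon, lat):
    """Consecutive-fix azimuths: heading[i] is the bearing fix i -> fix i+1."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return azimuth_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])


@dataclass
class Turn:
    """One accumulated full (360 deg) turn within a segment.

    ``start``/``end`` index the segment's fixes (end inclusive);
    ``cumulative_heading_change`` is signed degrees over the turn;
    ``diameter`` (metres) is filled in by :func:`turn_diameter_m`.
    """

    start: int
    end: int
    cumulative_heading_change: float
    diameter: float | None = None


def fit_circle(x, y):
    """Fit a circle to 2-D points; returns (cx, cy, radius).

    Hyper-accurate algebraic fit (Al-Sharadqah & Chernov): solves the
    generalized eigenproblem M A = eta H A for the circle parameters
    a(x^2+y^2) + b x + c y + d = 0.  Its leading-order noise bias vanishes,
    unlike the plain Kasa fit, which matters for small circles with
    metre-level GPS noise.

    Raises ``ValueError`` for degenerate (collinear or < 3 point) input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("circle fit needs at least 3 points")
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    z = u * u + v * v
    Z = np.column_stack([z, u, v, np.ones_like(u)])
    M = (Z.T @ Z) / x.size
    zbar = z.mean()
    H = np.array(
        [
            [8.0 * zbar, 0.0, 0.0, 2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [2.0, 0.0, 0.0, 0.0],
        ]
    )
    try:
        eigvals, eigvecs = linalg.eig(M, H)
    except linalg.LinAlgError as exc:  # pragma: no cover - scipy internal failure
        raise ValueError("degenerate circle fit") from exc
    eigvals = np.real(eigvals)
    finite = np.isfinite(eigvals)
    # smallest non-negative eigenvalue gives the hyper fit solution
    pos = finite & (eigvals > -1e-12)
    if not np.any(pos):
        raise ValueError("degenerate circle fit (collinear points?)")
    k = np.where(pos)[0][np.argmin(eigvals[pos])]
    a, b, c, d = np.real(eigvecs[:, k])
    if abs(a) < 1e-12 * max(abs(b), abs(c), 1.0):
        raise ValueError("degenerate circle fit (collinear points?)")
    cx = -b / (2 * a)
    cy = -c / (2 * a)
    r2 = cx * cx + cy * cy - d / a
    if not np.isfinite(r2) or r2 <= 0:
        raise ValueError("degenerate circle fit")
    r = float(np.sqrt(r2))
    # noise pushes points outward on average, inflating the apparent radius
    # by ~sigma^2/r; shrink by the radial residual variance to compensate
    if x.size > 4:
        resid = np.hypot(u - cx, v - cy) - r
        s2 = float(np.var(resid, ddof=3))
        r = float(np.sqrt(max(r * r - s2, 0.04 * r * r)))
    return cx + xm, cy + ym, r


def detect_full_turns(lon, lat):
    """Scan cumulative signed heading change and emit a Turn per full 360 deg.

    Heading comes from consecutive-fix azimuths; after each full turn the
    cumulative count resets, carrying the residual beyond 360 deg into the
    next turn.  Fewer than 3 fixes -> no turns.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon.size < 3:
        return []
    headings = heading_series(lon, lat)
    deltas = signed_angle_diff(headings[:-1], headings[1:])
    turns: list[Turn] = []
    cum = 0.0
    start = 0  # fix index where the current turn started
    for i, d in enumerate(deltas):
        cum += d
        if abs(cum) >= FULL_TURN_DEG:
            end = i + 2  # delta i involves fixes i, i+1, i+2
            turns.append(Turn(start=start, end=end, cumulative_heading_change=float(cum)))
            cum -= np.sign(cum) * FULL_TURN_DEG
            start = end
    return turns


def turn_diameter_m(turn, lon, lat):
    """Least-squares circle diameter (metres) of one turn's fixes.

    Fits in the local tangent plane about the turn's own centroid and stores
    the result on ``turn.diameter``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    sl = slice(turn.start, turn.end + 1)
    x, y = local_tangent_xy(lon[sl], lat[sl])
    _, _, r = fit_circle(x, y)
    turn.diameter = 2.0 * r
    return turn.diameter


def classify_pattern(lon, lat, spiral_max_diameter_m=SPIRAL_DIAMETER_MAX_M):
    """Three-way soaring-pattern call for one soaring segment.

    No full turns -> ``s_shape``.  Otherwise each turn is classed by its
    fitted diameter (< 10 m spiral, >= 10 m staircase; the boundary value
    goes to staircase) and the segment takes the more frequent turn class,
    staircase on a tie.  Returns ``(pattern, turns, median_diameter_or_nan)``.
    """
    turns = detect_full_turns(lon, lat)
    diameters = []
    for t in turns:
        try:
            diameters.append(turn_diameter_m(t, lon, lat))
        except ValueError:
            continue  # unfittable turn (degenerate); ignore it
    if not diameters:
        return "s_shape", turns, float("nan")
    diam = np.asarray(diameters)
    n_spiral = int(np.sum(diam < spiral_max_diameter_m))
    n_stair = diam.size - n_spiral
    pattern = "spiral" if n_spiral > n_stair else "staircase"
    return pattern, turns, float(np.median(diam))
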