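"""Geodesic utilities, turn detection and circle fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soarflight.geometry import (
    EARTH_RADIUS_M,
    azimuth_deg,
    classify_pattern,
    detect_full_turns,
    fit_circle,
    haversine_m,
    local_tangent_xy,
    turn_diameter_m,
    xy_to_lonlat,
)


def brute_force_bearing(lon1, lat1, lon2, lat2):
    """Independent spherical bearing via 3-D vectors (east/north projection)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    p1 = np.array([np.cos(phi1) * np.cos(lam1), np.cos(phi1) * np.sin(lam1), np.sin(phi1)])
    p2 = np.array([np.cos(phi2) * np.cos(lam2), np.cos(phi2) * np.sin(lam2), np.sin(phi2)])
    east = np.array([-np.sin(lam1), np.cos(lam1), 0.0])
    north = np.cross(p1, east)
    d = p2 - p1 * (p1 @ p2)
    return np.degrees(np.arctan2(d @ east, d @ north)) % 360.0


class TestHaversine:
    def test_coincident_points(self):
        assert haversine_m(12.3, 45.6, 12.3, 45.6) == 0.0

    def test_one_degree_meridian_closed_form(self):
        # pi * R / 180 for one degree along a meridian
        expected = np.pi * EARTH_RADIUS_M / 180.0
        assert haversine_m(0.0, 0.0, 0.0, 1.0) == pytest.approx(expected, abs=1.0)
        assert haversine_m(0.0, 0.0, 0.0, 1.0) == pytest.approx(111_195.0, abs=1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        lon1=st.floats(-179, 179), lat1=st.floats(-85, 85),
        lon2=st.floats(-179, 179), lat2=st.floats(-85, 85),
    )
    def test_symmetry(self, lon1, lat1, lon2, lat2):
        assert haversine_m(lon1, lat1, lon2, lat2) == pytest.approx(
            haversine_m(lon2, lat2, lon1, lat1), rel=1e-12
        )


class TestAzimuth:
    @pytest.mark.parametrize(
        "p2,expected",
        [((45.001, 40.0), 90.0), ((45.0, 39.9), 180.0), ((45.0, 40.1), 0.0)],
    )
    def test_cardinal_directions(self, p2, expected):
        assert azimuth_deg(45.0, 40.0, *p2) == pytest.approx(expected, abs=0.05)

    def test_matches_brute_force_spherical_formula(self):
        got = azimuth_deg(15.0, 45.0, 16.0, 42.0)
        assert got == pytest.approx(brute_force_bearing(15.0, 45.0, 16.0, 42.0), abs=0.01)


class TestCircleFit:
    @pytest.mark.parametrize("radius", [4.0, 15.0])
    def test_exact_on_perfect_circle(self, radius):
        th = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        cx, cy, r = fit_circle(3 + radius * np.cos(th), -2 + radius * np.sin(th))
        assert (cx, cy, 2 * r) == pytest.approx((3, -2, 2 * radius), abs=0.05)

    def test_collinear_points_rejected(self):
        x = np.linspace(0, 10, 12)
        with pytest.raises(ValueError):
            fit_circle(x, 2 * x + 1)

    def test_noisy_circle_monte_carlo(self):
        # 20 points, sigma = 1 m GPS, radius 4 m: diameter within +-1.5 m
        rng = np.random.default_rng(42)
        diams = []
        for _ in range(200):
            th = rng.uniform(0, 2 * np.pi, 20)
            x = 4 * np.cos(th) + rng.normal(0, 1, 20)
            y = 4 * np.sin(th) + rng.normal(0, 1, 20)
            _, _, r = fit_circle(x, y)
            diams.append(2 * r)
        assert np.mean(diams) == pytest.approx(8.0, abs=1.5)

    @pytest.mark.parametrize("radius", [2.0, 10.0, 50.0])
    def test_estimator_unbiased_within_5pct(self, radius):
        rng = np.random.default_rng(int(radius))
        est = []
        for _ in range(400):
            th = rng.uniform(0, 2 * np.pi, 36)
            x = radius * np.cos(th) + rng.normal(0, 1.0, 36)
            y = radius * np.sin(th) + rng.normal(0, 1.0, 36)
            est.append(fit_circle(x, y)[2])
        assert np.mean(est) == pytest.approx(radius, rel=0.05)


def circle_track(radius_m=20.0, period_s=20.0, duration_s=62, lon0=15.0, lat0=43.0):
    t = np.arange(duration_s + 1, dtype=float)
    phi = 2 * np.pi * t / period_s
    return xy_to_lonlat(radius_m * np.sin(phi), radius_m * np.cos(phi), lon0, lat0)


class TestTurns:
    def test_three_turns_on_60s_circle(self):
        lon, lat = circle_track(period_s=20.0, duration_s=62)
        turns = detect_full_turns(lon, lat)
        assert len(turns) == 3
        for t in turns:
            assert abs(t.cumulative_heading_change) >= 360.0

    def test_straight_path_has_none(self):
        lon = np.linspace(15.0, 15.1, 50)
        lat = np.linspace(43.0, 43.05, 50)
        assert detect_full_turns(lon, lat) == []

    def test_turn_diameter_recovers_circle(self):
        lon, lat = circle_track(radius_m=15.0, period_s=24.0, duration_s=80)
        turns = detect_full_turns(lon, lat)
        d = turn_diameter_m(turns[0], lon, lat)
        assert d == pytest.approx(30.0, abs=0.2)

    def test_tangent_plane_round_trip(self):
        lon = np.array([14.9, 15.0, 15.1])
        lat = np.array([42.95, 43.0, 43.05])
        x, y = local_tangent_xy(lon, lat)
        lon2, lat2 = xy_to_lonlat(x, y, np.mean(lon), np.mean(lat))
        assert np.allclose(lon2, lon, atol=1e-9)
        assert np.allclose(lat2, lat, atol=1e-9)


class TestPatternRule:
    def test_small_circles_are_spiral(self):
        lon, lat = circle_track(radius_m=4.0, period_s=8.0, duration_s=60)
        pattern, turns, med = classify_pattern(lon, lat)
        assert pattern == "spiral"
        assert med < 10.0
        assert len(turns) >= 5

    def test_large_circles_are_staircase(self):
        lon, lat = circle_track(radius_m=15.0, period_s=15.0, duration_s=60)
        pattern, _, med = classify_pattern(lon, lat)
        assert pattern == "staircase"
        assert med > 10.0

    def test_heading_oscillation_is_s_shape(self):
        t = np.arange(120.0)
        h = np.radians(270.0 + 70.0 * np.sin(2 * np.pi * t / 20.0))
        x = np.cumsum(10 * np.sin(h))
        y = np.cumsum(10 * np.cos(h))
        lon, lat = xy_to_lonlat(x, y, 15.0, 43.0)
        pattern, turns, _ = classify_pattern(lon, lat)
        assert pattern == "s_shape"
        assert turns == []
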