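"""Crossing detection, metric identities and the departure dataset."""

import numpy as np
import pandas as pd
import pytest

from soarflight.crossings import build_departure_dataset, detect_crossings
from soarflight.synthetic import (
    SimConfig,
    make_corridor_mask,
    simulate_staging_and_crossing,
    straight_transit_track,
)
from soarflight.types import events_frame


class TestDetectCrossings:
    def test_constructed_189km_transit_metrics(self, corridor_mask):
        track = straight_transit_track(15.15, 43.0, 270.0, 189.0, 58.0)
        events = detect_crossings(track, corridor_mask)
        assert len(events) == 1
        e = events[0]
        assert e.route_length_km == pytest.approx(189.0, abs=1.0)
        assert e.mean_speed_kmh == pytest.approx(58.0, abs=0.5)
        assert e.duration_h == pytest.approx(e.route_length_km / e.mean_speed_kmh, rel=1e-9)

    def test_all_land_track_empty(self, corridor_mask):
        track = straight_transit_track(16.0, 43.0, 0.0, 50.0, 58.0)
        assert detect_crossings(track, corridor_mask) == []

    def test_two_transits_two_events(self, corridor_mask):
        # both transits end past the far coast so each over-water run closes
        out = straight_transit_track(15.15, 43.0, 270.0, 205.0, 58.0, bird_id="A")
        back = straight_transit_track(13.1, 43.0, 90.0, 185.0, 58.0, bird_id="A",
                                      start_time="2020-10-05 08:00:00")
        track = pd.concat([out, back], ignore_index=True)
        events = detect_crossings(track, corridor_mask)
        assert len(events) == 2

    def test_short_coastal_loop_excluded(self, corridor_mask):
        loop = straight_transit_track(15.15, 43.0, 270.0, 8.0, 40.0)
        assert detect_crossings(loop, corridor_mask) == []

    def test_event_fixes_all_over_water(self, corridor_mask):
        track = straight_transit_track(15.3, 43.0, 270.0, 220.0, 58.0)  # starts on land
        events = detect_crossings(track, corridor_mask)
        assert len(events) == 1
        e = events[0]
        seg = track[(track["timestamp"] >= e.departure_time) & (track["timestamp"] <= e.arrival_time)]
        assert not corridor_mask.is_land(seg["lon"].to_numpy(), seg["lat"].to_numpy()).any()

    def test_events_frame_empty_columns(self):
        assert list(events_frame([]).columns)[:3] == ["bird_id", "departure_time", "arrival_time"]


class TestDepartureDataset:
    @pytest.fixture(scope="class")
    @staticmethod
    def scenario():
        cfg = SimConfig(seed=3)
        return simulate_staging_and_crossing(cfg, n_birds=8)

    def test_rest_days_zero_crossing_day_one(self, scenario):
        track, mask, truth = scenario
        dep = build_departure_dataset(track, mask)
        assert set(dep["departed"].unique()) == {0, 1}
        # crossing-day records exist exactly for birds that actually departed
        departed_birds = set(dep[dep["departed"] == 1]["bird_id"])
        assert departed_birds <= {b for b, d in truth.items() if d is not None}
        for bird in departed_birds:
            day = dep[(dep["bird_id"] == bird) & (dep["departed"] == 1)]["date"].unique()
            assert len(day) == 1
            assert pd.Timestamp(day[0]) == truth[bird]

    def test_hours_within_morning_window(self, scenario):
        track, mask, _ = scenario
        dep = build_departure_dataset(track, mask)
        assert dep["hour"].between(6, 13).all()

    def test_offshore_excursion_without_crossing_stays_resting(self, corridor_mask):
        # a bird pokes 8 km offshore on a rest morning, returns, then crosses next day
        rest1 = straight_transit_track(15.25, 43.0, 270.0, 1.0, 10.0, fix_interval_s=600,
                                       start_time="2020-10-01 05:00:00", bird_id="X")
        poke_out = straight_transit_track(15.19, 43.0, 270.0, 8.0, 30.0, fix_interval_s=120,
                                          start_time="2020-10-02 05:00:00", bird_id="X")
        poke_back = straight_transit_track(poke_out["lon"].iloc[-1], 43.0, 90.0, 10.0, 30.0,
                                           fix_interval_s=120, start_time="2020-10-02 06:00:00",
                                           bird_id="X")  # ends back on land
        cross = straight_transit_track(15.19, 43.0, 270.0, 190.0, 58.0, fix_interval_s=120,
                                       start_time="2020-10-03 06:00:00", bird_id="X")
        track = pd.concat([rest1, poke_out, poke_back, cross], ignore_index=True)
        for c in ("tailwind", "sidewind", "cloud", "precip"):
            track[c] = 1.0
        dep = build_departure_dataset(track, corridor_mask, min_rest_days=2)
        poke_day = dep[dep["date"] == pd.Timestamp("2020-10-02")]
        assert len(poke_day) > 0
        assert (poke_day["departed"] == 0).all()
        cross_day = dep[dep["date"] == pd.Timestamp("2020-10-03")]
        assert (cross_day["departed"] == 1).all()

    def test_departure_dataset_recovers_wind_effect_sign(self):
        from soarflight.stats import ModelSpec, fit_model, standardize

        cfg = SimConfig(seed=11)
        track, mask, _ = simulate_staging_and_crossing(cfg, n_birds=25, beta_wind=2.0)
        dep = build_departure_dataset(track, mask)
        dep, _ = standardize(dep, ["tailwind"])
        res = fit_model(ModelSpec("departed", ["tailwind"]), dep)
        assert res.params["tailwind"] > 0
        assert res.pvalues["tailwind"] < 0.05

    def test_unannotated_track_refused(self, corridor_mask):
        track = straight_transit_track(15.15, 43.0, 270.0, 189.0, 58.0)
        with pytest.raises(ValueError, match="weather"):
            build_departure_dataset(track, corridor_mask)

    def test_no_staging_gives_empty_with_columns(self, corridor_mask):
        track = straight_transit_track(15.15, 43.0, 270.0, 189.0, 58.0)
        for c in ("tailwind", "sidewind", "cloud", "precip"):
            track[c] = 0.0
        dep = build_departure_dataset(track, corridor_mask)  # no rest days at all
        assert dep.empty
        assert "departed" in dep.columns
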