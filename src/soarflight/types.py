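"""Core record types shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BEHAVIORS = ("soaring", "gliding", "flapping")
PATTERNS = ("staircase", "spiral", "s_shape", "none")


@dataclass
class FlightSegment:
    """A classified burst: >= 11 consecutive 1 Hz fixes with one behavior label.

    ``pattern`` is one of staircase/spiral/s_shape for soaring segments and
    "none" otherwise.  ``climb_rate`` is (max - min altitude) / elapsed time
    between the two extrema, signed positive when the maximum comes later.
    """

    segment_id: int
    bird_id: object
    fixes: pd.DataFrame = field(repr=False)
    behavior: str = "soaring"
    pattern: str = "none"
    climb_rate: float = float("nan")
    mean_altitude: float = float("nan")
    n_turns: int = 0
    median_diameter_m: float = float("nan")

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if (self.behavior == "soaring") != (self.pattern != "none"):
            raise ValueError("pattern must be set iff behavior is soaring")

    def __len__(self):
        return len(self.fixes)


@dataclass
class CrossingEvent:
    """One sea crossing: the period between the first and last over-water fix."""

    bird_id: object
    departure_time: pd.Timestamp
    arrival_time: pd.Timestamp
    route_length_km: float
    n_fixes: int

    def __post_init__(self):
        if self.arrival_time <= self.departure_time:
            raise ValueError("arrival must come after departure")

    @property
    def duration_h(self) -> float:
        return (self.arrival_time - self.departure_time) / pd.Timedelta(hours=1)

    @property
    def mean_speed_kmh(self) -> float:
        return self.route_length_km / self.duration_h

    @property
    def year(self) -> int:
        return int(self.departure_time.year)

    def as_dict(self):
        return {
            "bird_id": self.bird_id,
            "departure_time": self.departure_time,
            "arrival_time": self.arrival_time,
            "duration_h": self.duration_h,
            "route_length_km": self.route_length_km,
            "mean_speed_kmh": self.mean_speed_kmh,
            "year": self.year,
            "n_fixes": self.n_fixes,
        }


def events_frame(events) -> pd.DataFrame:
    """Tabulate CrossingEvents (empty frame with the right columns if none)."""
    cols = [
        "bird_id", "departure_time", "arrival_time", "duration_h",
        "route_length_km", "mean_speed_kmh", "year", "n_fixes",
    ]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.as_dict() for e in events])[cols]
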