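"""Classify the fleet's bursts and score them against ground truth.

Reads results/tracks.csv, runs the sensor pipeline (roost filter, burst
segmentation, accelerometer activity split, magnetometer soaring/gliding
split, trajectory pattern call) and writes the per-fix segment table plus a
confusion summary.  Also prints the fleet's soar/flap position-count ratio,
the summary statistic used when contrasting terrain types.
"""

from pathlib import Path

import pandas as pd

from soarflight.classify import classify_track
from soarflight.io_formats import read_track, write_segments

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    track = read_track(OUT / "tracks.csv", dialect="simple")
    truth = pd.read_csv(OUT / "truth.csv", parse_dates=["timestamp"])
    track = track.merge(truth[["bird_id", "timestamp", "burst_id", "behavior", "pattern"]]
                        .rename(columns={"behavior": "true_behavior", "pattern": "true_pattern"}),
                        on=["bird_id", "timestamp"], how="left")

    segments = classify_track(track)
    write_segments(segments, OUT / "segments.csv", OUT / "segments.geojson")

    rows = []
    for seg in segments:
        rows.append({
            "true": seg.fixes["true_behavior"].mode()[0],
            "true_pattern": seg.fixes["true_pattern"].mode()[0],
            "pred": seg.behavior, "pattern": seg.pattern, "n": len(seg),
        })
    df = pd.DataFrame(rows)
    confusion = pd.crosstab(df["true"], df["pred"])
    confusion.to_csv(OUT / "classification_confusion.csv")
    print("behavior confusion (segments):")
    print(confusion.to_string())
    soar = df[df["pred"] == "soaring"]["n"].sum()
    flap = df[df["pred"] == "flapping"]["n"].sum()
    print(f"\nsoar/flap position ratio: {soar / flap:.2f} "
          f"({soar} soaring vs {flap} flapping fixes)")
    pat = pd.crosstab(df[df["true"] == "soaring"]["true_pattern"], df[df["true"] == "soaring"]["pattern"])
    print("\nsoaring pattern confusion:")
    print(pat.to_string())


if __name__ == "__main__":
    main()
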