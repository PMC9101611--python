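#!/usr/bin/env python
"""Compute the five texture features for every cohort ROI.

Each ROI is normalized to its own mean +/- 3 SD of optical density,
quantized to 64 gray levels, and summarized by co-occurrence entropy and
difference entropy (displacement distance 5, four directions averaged),
run-length long-run emphasis (four directions averaged), and the derived
texture and bone indices.  One CSV row per ROI goes to
results/features.csv.

By default the cohort is generated in memory from the same seed as
01_simulate_cohort.py (identical pixel data, no disk round trip); pass
--metadata to run instead from a cohort written to disk.

Usage: python analysis/02_extract_features.py [--n 166] [--seed 1]
"""

import argparse
from pathlib import Path

from lesiontex.imaging_io import iter_rois, read_metadata
from lesiontex.pipeline import compute_features
from lesiontex.synthetic_data import iter_cohort

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=166)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--metadata", type=Path, default=None,
                    help="ROI metadata CSV (e.g. scratch/cohort/metadata.csv)")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "features.csv")
    args = ap.parse_args()

    if args.metadata is not None:
        meta = read_metadata(args.metadata)
        rois = (
            (rec.source_id, roi)
            for rec, roi in zip(meta.itertuples(index=False),
                                iter_rois(meta, root=args.metadata.parent))
        )
    else:
        rois = iter_cohort(args.n, base_seed=args.seed)

    df = compute_features(rois)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.12g")
    print(f"wrote {len(df)} feature rows to {args.out}")
    print(df.groupby(["lighting", "group_label"])[["LngREmph", "Entropy", "TI"]]
            .mean().round(3).to_string())


if __name__ == "__main__":
    main()
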