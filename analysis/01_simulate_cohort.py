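#!/usr/bin/env python
"""Generate the synthetic dermoscopy cohort used by the downstream steps.

Writes 166 ROIs per lesion group (benign nevus, dysplastic nevus,
melanoma) per lighting mode (polarized, non-polarized) as 450x450 8-bit
grayscale PNGs plus the ROI metadata CSV, mirroring the size of the
clinical cohort the analysis is designed for.

The images land under scratch/cohort/ (they are bulky and fully
reproducible from the seed); the metadata CSV is the interface consumed
by 02_extract_features.py.

Usage: python analysis/01_simulate_cohort.py [--n 166] [--seed 1]
"""

import argparse
from pathlib import Path

from lesiontex.synthetic_data import generate_cohort

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=166, help="ROIs per group per mode")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    meta = generate_cohort(args.out, n_per_group=args.n, base_seed=args.seed)
    by_cell = meta.groupby(["lighting", "group_label"]).size()
    print(f"wrote {len(meta)} ROIs under {args.out}")
    print(by_cell.to_string())


if __name__ == "__main__":
    main()
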