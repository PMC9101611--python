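#!/usr/bin/env python
"""Group comparison of the texture features, by lighting mode.

For each feature within each lighting mode: Shapiro-Wilk per group routes
to one-way ANOVA (Tukey HSD post-hoc) or Kruskal-Wallis (Dunn-Bonferroni
post-hoc); significant omnibus results are summarized as ordering strings
("MM > DN > BN" when all pairs separate).  Writes results/report.json and
a readable results/report.md table (per-group mean +/- SD, omnibus p,
orderings) and prints the orderings.

Usage: python analysis/03_compare_groups.py [--alpha 0.05]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lesiontex.cohort_stats import (
    analyze_features,
    group_statistics,
    render_report_markdown,
    summarize_table,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=ROOT / "results" / "features.csv")
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    df = pd.read_csv(args.features)
    results = analyze_features(df, alpha=args.alpha)
    report = summarize_table(results, group_statistics(df), alpha=args.alpha)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    with open(args.out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    (args.out_dir / "report.md").write_text(render_report_markdown(report))

    for comp in report["comparisons"]:
        note = comp["ordering"] if comp["significant"] else "n.s."
        print(f"{comp['lighting']:13s} {comp['feature']:9s} "
              f"{comp['test']:15s} p={comp['p_value']:.3g}  {note}")
    print(f"\nwrote {args.out_dir / 'report.json'} and report.md")


if __name__ == "__main__":
    main()
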