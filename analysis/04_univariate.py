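"""Confirmatory per-metabolite table over the discriminant ppm windows.

Reads the PQN-normalized (unscaled) analysis bucket table from 02,
integrates each named window with partial-bucket overlap weighting, tests
PCa vs BPH with the two-sided Mann-Whitney U test, and prints the group
means ± s.e.m., p-values and percent variations.  Writes
results/univariate.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from urimet import BucketTable, build_table, discriminant_regions

parser = argparse.ArgumentParser()
parser.add_argument("--table", type=Path, default=Path("results/bucket_table.csv"))
parser.add_argument("--out", type=Path, default=Path("results/univariate.csv"))
args = parser.parse_args()

if not args.table.exists():
    raise SystemExit(f"{args.table} not found - run analysis/02_preprocess.py first")

table = BucketTable.from_csv(args.table)
rows = build_table(table, discriminant_regions(), reference_group="BPH", case_group="PCa")

frame = pd.DataFrame(
    {
        "metabolite": [r.name for r in rows],
        "window_low_ppm": [r.window[0] for r in rows],
        "window_high_ppm": [r.window[1] for r in rows],
        "mean_bph": [r.mean_reference for r in rows],
        "sem_bph": [r.sem_reference for r in rows],
        "mean_pca": [r.mean_case for r in rows],
        "sem_pca": [r.sem_case for r in rows],
        "u_statistic": [r.u_statistic for r in rows],
        "p_value": [r.p_value for r in rows],
        "pct_variation": [r.percent_variation for r in rows],
        "significant": [r.significant for r in rows],
    }
)
args.out.parent.mkdir(parents=True, exist_ok=True)
frame.to_csv(args.out, index=False)

with pd.option_context("display.width", 140):
    print(frame.round(3).to_string(index=False))
n_sig = int(frame["significant"].sum())
print(f"\n{n_sig} of {len(frame)} regions significant at p < 0.05; wrote {args.out}")
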