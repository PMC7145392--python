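"""Dose-response: exposure vs pre/post change in every EEG summary.

Joins the exposure table with the band summaries and graph metrics, forms
post - pre deltas per athlete, and tests each metric x band with a Pearson
correlation (Bonferroni x5 across bands, 500-draw percentile bootstrap CI).
Also reruns the whole table with the count-only nHI exposure variant.
"""

import argparse
from pathlib import Path

import pandas as pd

from headnet.pipeline import dose_response_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--exposure", type=Path, default=Path("results/exposure_scored.csv"))
parser.add_argument("--bands", type=Path, default=Path("results/band_summaries.csv"))
parser.add_argument("--graphs", type=Path, default=Path("results/graph_metrics.csv"))
parser.add_argument("--n-boot", type=int, default=500)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/dose_response.csv"))
args = parser.parse_args()

exposure = pd.read_csv(args.exposure, index_col="athlete_id")
table = pd.read_csv(args.bands).drop(columns=["mode"], errors="ignore")
if args.graphs.exists():
    table = pd.concat([table, pd.read_csv(args.graphs)], ignore_index=True)

for column, suffix in [("wchi", ""), ("nhi", "_nhi")]:
    dose = dose_response_table(
        table, exposure[column].astype(float), n_boot=args.n_boot, seed=args.seed
    )
    out = args.out.with_name(args.out.stem + suffix + args.out.suffix)
    dose.to_csv(out, index=False)
    top = dose.sort_values("p_raw").head(6)
    print(f"\nexposure = {column}: strongest associations")
    print(top[["metric", "band", "r", "p_raw", "p_bonferroni", "ci_low", "ci_high"]]
          .round(3).to_string(index=False))
    print(f"written to {out}")
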