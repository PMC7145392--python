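"""Score head-impact exposure: confirmed-impact filter, PCS, wCHI, nHI.

Reads the impact table written by 01_simulate_cohort.py (or any CSV with
athlete_id, pla, prv, pra, confirmed columns), keeps confirmed impacts with
PLA > 16 g, computes per-impact principal component scores pooled over the
cohort, and writes per-athlete wCHI (sum of PCS) and nHI (impact count).
"""

import argparse
from pathlib import Path

import pandas as pd

from headnet.exposure import compute_wchi, filter_impacts

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--impacts", type=Path, default=Path("results/impacts.csv"))
parser.add_argument("--pla-threshold", type=float, default=16.0)
parser.add_argument("--out", type=Path, default=Path("results/exposure_scored.csv"))
args = parser.parse_args()

impacts = pd.read_csv(args.impacts)
confirmed = filter_impacts(impacts, pla_threshold=args.pla_threshold)
roster = sorted(impacts["athlete_id"].unique())
summary = compute_wchi(confirmed, roster=roster)
args.out.parent.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out)

print(f"{len(confirmed)}/{len(impacts)} impacts confirmed above {args.pla_threshold} g")
print(f"mean PLA {confirmed['pla'].mean():.1f} g, "
      f"PRV {confirmed['prv'].mean():.1f} rad/s, PRA {confirmed['pra'].mean():.1f} krad/s^2")
print(summary.sort_values("wchi", ascending=False).head(5))
print(f"written to {args.out}")
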