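#!/usr/bin/env python
"""Pioneer-dependence of secondary-factor binding sites and early occupancy.

Classifies committed-stage secondary-factor (Pax5-like) sites by pioneer
co-occupancy and by binding in the pioneer-knockout induction sample
(four-way scheme), summarizes accessibility per label, and reports the
fraction of sites already occupied 6 h after a fast induction.
"""

import argparse
from pathlib import Path

from tfkinetics.benchmarks import dependence_benchmark, early_overlap_benchmark

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

r = dependence_benchmark(seed=args.seed, n_secondary=400)
args.outdir.mkdir(parents=True, exist_ok=True)
r["classification"].to_csv(args.outdir / "dependence_classification.tsv",
                           sep="\t", index=False)
r["per_label"].to_csv(args.outdir / "dependence_summary.tsv", sep="\t")

print("four-way dependence labels:")
print(r["classification"]["label"].value_counts().to_string())
print(f"dependent fraction among cobound sites: {r['cobound_dependent_fraction']:.3f} "
      f"(planted 0.50)")
print(f"pre-induction accessibility: dependent "
      f"{r['dependent_accessible_pre_fraction']:.2f}, independent "
      f"{r['independent_accessible_pre_fraction']:.2f}")

e = early_overlap_benchmark(seed=args.seed, n_sites=500)
print(f"6-h occupancy overlap: persistent {100 * e['persistent_6h_fraction']:.0f}%, "
      f"transient {100 * e['transient_6h_fraction']:.0f}%")
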