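#!/usr/bin/env python
"""Temporal occupancy classes from noisy peak calls, scored against truth.

Builds the unified site catalog from simulated ChIP peaks (pooled replicate
evidence), classifies each site as pre-existing / gain24 / gain72 / gainproB
/ transient, and reports the class counts, the five-class recovery against
the planted labels, and the canonical-motif fraction per class (planted low,
~22%, only in the late-gain cluster).
"""

import argparse
from pathlib import Path

from tfkinetics.benchmarks import temporal_recovery
from tfkinetics.peaks import class_counts

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

r = temporal_recovery(seed=args.seed, n_sites=500, dropout=0.05)
catalog = r["catalog"]
counts = class_counts(catalog)
args.outdir.mkdir(parents=True, exist_ok=True)
catalog.to_frame().to_csv(args.outdir / "occupancy_catalog.tsv", sep="\t", index=False)
counts.rename("n_sites").to_frame().to_csv(args.outdir / "occupancy_class_counts.tsv", sep="\t")
r["motif_fraction_by_class"].rename("motif_fraction").to_frame().to_csv(
    args.outdir / "motif_fraction_by_class.tsv", sep="\t"
)

print(f"catalog: {r['n_catalog']} sites from {r['n_sites']} planted")
print(counts.to_string())
print(f"five-class recovery vs planted truth: {100 * r['accuracy']:.1f}%")
print("canonical-motif fraction by class:")
print(r["motif_fraction_by_class"].round(3).to_string())
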