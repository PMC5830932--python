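#!/usr/bin/env python
"""Site-anchored DNA demethylation kinetics (cloud-map data).

Measures +/-100-bp CpG methylation around persistent and transient sites at
each stage and summarizes the per-class median deltas. Expected from the
planted kinetics: a modest loss by 72 h in both classes, a pronounced
committed-stage loss only at persistent sites, and a flat pro-B delta at
transient sites. Also calls LMRs on the committed-stage methylome.
"""

import argparse
from pathlib import Path

from tfkinetics.benchmarks import methylation_recovery
from tfkinetics.methylation import call_lmrs
from tfkinetics.synthetic import NoiseModel, generate_genome, generate_methylome

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

r = methylation_recovery(seed=args.seed, n_sites=200, coverage=30.0)
args.outdir.mkdir(parents=True, exist_ok=True)
r["cloud"].to_csv(args.outdir / "methylation_cloud.tsv", sep="\t", index=False)
r["summary"].to_csv(args.outdir / "methylation_deltas.tsv", sep="\t")

genome = generate_genome(n_sites=200, seed=args.seed,
                         class_proportions={"gain24": 0.5, "transient": 0.5},
                         lmr_prob=1.0)
meth = generate_methylome(genome, NoiseModel(seed=args.seed + 202))
lmrs = call_lmrs(meth["proB"])
lmrs.write(args.outdir / "lmrs_proB.bed")

print(f"cloud table: {len(r['cloud'])} sites; {len(lmrs)} LMRs at the committed stage")
print("median deltas by class:")
print(r["summary"].round(3).to_string())
print(f"persistent delta(proB - 72h) = {r['persistent_delta_proB_72h']:+.3f} "
      f"(planted -0.45); transient = {r['transient_delta_proB_72h']:+.3f} (planted 0)")
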