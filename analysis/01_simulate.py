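#!/usr/bin/env python
"""Generate the synthetic multi-omic time course with planted ground truth.

Writes per-time-point/replicate ChIP and ATAC peak BEDs, strand-split Tn5
cut-count bedGraphs, per-stage methylation TSVs, the FPKM expression table,
gene models (GTF), and the truth sidecar (JSON). Defaults: 1 chromosome x
2 Mb, 500 sites in five equal temporal classes, 200 genes, 2 replicates.
"""

import argparse
from pathlib import Path

from tfkinetics.methylation import write_methylation
from tfkinetics.synthetic import (
    NoiseModel,
    generate_cut_counts,
    generate_expression,
    generate_genome,
    generate_methylome,
    generate_timecourse_peaks,
    write_cut_tracks,
    write_peak_files,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/data"))
args = ap.parse_args()

out = args.outdir
genome = generate_genome(seed=args.seed)
noise = NoiseModel(seed=args.seed + 1)
genome.write_truth(out / "truth.json")
genome.write_gtf(out / "genes.gtf")

chip = generate_timecourse_peaks(genome, noise, n_replicates=2, assay="chip")
atac = generate_timecourse_peaks(genome, noise, n_replicates=2, assay="atac")
write_peak_files(chip, out / "chip")
write_peak_files(atac, out / "atac")
write_cut_tracks(generate_cut_counts(genome, noise), out / "cuts")
for tp, track in generate_methylome(genome, noise).items():
    write_methylation(track, out / "methylation" / f"meth_{tp}.tsv")
table = generate_expression(genome, noise)
(out / "expression").mkdir(parents=True, exist_ok=True)
table.write(out / "expression" / "fpkm.tsv", out / "expression" / "samples.tsv")

classes = genome.truth_frame()["true_class"].value_counts()
print(f"wrote synthetic dataset to {out}")
print(f"  {len(genome.sites)} sites: " + ", ".join(f"{k}={v}" for k, v in classes.items()))
print(f"  {len(genome.genes)} genes; peaks at "
      + ", ".join(sorted({tp for tp, _ in chip})))
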