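#!/usr/bin/env python
"""Chromatin-accessibility dynamics around binding sites.

Computes +/-3 kb RPKM signal matrices from Tn5 cut tracks at each stage,
assigns the five accessibility clusters (pre-existing, gains at successive
stages, transient), summarizes the central dip of the committed-stage
profile, and reports the binding-site frequency within ATAC-peak clusters
(high in early clusters, low in the committed-stage cluster).
"""

import argparse
from pathlib import Path

import numpy as np

from tfkinetics.benchmarks import truth_catalog
from tfkinetics.signal import (
    SignalTrack,
    atac_peak_site_frequency,
    central_depletion_profile,
    classify_accessibility,
    compute_signal_matrix,
    estimate_background_rpkm,
)
from tfkinetics.synthetic import (
    NoiseModel,
    generate_cut_counts,
    generate_genome,
    generate_timecourse_peaks,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

genome = generate_genome(seed=args.seed)
noise = NoiseModel(seed=args.seed + 1)
catalog = truth_catalog(genome)
cuts = generate_cut_counts(genome, noise)
tracks = {tp: SignalTrack.from_cut_tracks(cuts[tp]) for tp in cuts}
mats = {tp: compute_signal_matrix(tracks[tp], catalog) for tp in tracks}
bg = estimate_background_rpkm(tracks["0h"], catalog)
labels = classify_accessibility(mats, catalog, min_rpkm="auto", background_rpkm=bg)
truth = np.array([s.true_class for s in genome.sites])
acc = float((labels.to_numpy() == truth).mean())

prof = central_depletion_profile(mats["proB"], labels)
atac = generate_timecourse_peaks(genome, noise, n_replicates=1, assay="atac")
freq = atac_peak_site_frequency({tp: atac[(tp, "rep1")] for tp in
                                 ("0h", "24h", "72h", "proB")}, catalog)

args.outdir.mkdir(parents=True, exist_ok=True)
labels.to_frame().to_csv(args.outdir / "accessibility_classes.tsv", sep="\t")
prof.to_csv(args.outdir / "central_depletion_proB.tsv", sep="\t", index=False)
freq.to_csv(args.outdir / "atac_peak_site_frequency.tsv", sep="\t", index=False)

print(f"background RPKM (toy library): {bg:.1f}; auto threshold = {5 * bg:.1f}")
print(f"accessibility-class recovery vs planted truth: {100 * acc:.1f}%")
print(labels.value_counts().to_string())
print("committed-stage center/shoulder ratios by cluster:")
print(prof[["class", "center_shoulder_ratio"]].round(3).to_string(index=False))
print("binding-site frequency within ATAC-peak clusters:")
print(freq.round(3).to_string(index=False))
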