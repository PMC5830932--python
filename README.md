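# tfkinetics

Time-resolved multi-omic analysis of pioneer-factor-driven lineage
programming, built for regulatory genomicists studying how an induced
transcription factor (the motivating system: EBF1 switching *Ebf1*⁻/⁻
pre-pro-B progenitors to committed CD19⁺ pro-B cells) reorganizes the
epigenome and transcriptome over a 0 h → 24 h → 72 h → committed-stage time
course. The package classifies binding sites by temporal occupancy, clusters
chromatin accessibility and methylation dynamics around them, calls Tn5
protection footprints and motif co-occurrence over time, clusters
gene-expression trajectories anchored to binding sites, and classifies
secondary-factor sites by their dependence on the pioneer — all runnable
end-to-end on synthetic data with planted ground truth.

## What it computes

- **Temporal occupancy classes.** Sites occupied at the committed stage are
  *persistent* (subclassed `preexisting`/`gain24`/`gain72`/`gainproB` by
  first occupied stage and prior accessibility); sites occupied at 24 and/or
  72 h but lost at commitment are *transient*.
- **Accessibility clusters.** RPKM signal matrices (±3 kb, 50-bp bins;
  RPKM = count·10⁹/(bin·library size)) feed a five-cluster scheme on central
  (±500 bp) signal with a gain threshold of 2× baseline.
- **Methylation kinetics.** Coverage-weighted CpG means in ±100-bp windows
  around LMR-associated sites, per stage, with per-class median deltas
  (cloud-map tables).
- **Footprints.** A Wellington-style strand-aware score,
  −log₁₀ P(Binom(N_fp + N_sh, w/(w+s)) ≤ N_fp) summed over strands, with
  shuffle-calibrated thresholds, plus per-motif footprinted fractions over
  time and pairwise co-occurrence odds ratios (Fisher, BH-adjusted).
- **Expression.** DE between 0 h and commitment (|log₂FC| > 1, p < 0.01 by a
  variance-moderated t on log₂(FPKM+0.1), FPKM ≥ 1 filter), >10-fold vs
  2–10-fold strata, ±25-kb nearest-TSS site linkage, and STEM-style
  trajectory clustering with permutation significance.
- **Dependence.** Four-way classification of secondary-factor sites
  (cobound/solo × dependent/independent) from committed-stage co-occupancy
  and binding in a pioneer-knockout induction sample.

See `docs/methods.md` for models, assumptions, defaults, and limitations.

## Worked example

Run the numbered analysis scripts (each regenerates its synthetic inputs
deterministically from `--seed`):

```bash
python analysis/01_simulate.py          --seed 1 --outdir results/data
python analysis/02_occupancy_classes.py --seed 1 --outdir results
python analysis/04_methylation_dynamics.py --seed 1 --outdir results
```

`02_occupancy_classes.py` prints:

```
catalog: 500 sites from 500 planted
preexisting     100
gain24           98
gain72           99
gainproB        101
transient       102
unclassified      0
five-class recovery vs planted truth: 99.4%
canonical-motif fraction by class:
preexisting    0.700
gain24         0.694
gain72         0.667
gainproB       0.228
transient      0.676
```

500 planted sites (100 per class) come back as 500 catalog entries with
99.4% correct five-class labels despite 5% per-replicate peak dropout, and
the canonical-motif fraction is low (~23%) only in the late-gain cluster —
the signature of sites opened by partner factors rather than direct motif
recognition. `04_methylation_dynamics.py` prints:

```
            n_sites  delta_24h_0h  delta_72h_24h  delta_proB_72h
gain24          100        -0.006         -0.152          -0.452
persistent      100        -0.006         -0.152          -0.452
transient       100        -0.004         -0.141           0.001
persistent delta(proB - 72h) = -0.452 (planted -0.45); transient = +0.001 (planted 0)
```

Both classes lose ~0.15 methylation by 72 h, but only persistently occupied
sites show the pronounced committed-stage demethylation — occupancy and
accessibility precede methylation loss, and transient occupancy leaves the
methylome where it was.

The same stages run as one pipeline with a manifest:

```bash
tfkinetics run-all --seed 1 --outdir results/run
```

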