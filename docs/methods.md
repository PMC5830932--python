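# Methods

`tfkinetics` implements a time-resolved multi-omic analysis of
pioneer-factor-driven lineage programming: a transcription factor (the
motivating system is EBF1 switching multipotent pre-pro-B progenitors to the
committed CD19+ pro-B state) is induced at t = 0 and the cell population is
profiled at 24 h, 72 h, and the committed stage — optionally also at 6 h
under a fast Tet-on induction — with ChIP-seq for factor occupancy, ATAC-seq
for chromatin accessibility and Tn5 footprints, whole-genome bisulfite
sequencing for CpG methylation, and RNA-seq for expression. The package
provides each analysis stage as library code plus a synthetic-data module
that emulates all assays at toy-genome scale with planted ground truth, so
every stage is testable end-to-end without sequencing data.

## Temporal occupancy classes

Peak calls per time point and replicate are reduced to a unified site
catalog: peaks are pooled and merged (0-based half-open intervals; with
`merge_gap_bp = 0` only true overlaps of ≥ 1 shared base merge), and each
merged site gets a binary occupancy vector over time points. Classes:

- **persistent** — occupied at the committed stage; subclassed by the first
  occupied induced time point into `gain24`, `gain72`, `gainproB`, with
  `gain24` sites whose locus was already accessible before induction
  relabelled `preexisting`;
- **transient** — occupied at 24 and/or 72 h but absent at the committed
  stage;
- **unclassified** — never occupied at an induced or final time point
  (excluded downstream).

A 6-h column, when present, never changes these labels; persistence is
defined on the 24 h / 72 h / final grid and early occupancy is reported
separately as an overlap fraction per class.

Two replicate-combination rules are provided. `replicate_consensus`
implements the classical concordance rule (peaks of replicate 1 supported by
≥ `min_overlap_bp` shared bases in every other replicate). For the occupancy
matrix itself the default is *pooled* evidence — a site is occupied at t if
any replicate has a peak there — because occupancy subclassing reads a
temporal *pattern*: under independent per-replicate miss probability q, the
intersection rule corrupts each pattern cell with probability ≈ 2q, and at
q = 0.05 that caps five-class recovery near 85%, whereas pooled evidence
(miss ≈ q²) recovers > 99% of planted labels. `peaks.replicate_rule:
consensus` restores the intersection everywhere for users who want it.

## Accessibility clusters and signal matrices

Signal around sites is binned fragment density in ±3 kb windows (50-bp
bins), normalized as RPKM = count × 10⁹ / (bin_bp × library size). Fragments
are counted by midpoint so bins are additive and the matrix total
back-transforms exactly to the fragment count in the windows. Sites at
chromosome edges are zero-padded and flagged.

Accessibility clustering uses the mean RPKM within ±500 bp ("central
signal"). A site is accessible at t when central(t) ≥ `min_rpkm`; it is
`preexisting` when accessible at 0 h and ChIP-occupied at 24 h; otherwise it
gains at the first induced t with central(t) ≥ `gain_fold` × max(central(0 h),
floor); a site that gains by 72 h but falls back below the gain threshold at
the committed stage is `transient`. On a toy genome RPKM scales inversely
with library size, so fixed thresholds are depth-specific; the default
`min_rpkm = "auto"` estimates the background RPKM from the genome-wide
fragment rate outside site windows and sets `min_rpkm` = 5 × background with
the baseline floor equal to the background. A fixed numeric `min_rpkm` (with
a 0.25-RPKM pseudo-floor) remains available.

Central depletion — the local dip of e.g. H3K4me2 at the bound site — is
summarized per class as mean(±100 bp) / mean(shoulders at ±500–1000 bp);
ratios < 1 indicate the dip, and zero shoulders yield a flagged missing
value.

## Low-methylated regions and demethylation kinetics

Methylation input is a bismark-coverage-like TSV (chrom, 1-based position,
%methylation, coverage); rows under 5× coverage are dropped. LMRs follow the
Stadler-style convention: maximal runs of consecutive CpGs with fraction
< 0.50 and inter-CpG gaps ≤ 250 bp, kept when they contain ≥ 4 CpGs and
their mean lies in the 10–50% band. Site methylation is the
coverage-weighted mean over CpGs in ±100 bp of the site center (an
unweighted switch exists); the cloud-map table carries one row per site with
per-stage means, and the summary reports per-class median deltas between
consecutive assayed stages, with persistent subclasses also pooled.

"Associated with LMRs" is operationalized as the site center lying within an
LMR ± 100 bp, applied only when an LMR set is passed to
`methylation_dynamics`. The planted-kinetics benchmark passes no LMR set and
instead plants every site as LMR-associated: transient sites plateau at 0.65
methylation and never form a callable LMR under the 10–50% band, so an
LMR-restricted cloud would silently drop the class whose flat committed-stage
delta is the point of the comparison. The end-to-end pipeline, in contrast,
restricts by LMRs called on the final-stage methylome, which is the
realistic use.

## Tn5-protection footprints

The footprint statistic is a simplified Wellington-style score. For a
candidate interior of width w with shoulders of s bp, each strand
contributes a binomial lower-tail p-value for its interior cut count
N_fp out of N_fp + N_shoulder trials at p₀ = w/(w+s), with forward-strand
cuts tested against the upstream shoulder and reverse-strand cuts against
the downstream one; the score is −log₁₀p_fwd − log₁₀p_rev, and 0 when either
shoulder holds no cuts (no information). Calls per accessible region take
the best score over a width ladder (11–25 bp, step 2) at each position,
threshold at the (1 − FDR) quantile of per-region max scores from
within-region cut shuffles (uniform multinomial redistribution preserving
each strand's total — the exchangeable null), and resolve overlaps greedily
by score. Scores are computed via memoized log-CDF tables indexed by integer
counts, which keeps the benchmark (1000 regions × 8 widths × ~200 positions
× 21 shuffle evaluations) in seconds.

The planted benchmark plants fully parameterized footprints (interior rate
0.15 × shoulder rate) in half the regions at 30× per-base cut coverage —
coverage semantics, i.e. ~15 cuts/bp/strand in open chromatin. At sparse
per-site depths the score is information-limited: a fully protected 15-bp
footprint against 15-cut shoulders cannot exceed ≈ 4.6, below typical
per-region null maxima, so depth is the operative dial for footprint
resolution, exactly as in real digital footprinting.

Motif handling: JASPAR PWM text is parsed with Biopython; scanning is a
both-strand log-odds scan (background 0.25, floor 10⁻⁴) with overlapping
same-motif hits deduplicated by score. A motif instance is *footprinted* at
t when its midpoint falls inside a call at t; per-motif footprinted
fractions over time are compared between consecutive stages by Fisher exact
tests with Benjamini–Hochberg adjustment. Pairwise co-occurrence between two
stages counts, for each unordered motif pair, footprinted instances with a
footprinted partner within ±100 bp (200-bp regions), pooled symmetrically;
the 2×2 stage-contrast table gives a Fisher odds ratio and p-value
(Haldane–Anscombe +0.5 on zero marginals, flagged), BH-adjusted across
pairs, with an average-linkage display order on the log-odds matrix.

## Differential expression and trajectory clusters

DE is called between 0 h and the committed stage on replicate FPKM values:
log₂ fold change on replicate means with pseudocount 0.1, and a gene is DE
when |log₂FC| > log₂2, p < 0.01, and FPKM ≥ 1 in at least one of the two
states. The default test is a moderated t on log₂(FPKM + 0.1): the pooled
per-gene variance is shrunk toward the gene-wide mean with a prior weight of
4 df (limma-style). At two replicates a plain Welch t has ~2 df and needs
|t| > 9.9 for p < 0.01, which a 4-fold effect at σ = 0.25 log₂ clears less
than half the time; borrowing strength across genes is the standard remedy
and restores near-complete sensitivity while the fold-change filter keeps
false positives at zero for null genes. `moderated=False` gives the plain
Welch test. Strata: stringent > 10-fold, lenient 2–10-fold (strict
inequality — exactly 10-fold is lenient). The unchanged-gene control set is
|FC| < 1.5 with FPKM ≥ 1 at both ends.

Sites link to genes by the ±25-kb nearest-TSS rule: a site within the window
of several TSSs goes only to the nearest (ties to the lexicographically
smaller gene id), and a DE gene is *factor-regulated* when ≥ 1 site is
assigned to it. Group differences in sites-per-gene and nearest-TSS distance
(up vs unchanged, down vs unchanged) use Mann–Whitney tests, BH-adjusted.

Trajectory clustering follows the Short Time-series Expression Miner
pattern. Candidate model profiles are all integer-step trajectories starting
at 0 with per-transition steps in {−c..c} (c = 2); a greedy max–min-distance
subset is kept, each gene (log₂FC vs 0 h over induced time points, the
implicit 0-h point included) goes to the Pearson-nearest profile, profile
enrichment is tested by comparing observed member counts with their
expectation under per-gene time-order permutations (binomial upper tail,
Bonferroni across profiles), and significant profiles with trajectory
correlation ≥ 0.7 merge into display clusters. Up- and down-regulated genes
are clustered separately. On the 4-point grid the Pearson shape space has
only two effective degrees of freedom: greedy selections beyond ~6 profiles
contain pairs correlated above the 0.7 merge threshold — duplicates of the
same shape family, which buys no resolution but splits noisy genes across
near-identical profiles. The default profile count is therefore 6 (the
largest set whose members remain mutually resolvable at the planted noise
scale); longer series warrant larger counts, and the parameter is
configurable. Selection and assignment are seed-free and deterministic (ties
break lexicographically); the seed only subsamples permutations when the
exact enumeration exceeds `n_permutations`.

## Dependence of secondary-factor sites

Secondary-factor (Pax5-like) sites profiled at the committed stage are
classified by two flags: *cobound* (a pioneer-factor peak center within
±200 bp of the site center) and *bound-without-pioneer* (overlap with a peak
from the secondary factor induced in pioneer-knockout progenitors);
*dependent* = not bound without the pioneer. The four labels
cobound/solo × dependent/independent exhaust the flag space. Accessibility
flags before induction and at the committed stage come from central RPKM
thresholds, and a Fisher test compares dependent vs independent
pre-accessibility. Dependence is peak-presence-based to mirror the four-way
heat-map grouping; a signal-ratio variant is left to configuration.

## Synthetic data: what is emulated, and what is not

The generator lays a toy genome (default 1 chromosome × 2 Mb, 200 genes,
500 sites placed on a jittered grid so neighbours never merge) and plants,
per site: a temporal class (exact requested proportions via
largest-remainder apportionment), a canonical-motif flag (~70% in most
classes, ~22% in the late-gain class), LMR association, a footprint width
(11–25 bp), a demethylation profile (persistent 0.8→0.8→0.65→0.2; transient
flat at 0.65 after 72 h; pre-accessible sites lowly methylated throughout),
a 6-h occupancy flag (44% persistent, 57% transient), and a linked gene that
inherits a class-matched expression template (early jump U1-like, gradual
U3-like, late U4/U5-like, transient-up-then-repressed D4-like). Boolean
flags are planted at exact per-class counts rather than Bernoulli draws so
that planted fractions are recoverable without sampling variance — the
generator defines conditions, it does not add avoidable noise to them.
ATAC peak sets additionally include standalone open-chromatin peaks placed
clear of sites, in exact numbers per first-accessible cluster so the
site-containing fraction of each cluster matches the planted values (0.9 at
24 h declining to 0.42 at the committed stage).

Noise model: per-replicate Bernoulli peak dropout (default 0.05), 200–400-bp
peak widths with ≤ 50 bp jitter, Poisson background cuts (0.5/kb/strand)
with shoulder-rate pile-ups and 0.15× protected interiors at accessible
sites, beta-binomial CpG methylation at Poisson ~30× coverage (CpG spacing
~25 bp near LMR-associated sites, ~100 bp elsewhere), and lognormal
replicate noise (σ = 0.25 log₂) on expression. All generators are
deterministic in (genome seed, noise seed, stage offset).

Not emulated: read-level sequencing (mappability, GC and Tn5 sequence bias),
fragment-length structure, graded transient occupancy (transience is
complete peak absence at the committed stage), biological covariance between
assays beyond the planted class structure, and replicate batch effects.
Passing tests therefore demonstrate that the analysis recovers what it is
meant to measure under its own stated noise model — not robustness to the
artefacts of real sequencing data.

## Numerical choices and degenerate inputs

Intervals are 0-based half-open everywhere except the methylation TSV
boundary (1-based). Empty signal tracks produce all-zero matrices with a
warning; zero shoulder signal yields a missing depletion ratio with a
warning; an empty secondary-site universe returns an empty classification
with a warning. Binomial CDFs are evaluated in log space; score ties in
footprint resolution break by position; STEM tie-breaks are lexicographic.
The pipeline's master seed fans out to per-stage seeds by fixed offsets, and
the run manifest records config, seeds, row counts, and SHA-256 checksums of
every output; re-running with the same seed is byte-identical.

## Problem sizes

Default scales are chosen for seconds-scale runs with stable statistics: 500
sites / 2 Mb for classification, 200 sites for methylation kinetics, 500
true + 500 null regions for footprinting, 500-gene tables (10 repeats) for
DE, 500 genes for trajectory recovery, 400 secondary sites for dependence.
The full synthetic pipeline runs in ~10 s; `scripts/acceptance.py`
recomputes every benchmark in under a minute.

## Known limitations

The enrichment peak caller is a minimal Poisson scanner meant only to close
the loop on synthetic coverage; real analyses should supply MACS2-style
narrowPeak files. The footprint score uses a single shoulder span and no
Tn5 sequence-bias correction. The co-occurrence contrast is a transparent
Fisher enrichment between two stages, not a reimplementation of any
particular published clustering tool. Headline counts from the motivating
study (thousands of sites, tens of thousands of footprints) depend on real
sequencing depth and are out of scope at toy-genome scale.
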