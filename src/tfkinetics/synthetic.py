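"""Toy-genome multi-omic time-course simulator with planted ground truth.

Emulates the assays of an induced-pioneer-factor programming experiment on a
small genome: per-time-point/replicate ChIP peak calls, strand-specific Tn5
cut-count tracks with planted footprints, a CpG methylome with planted
demethylation kinetics, and an FPKM expression table with planted trajectory
clusters. Every planted property (temporal class, canonical-motif flag, LMR
association, footprint width, methylation profile, expression template) is
recorded per site/gene so downstream stages can be scored against truth.

Time grid: 0 h (uninduced), 24 h, 72 h, committed pro-B stage; an optional
6 h point models a fast Tet-on induction and is emitted only when requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, write_bed, write_bedgraph
from .peaks import TEMPORAL_CLASSES

__all__ = [
    "SyntheticGenome",
    "PlantedSite",
    "NoiseModel",
    "generate_genome",
    "generate_timecourse_peaks",
    "generate_cut_counts",
    "generate_methylome",
    "generate_expression",
    "TIMEPOINTS",
    "CLASS_OCCUPANCY",
    "CLASS_ACCESSIBILITY",
    "METH_PROFILES",
    "EXPRESSION_TEMPLATES",
]


class ConfigurationError(ValueError):
    pass


#: canonical core time grid (6 h is optional and inserted after 0 h on request)
TIMEPOINTS = ("0h", "24h", "72h", "proB")
INDUCED = ("24h", "72h", "proB")

#: ChIP peak presence per temporal class. The pioneer factor is absent before
#: induction, so even "preexisting" (pre-accessible) sites have no 0 h peak.
CLASS_OCCUPANCY: dict[str, tuple[str, ...]] = {
    "preexisting": ("24h", "72h", "proB"),
    "gain24": ("24h", "72h", "proB"),
    "gain72": ("72h", "proB"),
    "gainproB": ("proB",),
    "transient": ("24h", "72h"),
}

#: chromatin accessibility per class; pre-existing sites are open throughout.
CLASS_ACCESSIBILITY: dict[str, tuple[str, ...]] = {
    "preexisting": ("0h", "6h", "24h", "72h", "proB"),
    "gain24": ("24h", "72h", "proB"),
    "gain72": ("72h", "proB"),
    "gainproB": ("proB",),
    "transient": ("24h", "72h"),
}

#: probability that a site is already ChIP-occupied at 6 h in the fast
#: induction system (persistent ~44%, transient ~57%).
EARLY_OCCUPANCY_PROB: dict[str, float] = {
    "preexisting": 0.44,
    "gain24": 0.44,
    "gain72": 0.44,
    "gainproB": 0.44,
    "transient": 0.57,
}

#: per-time-point target methylation fraction (0 h, 24 h, 72 h, pro-B).
#: Persistent sites: modest loss at 72 h, pronounced loss at pro-B;
#: transient sites: no further loss after 72 h; pre-accessible sites are
#: already lowly methylated.
METH_PROFILES: dict[str, tuple[float, ...]] = {
    "preexisting": (0.15, 0.15, 0.15, 0.15),
    "gain24": (0.8, 0.8, 0.65, 0.2),
    "gain72": (0.8, 0.8, 0.65, 0.2),
    "gainproB": (0.8, 0.8, 0.65, 0.2),
    "transient": (0.8, 0.8, 0.65, 0.65),
}

#: fraction of ATAC peaks in each first-accessible cluster that contain a
#: binding site: high in the early clusters (~90%), declining to ~42% in the
#: committed-stage cluster, where other factors shape the open chromatin.
ATAC_SITE_FRACTION: dict[str, float] = {
    "0h": 0.60,
    "6h": 0.60,
    "24h": 0.90,
    "72h": 0.70,
    "proB": 0.42,
}

#: probability a site carries a canonical recognition motif: low in the
#: late-gain cluster (~22%), high elsewhere (~67-71%).
MOTIF_PROB: dict[str, float] = {
    "preexisting": 0.70,
    "gain24": 0.70,
    "gain72": 0.67,
    "gainproB": 0.22,
    "transient": 0.67,
}

#: log2 fold change vs 0 h at (24 h, 72 h, pro-B). U1: early jump then
#: plateau; U3: gradual rise; U4: late activation from 72 h; U5: pro-B-only
#: activation; D4: transient up-regulation before sharp pro-B repression.
EXPRESSION_TEMPLATES: dict[str, tuple[float, ...]] = {
    "U1": (4.0, 4.0, 4.5),
    "U3": (1.5, 2.5, 3.5),
    "U4": (0.0, 1.5, 3.5),
    "U5": (0.0, 0.0, 3.5),
    "D4": (1.5, 1.5, -3.3),
}

#: which trajectory template a site-linked gene inherits, by site class.
CLASS_TEMPLATE: dict[str, str] = {
    "preexisting": "U3",
    "gain24": "U1",
    "gain72": "U4",
    "gainproB": "U5",
    "transient": "D4",
}


@dataclass
class PlantedSite:
    site_id: str
    chrom: str
    center: int
    true_class: str
    has_canonical_motif: bool
    lmr_associated: bool
    footprint_width: int  # bp; 0 means no planted footprint
    demethylation_profile: tuple[float, ...]  # over TIMEPOINTS
    linked_gene_id: str | None = None
    occupied_6h: bool = False

    def __post_init__(self):
        if self.true_class not in TEMPORAL_CLASSES:
            raise ConfigurationError(f"unknown temporal class {self.true_class!r}")
        if any(not (0.0 <= m <= 1.0) for m in self.demethylation_profile):
            raise ConfigurationError("demethylation profile values must lie in [0, 1]")


@dataclass
class NoiseModel:
    """Noise settings shared across the generators.

    peak_dropout_prob: per-replicate probability a planted peak is missed.
    signal_depth: mean Tn5 cuts per strand landing in one site's shoulders.
    background_rate: background cuts per kb per strand.
    meth_coverage: mean reads per CpG.
    expr_dispersion: replicate sd of log2 expression.
    """

    peak_dropout_prob: float = 0.05
    signal_depth: float = 30.0
    background_rate: float = 0.5
    meth_coverage: float = 30.0
    expr_dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.peak_dropout_prob <= 1.0:
            raise ConfigurationError("peak_dropout_prob must lie in [0, 1]")
        for name in ("signal_depth", "background_rate", "meth_coverage", "expr_dispersion"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")


@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    genes: list[tuple[str, str, str, int, int]]  # (gene_id, chrom, strand, TSS, length)
    sites: list[PlantedSite]
    seed: int

    def __post_init__(self):
        gene_ids = [g[0] for g in self.genes]
        site_ids = [s.site_id for s in self.sites]
        if len(set(gene_ids)) != len(gene_ids):
            raise ConfigurationError("gene_ids must be unique")
        if len(set(site_ids)) != len(site_ids):
            raise ConfigurationError("site_ids must be unique")
        for gid, chrom, _, tss, _ in self.genes:
            if not 0 <= tss < self.chrom_sizes[chrom]:
                raise ConfigurationError(f"gene {gid} TSS outside chromosome bounds")
        for s in self.sites:
            if not 0 <= s.center < self.chrom_sizes[s.chrom]:
                raise ConfigurationError(f"site {s.site_id} outside chromosome bounds")

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_id": s.site_id,
                    "chrom": s.chrom,
                    "center": s.center,
                    "true_class": s.true_class,
                    "has_canonical_motif": s.has_canonical_motif,
                    "lmr_associated": s.lmr_associated,
                    "footprint_width": s.footprint_width,
                    "linked_gene_id": s.linked_gene_id,
                    "occupied_6h": s.occupied_6h,
                }
                for s in self.sites
            ]
        )

    def write_truth(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "chrom_sizes": self.chrom_sizes,
            "seed": self.seed,
            "sites": self.truth_frame().to_dict(orient="records"),
            "genes": [
                {"gene_id": g, "chrom": c, "strand": s, "tss": t, "length": ln}
                for g, c, s, t, ln in self.genes
            ],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))

    def write_gtf(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for gid, chrom, strand, tss, length in self.genes:
                start = tss if strand == "+" else tss - length + 1
                end = tss + length - 1 if strand == "+" else tss
                fh.write(
                    f"{chrom}\tsynthetic\tgene\t{start + 1}\t{end + 1}\t.\t{strand}\t.\t"
                    f'gene_id "{gid}";\n'
                )


def _rng(genome_seed: int, noise_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([genome_seed, noise_seed, stage])


def _stratified_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment so requested class proportions are exact."""
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"class proportions sum to {total}, not 1")
    raw = {c: n * p for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: (counts[c] - raw[c], c))[:short]:
        counts[c] += 1
    return counts


def generate_genome(
    n_chroms: int = 1,
    chrom_len: int = 2_000_000,
    n_genes: int = 200,
    n_sites: int = 500,
    class_proportions: Mapping[str, float] | None = None,
    seed: int = 0,
    lmr_prob: float = 0.6,
    motif_prob: Mapping[str, float] | None = None,
    link_window_bp: int = 25_000,
) -> SyntheticGenome:
    """Lay out a toy genome with planted binding sites and genes.

    Sites are placed on a jittered grid (so neighbouring sites never merge at
    default peak widths) and assigned temporal classes in the exact requested
    proportions by stratified largest-remainder apportionment. Each site is
    linked to the nearest gene TSS within ``link_window_bp``, if any.
    """
    if n_sites < 5:
        raise ConfigurationError("need n_sites >= 5 (one per temporal class)")
    if class_proportions is None:
        class_proportions = {c: 1.0 / len(TEMPORAL_CLASSES) for c in TEMPORAL_CLASSES}
    unknown = set(class_proportions) - set(TEMPORAL_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown classes in proportions: {sorted(unknown)}")
    motif_prob = dict(MOTIF_PROB, **(motif_prob or {}))
    rng = np.random.default_rng(seed)

    chrom_sizes = {f"chr{i + 1}": int(chrom_len) for i in range(n_chroms)}
    chroms = list(chrom_sizes)

    # class labels, exact proportions, shuffled across placements
    counts = _stratified_counts(n_sites, class_proportions)
    labels = [c for c in TEMPORAL_CLASSES for _ in range(counts.get(c, 0))]
    labels = [labels[i] for i in rng.permutation(n_sites)]

    # jittered-grid site centers, round-robin over chromosomes
    margin = 5_000
    per_chrom = [n_sites // n_chroms + (1 if i < n_sites % n_chroms else 0) for i in range(n_chroms)]
    centers: list[tuple[str, int]] = []
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        slot = (chrom_len - 2 * margin) / k
        jitter = rng.integers(-int(slot * 0.2), int(slot * 0.2) + 1, size=k)
        pos = (margin + (np.arange(k) + 0.5) * slot + jitter).astype(int)
        centers.extend((chrom, int(p)) for p in pos)

    # genes on their own jittered grid
    genes: list[tuple[str, str, str, int, int]] = []
    per_chrom_g = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    gi = 0
    for ci, chrom in enumerate(chroms):
        k = per_chrom_g[ci]
        if k == 0:
            continue
        slot = (chrom_len - 2 * margin) / k
        jitter = rng.integers(-int(slot * 0.2), int(slot * 0.2) + 1, size=k)
        tss = (margin + (np.arange(k) + 0.5) * slot + jitter).astype(int)
        strands = rng.choice(["+", "-"], size=k)
        lengths = rng.integers(2_000, 10_001, size=k)
        for p, st, ln in zip(tss, strands, lengths):
            genes.append((f"gene_{gi:04d}", chrom, str(st), int(p), int(ln)))
            gi += 1

    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in chroms:
        sub = [(t, g) for g, c, _, t, _ in genes if c == chrom]
        sub.sort()
        tss_by_chrom[chrom] = (np.array([t for t, _ in sub]), [g for _, g in sub])

    # per-class boolean flags planted at exact counts (round(p * n_class)) so
    # planted fractions are recoverable without Bernoulli sampling variance
    def exact_flags(idxs: np.ndarray, p: float) -> np.ndarray:
        flags = np.zeros(n_sites, dtype=bool)
        k = int(round(p * idxs.size))
        flags[rng.permutation(idxs)[:k]] = True
        return flags

    label_arr = np.array(labels)
    motif_flags = np.zeros(n_sites, dtype=bool)
    lmr_flags = np.zeros(n_sites, dtype=bool)
    early_flags = np.zeros(n_sites, dtype=bool)
    for cls in TEMPORAL_CLASSES:
        idxs = np.flatnonzero(label_arr == cls)
        if idxs.size == 0:
            continue
        motif_flags |= exact_flags(idxs, motif_prob[cls])
        lmr_flags |= exact_flags(idxs, lmr_prob)
        early_flags |= exact_flags(idxs, EARLY_OCCUPANCY_PROB[cls])

    sites: list[PlantedSite] = []
    for i, ((chrom, center), cls) in enumerate(zip(centers, labels)):
        tss_arr, gids = tss_by_chrom[chrom]
        linked = None
        if tss_arr.size:
            j = int(np.argmin(np.abs(tss_arr - center)))
            if abs(int(tss_arr[j]) - center) <= link_window_bp:
                linked = gids[j]
        sites.append(
            PlantedSite(
                site_id=f"true_{i:05d}",
                chrom=chrom,
                center=center,
                true_class=cls,
                has_canonical_motif=bool(motif_flags[i]),
                lmr_associated=bool(lmr_flags[i]),
                footprint_width=int(rng.choice(np.arange(11, 26, 2))),
                demethylation_profile=METH_PROFILES[cls],
                linked_gene_id=linked,
                occupied_6h=bool(early_flags[i]),
            )
        )
    return SyntheticGenome(chrom_sizes=chrom_sizes, genes=genes, sites=sites, seed=int(seed))


def _site_present(site: PlantedSite, timepoint: str, assay: str) -> bool:
    if assay == "chip":
        if timepoint == "6h":
            return site.occupied_6h
        return timepoint in CLASS_OCCUPANCY[site.true_class]
    if assay == "atac":
        return timepoint in CLASS_ACCESSIBILITY[site.true_class]
    raise ConfigurationError(f"unknown assay {assay!r}")


def generate_timecourse_peaks(
    genome: SyntheticGenome,
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS,
    n_replicates: int = 2,
    assay: str = "chip",
    atac_site_fraction: Mapping[str, float] | None = None,
) -> dict[tuple[str, str], list[GenomicInterval]]:
    """Per-(timepoint, replicate) peak calls for a ChIP or ATAC assay.

    Each planted site emits a peak at exactly the time points its true class
    dictates, minus independent Bernoulli(dropout) losses per replicate. Peaks
    are 200-400 bp wide, centered on the site with <= 50 bp jitter.

    The ATAC assay additionally emits standalone open-chromatin peaks (away
    from any binding site, persisting from their first stage onward) in exact
    numbers such that the site-containing fraction of each first-accessible
    peak cluster equals ``atac_site_fraction`` (default
    :data:`ATAC_SITE_FRACTION`).
    """
    if n_replicates < 1:
        raise ConfigurationError("need n_replicates >= 1")
    rng = _rng(genome.seed, noise.seed, 1 if assay == "chip" else 2)
    out: dict[tuple[str, str], list[GenomicInterval]] = {
        (tp, f"rep{r + 1}"): [] for tp in timepoints for r in range(n_replicates)
    }
    for site in genome.sites:
        for tp in timepoints:
            present = _site_present(site, tp, assay)
            for r in range(n_replicates):
                # draw consistently so the random stream is independent of presence
                width = int(rng.integers(200, 401))
                jitter = int(rng.integers(-50, 51))
                drop = rng.random() < noise.peak_dropout_prob
                if not present or drop:
                    continue
                center = site.center + jitter
                start = max(0, center - width // 2)
                out[(tp, f"rep{r + 1}")].append(
                    GenomicInterval(
                        site.chrom, start, start + width,
                        name=f"{assay}_{site.site_id}_{tp}_rep{r + 1}",
                    )
                )

    if assay == "atac":
        fracs = dict(ATAC_SITE_FRACTION, **(atac_site_fraction or {}))
        site_centers = {
            chrom: np.sort(np.array([s.center for s in genome.sites
                                     if s.chrom == chrom]))
            for chrom in genome.chrom_sizes
        }
        chroms = list(genome.chrom_sizes)

        placed: dict[str, list[int]] = {chrom: [] for chrom in chroms}

        def clear_position(chrom, pos, margin=700):
            # clear of binding sites and of previously placed open peaks so
            # standalone peaks neither contain a site nor merge together
            arr = site_centers[chrom]
            j = np.searchsorted(arr, pos)
            near = [arr[k] for k in (j - 1, j) if 0 <= k < arr.size]
            if any(abs(pos - c) <= margin for c in near):
                return False
            return all(abs(pos - c) > margin for c in placed[chrom])

        for ti, tp in enumerate(timepoints):
            n_first = sum(
                1 for s in genome.sites
                if _site_present(s, tp, "atac")
                and not any(_site_present(s, t2, "atac") for t2 in timepoints[:ti])
            )
            f = fracs.get(tp, 1.0)
            n_extra = int(round(n_first * (1.0 - f) / f)) if f > 0 else 0
            for k in range(n_extra):
                while True:
                    chrom = chroms[int(rng.integers(len(chroms)))]
                    pos = int(rng.integers(5_000, genome.chrom_sizes[chrom] - 5_000))
                    if clear_position(chrom, pos):
                        break
                placed[chrom].append(pos)
                for tp2 in timepoints[ti:]:
                    for r in range(n_replicates):
                        width = int(rng.integers(200, 401))
                        jitter = int(rng.integers(-50, 51))
                        if rng.random() < noise.peak_dropout_prob:
                            continue
                        start = max(0, pos + jitter - width // 2)
                        out[(tp2, f"rep{r + 1}")].append(
                            GenomicInterval(
                                chrom, start, start + width,
                                name=f"atac_open_{tp}_{k:04d}_{tp2}_rep{r + 1}",
                            )
                        )
    return out


def generate_cut_counts(
    genome: SyntheticGenome,
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS,
    shoulder_bp: int = 35,
    protection: float = 0.15,
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Strand-specific per-base Tn5 cut counts per time point.

    Background cuts are Poisson at ``background_rate`` per kb per strand.
    At a site accessible at t, shoulders of ``shoulder_bp`` on each side of the
    footprint carry an elevated per-base rate r_s = signal_depth / (2 *
    shoulder_bp) (at least 5x background) while the footprint interior is
    depleted to ``protection`` x r_s. Sites without a planted footprint get the
    shoulder rate across the whole span.

    Returns {timepoint: {chrom: (fwd, rev)}} with int32 arrays.
    """
    if protection > 0.2:
        raise ConfigurationError("protection must be <= 0.2 (interior vs shoulder)")
    rng = _rng(genome.seed, noise.seed, 3)
    bg = noise.background_rate / 1000.0
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for tp in timepoints:
        tracks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, size in genome.chrom_sizes.items():
            fwd = rng.poisson(bg, size=size).astype(np.int32)
            rev = rng.poisson(bg, size=size).astype(np.int32)
            tracks[chrom] = (fwd, rev)
        for site in genome.sites:
            if not _site_present(site, tp, "atac"):
                continue
            fwd, rev = tracks[site.chrom]
            w = site.footprint_width
            r_s = max(noise.signal_depth / (2 * shoulder_bp), 5 * bg)
            half = w // 2
            lo = site.center - half - shoulder_bp
            hi = site.center + half + 1 + shoulder_bp
            if lo < 0 or hi > genome.chrom_sizes[site.chrom]:
                continue
            span = hi - lo
            rates = np.full(span, r_s)
            if w > 0:
                rates[shoulder_bp: shoulder_bp + w] = protection * r_s
            fwd[lo:hi] += rng.poisson(rates).astype(np.int32)
            rev[lo:hi] += rng.poisson(rates).astype(np.int32)
        out[tp] = tracks
    return out


def generate_methylome(
    genome: SyntheticGenome,
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS,
    cpg_spacing_lmr: int = 25,
    cpg_spacing_bg: int = 100,
    lmr_halfwidth: int = 150,
    concentration: float = 60.0,
):
    """Per-time-point CpG methylation tracks with planted demethylation kinetics.

    CpGs are laid down with mean spacing ``cpg_spacing_bg`` genome-wide and
    ``cpg_spacing_lmr`` within +/- ``lmr_halfwidth`` of LMR-associated sites.
    Per CpG and time point, the observed fraction is Binomial(coverage, m')
    where m' ~ Beta around the site's planted profile value (background CpGs
    sit at 85-95% methylation, constant over time).

    Returns {timepoint: MethylationTrack} (1-based positions).
    """
    from .methylation import MethylationTrack

    if cpg_spacing_lmr <= 0 or cpg_spacing_bg <= 0:
        raise ConfigurationError("CpG spacing must be positive")
    rng = _rng(genome.seed, noise.seed, 4)
    tp_index = {tp: TIMEPOINTS.index(tp) for tp in timepoints if tp != "6h"}

    positions: dict[str, np.ndarray] = {}
    base_level: dict[str, np.ndarray] = {}
    site_target: dict[str, dict[int, PlantedSite]] = {}
    for chrom, size in genome.chrom_sizes.items():
        gaps = rng.exponential(cpg_spacing_bg, size=int(2.0 * size / cpg_spacing_bg))
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[(pos >= 1) & (pos <= size)]
        extra = []
        for site in genome.sites:
            if site.chrom != chrom or not site.lmr_associated:
                continue
            n_cpg = max(4, int(2 * lmr_halfwidth / cpg_spacing_lmr))
            offs = np.sort(rng.integers(-lmr_halfwidth, lmr_halfwidth + 1, size=n_cpg))
            extra.append(site.center + 1 + offs)
        if extra:
            pos = np.unique(np.concatenate([pos] + extra))
        positions[chrom] = pos
        base_level[chrom] = rng.uniform(0.85, 0.95, size=pos.size)
        site_target[chrom] = {}

    # map CpGs near LMR-associated sites to the site's planted profile
    target_idx: dict[str, np.ndarray] = {}
    for chrom, pos in positions.items():
        owner = np.full(pos.size, -1, dtype=np.int64)
        for si, site in enumerate(genome.sites):
            if site.chrom != chrom or not site.lmr_associated:
                continue
            lo = np.searchsorted(pos, site.center + 1 - lmr_halfwidth)
            hi = np.searchsorted(pos, site.center + 1 + lmr_halfwidth, side="right")
            owner[lo:hi] = si
        target_idx[chrom] = owner

    out = {}
    for tp in timepoints:
        if tp == "6h":  # methylome not assayed in the fast-induction arm
            continue
        ti = tp_index[tp]
        tracks = {}
        for chrom, pos in positions.items():
            target = base_level[chrom].copy()
            owner = target_idx[chrom]
            planted = owner >= 0
            if planted.any():
                prof = np.array(
                    [genome.sites[si].demethylation_profile[ti] for si in owner[planted]]
                )
                target[planted] = prof
            target = np.clip(target, 1e-3, 1 - 1e-3)
            m_true = rng.beta(target * concentration, (1 - target) * concentration)
            cov = rng.poisson(noise.meth_coverage, size=pos.size)
            keep = cov > 0
            meth = rng.binomial(cov[keep], m_true[keep])
            tracks[chrom] = (pos[keep], meth / cov[keep], cov[keep])
        out[tp] = MethylationTrack(
            {c: (p.astype(np.int64), f.astype(float), cv.astype(np.int64))
             for c, (p, f, cv) in tracks.items()}
        )
    return out


def generate_expression(
    genome: SyntheticGenome,
    noise: NoiseModel,
    timepoints: Sequence[str] = TIMEPOINTS,
    n_replicates: int = 2,
    cluster_templates: Mapping[str, Sequence[float]] | None = None,
    low_expr_frac: float = 0.1,
    baseline_log2_mean: float = 3.0,
    baseline_log2_sd: float = 1.0,
):
    """FPKM expression table with planted trajectory templates.

    Genes linked to planted sites inherit the template matching the site's
    temporal class; unlinked genes are flat. A ``low_expr_frac`` fraction of
    unlinked genes is planted at FPKM < 1 at both ends to exercise the
    low-expression filter. Replicate noise is lognormal with sd
    ``noise.expr_dispersion`` in log2 units.

    Returns an :class:`~tfkinetics.expression.ExpressionTable`; the planted
    template per gene is in ``table.truth['template']``.
    """
    from .expression import ExpressionTable

    core_tps = [tp for tp in timepoints if tp != "6h"]
    induced = [tp for tp in core_tps if tp != "0h"]
    templates = {k: tuple(v) for k, v in (cluster_templates or EXPRESSION_TEMPLATES).items()}
    for name, vec in templates.items():
        if len(vec) != len(induced):
            raise ConfigurationError(
                f"template {name!r} has {len(vec)} values for {len(induced)} induced time points"
            )
    rng = _rng(genome.seed, noise.seed, 5)

    gene_template: dict[str, str | None] = {g[0]: None for g in genome.genes}
    for site in genome.sites:
        if site.linked_gene_id is not None:
            name = CLASS_TEMPLATE[site.true_class]
            if name in templates and gene_template[site.linked_gene_id] is None:
                gene_template[site.linked_gene_id] = name

    samples = [(tp, f"rep{r + 1}") for tp in core_tps for r in range(n_replicates)]
    values = np.zeros((len(genome.genes), len(samples)))
    truth_rows = []
    for gi, (gid, chrom, strand, tss, length) in enumerate(genome.genes):
        tmpl_name = gene_template[gid]
        baseline = 2.0 ** rng.normal(baseline_log2_mean, baseline_log2_sd)
        low = tmpl_name is None and rng.random() < low_expr_frac
        if low:
            baseline = float(rng.uniform(0.05, 0.5))
        lfc = {tp: 0.0 for tp in core_tps}
        if tmpl_name is not None:
            for tp, v in zip(induced, templates[tmpl_name]):
                lfc[tp] = float(v)
        for sj, (tp, rep) in enumerate(samples):
            eps = rng.normal(0.0, noise.expr_dispersion)
            values[gi, sj] = baseline * 2.0 ** (lfc[tp] + eps)
        truth_rows.append(
            {"gene_id": gid, "template": tmpl_name, "baseline_fpkm": baseline,
             "planted_low": low}
        )

    frame = pd.DataFrame(values, index=[g[0] for g in genome.genes],
                         columns=[f"{tp}_{rep}" for tp, rep in samples])
    meta = pd.DataFrame(
        {"sample": frame.columns,
         "timepoint": [tp for tp, _ in samples],
         "replicate": [rep for _, rep in samples]}
    ).set_index("sample")
    coords = pd.DataFrame(
        {"gene_id": [g[0] for g in genome.genes],
         "chrom": [g[1] for g in genome.genes],
         "strand": [g[2] for g in genome.genes],
         "tss": [g[3] for g in genome.genes]}
    ).set_index("gene_id")
    table = ExpressionTable(values=frame, samples=meta, gene_coords=coords)
    table.truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return table


def generate_dependency_scenario(
    genome: SyntheticGenome,
    noise: NoiseModel,
    n_secondary: int = 400,
    cobound_frac: float = 0.5,
    dependent_frac_cobound: float = 0.5,
    independent_frac_solo: float = 0.9,
    preaccessible_frac_independent: float = 0.9,
    cooccupancy_window_bp: int = 200,
    open_rpkm: float = 20.0,
    closed_rpkm: float = 0.5,
) -> dict:
    """Plant a secondary-factor (Pax5-like) dependence scenario.

    Secondary-factor committed-stage sites are placed either next to a
    persistent pioneer site (cobound, within half the co-occupancy window) or
    at standalone positions. A planted fraction of cobound sites is bound in
    the pioneer-knockout induction sample (independent); dependent sites are
    planted inaccessible before induction and accessible at the committed
    stage, independent sites pre-accessible with probability
    ``preaccessible_frac_independent``.

    Returns dict with keys: secondary_sites, knockout_peaks, pioneer_peaks,
    rpkm_0h, rpkm_final (pd.Series by site id), truth (DataFrame).
    """
    rng = _rng(genome.seed, noise.seed, 6)
    persistent = [s for s in genome.sites
                  if "proB" in CLASS_OCCUPANCY[s.true_class]]
    n_cobound = int(round(n_secondary * cobound_frac))
    n_solo = n_secondary - n_cobound
    chroms = list(genome.chrom_sizes)

    pioneer_peaks = []
    for s in persistent:
        half = int(rng.integers(100, 201))
        pioneer_peaks.append(
            GenomicInterval(s.chrom, max(0, s.center - half), s.center + half,
                            name=f"pioneer_{s.site_id}")
        )

    # dependence planted at exact counts within the cobound stratum so the
    # planted fraction is recoverable without Bernoulli sampling variance
    n_dep_cobound = int(round(n_cobound * dependent_frac_cobound))
    cobound_dependent = np.zeros(n_cobound, dtype=bool)
    cobound_dependent[rng.permutation(n_cobound)[:n_dep_cobound]] = True

    pioneer_by_chrom: dict[str, np.ndarray] = {}
    for p in persistent:
        pioneer_by_chrom.setdefault(p.chrom, []).append(p.center)
    pioneer_by_chrom = {c: np.sort(np.array(v)) for c, v in pioneer_by_chrom.items()}

    def clear_of_pioneers(chrom: str, center: int, margin: int) -> bool:
        arr = pioneer_by_chrom.get(chrom)
        if arr is None:
            return True
        j = np.searchsorted(arr, center)
        near = [arr[k] for k in (j - 1, j) if 0 <= k < arr.size]
        return all(abs(center - c) > margin for c in near)

    records = []
    anchor_idx = rng.choice(len(persistent), size=n_cobound,
                            replace=n_cobound > len(persistent))
    for i in range(n_secondary):
        if i < n_cobound:
            anchor = persistent[int(anchor_idx[i])]
            offset = int(rng.integers(-cooccupancy_window_bp // 2,
                                      cooccupancy_window_bp // 2 + 1))
            chrom, center = anchor.chrom, anchor.center + offset
            cobound = True
            independent = not bool(cobound_dependent[i])
        else:
            # solo means not co-localized: keep well clear of any pioneer site
            while True:
                chrom = chroms[int(rng.integers(len(chroms)))]
                center = int(rng.integers(5_000, genome.chrom_sizes[chrom] - 5_000))
                if clear_of_pioneers(chrom, center, 2 * cooccupancy_window_bp):
                    break
            cobound = False
            independent = bool(rng.random() < independent_frac_solo)
        records.append(
            {"site_id": f"sec_{i:05d}", "chrom": chrom, "center": center,
             "cobound": cobound, "independent": independent,
             "accessible_pre": False}
        )

    # pre-induction accessibility planted at exact counts within each
    # independent stratum; dependent sites stay closed before induction
    for group in (True, False):  # cobound, solo
        idxs = [i for i, r in enumerate(records)
                if r["independent"] and r["cobound"] == group]
        k = int(round(preaccessible_frac_independent * len(idxs)))
        for j in rng.permutation(len(idxs))[:k]:
            records[idxs[j]]["accessible_pre"] = True

    secondary_sites, knockout_peaks = [], []
    rpkm_0h, rpkm_final = {}, {}
    for r in records:
        half = int(rng.integers(100, 201))
        iv = GenomicInterval(r["chrom"], max(0, r["center"] - half),
                             r["center"] + half, name=r["site_id"])
        secondary_sites.append(iv)
        if r["independent"]:
            jitter = int(rng.integers(-50, 51))
            knockout_peaks.append(
                GenomicInterval(r["chrom"], max(0, r["center"] + jitter - half),
                                r["center"] + jitter + half,
                                name=f"ko_{r['site_id']}")
            )
        mean0 = open_rpkm if r["accessible_pre"] else closed_rpkm
        rpkm_0h[r["site_id"]] = float(mean0 * 2.0 ** rng.normal(0.0, 0.2))
        rpkm_final[r["site_id"]] = float(open_rpkm * 2.0 ** rng.normal(0.0, 0.2))

    truth = pd.DataFrame(records).set_index("site_id")
    return {
        "secondary_sites": secondary_sites,
        "knockout_peaks": knockout_peaks,
        "pioneer_peaks": pioneer_peaks,
        "rpkm_0h": pd.Series(rpkm_0h),
        "rpkm_final": pd.Series(rpkm_final),
        "truth": truth,
    }


def write_peak_files(peak_sets: Mapping[tuple[str, str], list], outdir) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    for (tp, rep), peaks in peak_sets.items():
        p = outdir / f"peaks_{tp}_{rep}.bed"
        write_bed(peaks, p)
        paths.append(p)
    return paths


def write_cut_tracks(cut_tracks: Mapping[str, Mapping[str, tuple]], outdir) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    for tp, per_chrom in cut_tracks.items():
        for strand, k in (("fwd", 0), ("rev", 1)):
            p = outdir / f"cuts_{tp}_{strand}.bedGraph"
            write_bedgraph({c: arrs[k] for c, arrs in per_chrom.items()}, p)
            paths.append(p)
    return paths
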