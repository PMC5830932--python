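"""CpG methylation tracks, low-methylated-region (LMR) calling, and
site-anchored demethylation dynamics.

The central analysis: for binding sites associated with LMRs, compare the mean
CpG methylation in a +/-100 bp window around each site center across the time
course. Persistently occupied sites are expected to lose methylation markedly
by the committed stage, transiently occupied sites to show no further loss
after 72 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, write_bed
from .peaks import PERSISTENT_CLASSES, SiteCatalog

__all__ = [
    "MethylationTrack",
    "LMRSet",
    "read_methylation",
    "write_methylation",
    "call_lmrs",
    "site_methylation",
    "methylation_dynamics",
]


@dataclass
class MethylationTrack:
    """Per-chromosome CpG arrays: (1-based position, fraction in [0,1], coverage)."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self):
        for chrom, (pos, frac, cov) in self.data.items():
            if not (len(pos) == len(frac) == len(cov)):
                raise ValueError(f"{chrom}: ragged arrays")
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if len(frac) and (frac.min() < 0 or frac.max() > 1):
                raise ValueError(f"{chrom}: fractions must lie in [0, 1]")

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def n_cpgs(self) -> int:
        return sum(len(p) for p, _, _ in self.data.values())

    def window(self, chrom: str, start_1based: int, end_1based: int):
        """CpGs with start <= pos <= end (inclusive, 1-based)."""
        if chrom not in self.data:
            return (np.array([], dtype=np.int64),) * 3
        pos, frac, cov = self.data[chrom]
        lo = np.searchsorted(pos, start_1based, side="left")
        hi = np.searchsorted(pos, end_1based, side="right")
        return pos[lo:hi], frac[lo:hi], cov[lo:hi]


@dataclass
class LMRSet:
    """Called low-methylated regions with per-region mean and CpG count."""

    regions: list[GenomicInterval]  # meta: mean_meth, n_cpgs
    low_band: tuple[float, float]
    min_cpgs: int

    def __len__(self) -> int:
        return len(self.regions)

    def write(self, path) -> None:
        write_bed(self.regions, path)


def read_methylation(path, min_coverage: int = 5) -> MethylationTrack:
    """Read a 4-column TSV (chrom, 1-based pos, %methylation, coverage).

    Percentages are stored as proportions; rows below ``min_coverage`` are
    dropped (count available via the returned track's ``n_dropped``).
    """
    chroms: dict[str, list[tuple[int, float, int]]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, pos, pct, cov = f[0], int(f[1]), float(f[2]), int(f[3])
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{path}: line {lineno}: %methylation {pct} outside [0, 100]")
            if cov < min_coverage:
                n_dropped += 1
                continue
            chroms.setdefault(chrom, []).append((pos, pct / 100.0, cov))
    data = {}
    for chrom, rows in chroms.items():
        pos = np.array([r[0] for r in rows], dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{path}: positions not strictly increasing on {chrom}")
        data[chrom] = (
            pos,
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows], dtype=np.int64),
        )
    track = MethylationTrack(data)
    track.n_dropped = n_dropped
    return track


def write_methylation(track: MethylationTrack, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, frac, cov = track.data[chrom]
            for p, f, c in zip(pos, frac, cov):
                fh.write(f"{chrom}\t{p}\t{100.0 * f:.4f}\t{c}\n")


def call_lmrs(
    track: MethylationTrack,
    low_band: tuple[float, float] = (0.10, 0.50),
    min_cpgs: int = 4,
    max_gap_bp: int = 250,
) -> LMRSet:
    """Maximal runs of lowly methylated CpGs.

    A run extends over consecutive CpGs each with fraction < ``low_band[1]``
    and inter-CpG gap <= ``max_gap_bp``; it is reported iff it contains
    >= ``min_cpgs`` CpGs and its mean methylation lies within ``low_band``.
    Intervals are 0-based half-open spanning first..last CpG of the run.
    """
    if track.n_cpgs() == 0:
        raise ValueError("methylation track is empty")
    hi_cut = low_band[1]
    regions: list[GenomicInterval] = []
    for chrom, (pos, frac, cov) in track.data.items():
        low = frac < hi_cut
        i = 0
        n = len(pos)
        while i < n:
            if not low[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and low[j + 1] and pos[j + 1] - pos[j] <= max_gap_bp:
                j += 1
            run = slice(i, j + 1)
            k = j - i + 1
            mean = float(frac[run].mean())
            if k >= min_cpgs and low_band[0] <= mean <= hi_cut:
                regions.append(
                    GenomicInterval(
                        chrom, int(pos[i]) - 1, int(pos[j]),
                        score=mean, name=f"lmr_{len(regions):05d}",
                        meta={"mean_meth": mean, "n_cpgs": k},
                    )
                )
            i = j + 1
    return LMRSet(regions=regions, low_band=low_band, min_cpgs=min_cpgs)


def site_methylation(
    track: MethylationTrack,
    catalog: SiteCatalog,
    window_bp: int = 100,
    coverage_weighted: bool = True,
) -> pd.Series:
    """Mean CpG methylation in a +/-``window_bp`` window around each site center.

    Coverage-weighted by default; NaN where no covered CpG falls in the window.
    Positions are 1-based inside the track, so site center c (0-based) maps to
    window [c+1-window, c+1+window].
    """
    out = {}
    for site in catalog.sites:
        c1 = site.center + 1
        _, frac, cov = track.window(site.chrom, c1 - window_bp, c1 + window_bp)
        if len(frac) == 0:
            out[site.name] = np.nan
        elif coverage_weighted:
            out[site.name] = float(np.average(frac, weights=cov))
        else:
            out[site.name] = float(frac.mean())
    return pd.Series(out, name="mean_meth")


def methylation_dynamics(
    per_timepoint_site_methylation: Mapping[str, pd.Series],
    catalog: SiteCatalog,
    lmr_set: LMRSet | None = None,
    association_bp: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cloud-map table and per-class demethylation deltas at LMR-associated sites.

    Sites are restricted to those whose center lies within an LMR or within
    ``association_bp`` of one (no restriction if ``lmr_set`` is None). Returns
    (cloud, summary): ``cloud`` has one row per site with per-time-point means
    and the class label; ``summary`` has the per-class median deltas between
    consecutive assayed stages, with persistent subclasses also pooled as
    "persistent".
    """
    timepoints = list(per_timepoint_site_methylation)
    keep = np.ones(len(catalog), dtype=bool)
    if lmr_set is not None:
        from .intervals import IntervalIndex

        ix = IntervalIndex(lmr_set.regions)
        for i, site in enumerate(catalog.sites):
            keep[i] = ix.any_overlap(
                site.chrom, site.center - association_bp, site.center + association_bp + 1
            )
    labels = catalog.class_array()
    rows = []
    for i, site in enumerate(catalog.sites):
        if not keep[i] or labels[i] == "unclassified":
            continue
        row = {"site_id": site.name, "class": labels[i]}
        for tp in timepoints:
            row[f"m_{tp}"] = per_timepoint_site_methylation[tp].get(site.name, np.nan)
        rows.append(row)
    cloud = pd.DataFrame(rows)

    groups: dict[str, pd.DataFrame] = {}
    if not cloud.empty:
        for cls, sub in cloud.groupby("class"):
            groups[cls] = sub
        pers = cloud[cloud["class"].isin(PERSISTENT_CLASSES)]
        if not pers.empty:
            groups["persistent"] = pers
    srows = []
    for cls, sub in sorted(groups.items()):
        row = {"class": cls, "n_sites": len(sub)}
        for a, b in zip(timepoints[:-1], timepoints[1:]):
            row[f"delta_{b}_{a}"] = float((sub[f"m_{b}"] - sub[f"m_{a}"]).median())
        srows.append(row)
    summary = pd.DataFrame(srows)
    return cloud, summary
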