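"""RPKM signal matrices around site centers, accessibility clustering,
central-depletion profiles, and a minimal Poisson enrichment peak caller.

Signal is binned fragment (or cut) density in a fixed window (default +/-3 kb,
50-bp bins) around each catalog site, normalized as reads per kilobase per
million mapped fragments. Fragments are counted by midpoint so bins are
additive. The accessibility classifier reproduces the five-cluster scheme:
pre-existing accessibility, gains at successive time points, and transient
accessibility lost again at the committed stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex, merge_intervals
from .peaks import SiteCatalog, build_site_catalog

__all__ = [
    "SignalTrack",
    "SignalMatrix",
    "compute_signal_matrix",
    "classify_accessibility",
    "central_depletion_profile",
    "atac_peak_site_frequency",
    "call_enrichment_peaks",
    "ACCESSIBILITY_CLASSES",
]

ACCESSIBILITY_CLASSES = ("preexisting", "gain24", "gain72", "gainproB", "transient")


@dataclass
class SignalTrack:
    """Sorted fragment midpoints per chromosome plus the library size."""

    midpoints: dict[str, np.ndarray]
    total_mapped_fragments: int
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_mapped_fragments <= 0:
            raise ValueError("total_mapped_fragments must be > 0")
        for chrom, mids in self.midpoints.items():
            if len(mids) and np.any(np.diff(mids) < 0):
                self.midpoints[chrom] = np.sort(mids)

    @classmethod
    def from_fragments(cls, fragments: Sequence[GenomicInterval],
                       chrom_sizes: dict[str, int] | None = None) -> "SignalTrack":
        mids: dict[str, list[int]] = {}
        for f in fragments:
            mids.setdefault(f.chrom, []).append(f.center)
        arrays = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids.items()}
        return cls(arrays, max(1, len(fragments)), chrom_sizes or {})

    @classmethod
    def from_cut_tracks(cls, tracks: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> "SignalTrack":
        """Treat every Tn5 cut (either strand) as one fragment midpoint."""
        mids = {}
        total = 0
        sizes = {}
        for chrom, (fwd, rev) in tracks.items():
            counts = np.asarray(fwd) + np.asarray(rev)
            pos = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
            mids[chrom] = pos
            total += int(counts.sum())
            sizes[chrom] = int(counts.size)
        return cls(mids, max(1, total), sizes)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self.midpoints:
            return 0
        m = self.midpoints[chrom]
        return int(np.searchsorted(m, end) - np.searchsorted(m, start))


@dataclass
class SignalMatrix:
    """sites x bins RPKM matrix in a symmetric window around site centers."""

    site_ids: list[str]
    bin_centers: np.ndarray  # bp relative to site center
    values: np.ndarray  # (n_sites, n_bins) RPKM
    window_bp: int
    bin_bp: int
    truncated: np.ndarray | None = None  # bool per site: zero-padded at an edge

    def __post_init__(self):
        if self.values.shape != (len(self.site_ids), len(self.bin_centers)):
            raise ValueError("values shape mismatch")
        if (self.values < 0).any():
            raise ValueError("RPKM values must be nonnegative")

    def central_mean(self, center_bp: int = 500) -> np.ndarray:
        mask = np.abs(self.bin_centers) <= center_bp
        return self.values[:, mask].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids,
                            columns=[int(b) for b in self.bin_centers])


def compute_signal_matrix(
    track: SignalTrack,
    catalog: SiteCatalog,
    window_bp: int = 3000,
    bin_bp: int = 50,
) -> SignalMatrix:
    """Bin fragment midpoints around each site center and normalize to RPKM.

    value(site, bin) = count x 1e9 / (bin_bp x total_mapped_fragments).
    Bins extending past a chromosome edge are zero-padded and the site is
    flagged in ``truncated``.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be divisible by bin_bp")
    n_bins = 2 * window_bp // bin_bp
    offsets = -window_bp + bin_bp * np.arange(n_bins + 1)
    bin_centers = (offsets[:-1] + offsets[1:]) / 2.0
    if track.total_mapped_fragments <= 0 or all(len(v) == 0 for v in track.midpoints.values()):
        warnings.warn("empty signal track: all-zero matrix")
    scale = 1e9 / (bin_bp * track.total_mapped_fragments)
    values = np.zeros((len(catalog), n_bins))
    truncated = np.zeros(len(catalog), dtype=bool)
    for i, site in enumerate(catalog.sites):
        edges = site.center + offsets
        size = track.chrom_sizes.get(site.chrom)
        if edges[0] < 0 or (size is not None and edges[-1] > size):
            truncated[i] = True
        mids = track.midpoints.get(site.chrom, np.array([], dtype=np.int64))
        counts = np.diff(np.searchsorted(mids, edges))
        if truncated[i]:
            bad = (edges[1:] <= 0) | ((size is not None) & (edges[:-1] >= (size or 0)))
            counts = np.where(bad, 0, counts)
        values[i] = counts * scale
    return SignalMatrix(catalog.site_ids, bin_centers, values, window_bp, bin_bp, truncated)


def estimate_background_rpkm(track: SignalTrack, catalog: SiteCatalog,
                             exclude_bp: int = 2000) -> float:
    """Genome-wide background RPKM from fragment density outside site windows."""
    if not track.chrom_sizes:
        raise ValueError("track has no chromosome sizes; cannot estimate background")
    excl = {c: np.zeros(n, dtype=bool) for c, n in track.chrom_sizes.items()}
    for s in catalog.sites:
        if s.chrom in excl:
            lo = max(0, s.center - exclude_bp)
            hi = min(len(excl[s.chrom]), s.center + exclude_bp)
            excl[s.chrom][lo:hi] = True
    n_frag = 0
    n_bp = 0
    for chrom, mask in excl.items():
        mids = track.midpoints.get(chrom, np.array([], dtype=np.int64))
        inside = mids[(mids >= 0) & (mids < mask.size)]
        n_frag += int((~mask[inside]).sum())
        n_bp += int((~mask).sum())
    if n_bp == 0:
        return 0.0
    return n_frag / n_bp * 1e9 / track.total_mapped_fragments


def classify_accessibility(
    matrices_by_timepoint: Mapping[str, SignalMatrix],
    catalog: SiteCatalog,
    center_bp: int = 500,
    gain_fold: float = 2.0,
    min_rpkm: float | str = "auto",
    baseline_timepoint: str = "0h",
    occupied_24h_timepoint: str = "24h",
    final_timepoint: str = "proB",
    baseline_floor: float | None = None,
    background_rpkm: float | None = None,
) -> pd.Series:
    """Five-cluster accessibility labels from per-time-point central signal.

    central(t) = mean RPKM within +/-``center_bp``. A site is accessible at t
    iff central(t) >= min_rpkm. Labels:

    - preexisting: accessible at 0 h and ChIP-occupied at 24 h;
    - gain24/gain72/gainproB: first induced t with central(t) >= gain_fold x
      max(central(0 h), floor) and >= min_rpkm;
    - transient: gains by 72 h but drops back below the gain threshold at the
      final stage;
    - unclassified: never crosses the threshold.

    ``min_rpkm="auto"`` sets min_rpkm = 5 x background and the baseline floor
    to the background RPKM (RPKM scales inversely with library size, so a
    fixed threshold is only meaningful for a given depth).
    """
    tps = list(matrices_by_timepoint)
    if baseline_timepoint not in tps or final_timepoint not in tps:
        raise ValueError("need baseline and final time points")
    central = {tp: m.central_mean(center_bp) for tp, m in matrices_by_timepoint.items()}
    if min_rpkm == "auto":
        if background_rpkm is None:
            raise ValueError("min_rpkm='auto' requires background_rpkm")
        min_rpkm_val = 5.0 * background_rpkm
        floor = background_rpkm
    else:
        min_rpkm_val = float(min_rpkm)
        floor = baseline_floor if baseline_floor is not None else 0.25
    floor = max(floor, 1e-9)

    induced = [tp for tp in tps if tp not in (baseline_timepoint, "6h")]
    occ24 = None
    if occupied_24h_timepoint in catalog.timepoints:
        occ24 = catalog.occupancy[:, catalog.timepoints.index(occupied_24h_timepoint)]
    labels = []
    base = central[baseline_timepoint]
    for i, sid in enumerate(catalog.site_ids):
        b = max(base[i], floor)
        thresh = gain_fold * b
        if base[i] >= min_rpkm_val and occ24 is not None and occ24[i]:
            labels.append("preexisting")
            continue
        gained_at = None
        for tp in induced:
            if central[tp][i] >= thresh and central[tp][i] >= min_rpkm_val:
                gained_at = tp
                break
        if gained_at is None:
            labels.append("unclassified")
        elif gained_at != final_timepoint and central[final_timepoint][i] < thresh:
            labels.append("transient")
        else:
            labels.append(f"gain{gained_at.rstrip('h')}" if gained_at != final_timepoint
                          else "gainproB")
    return pd.Series(labels, index=catalog.site_ids, name="accessibility_class")


def central_depletion_profile(
    matrix: SignalMatrix,
    class_labels: Mapping[str, str] | pd.Series,
    center_bp: int = 100,
    shoulder_range: tuple[int, int] = (500, 1000),
) -> pd.DataFrame:
    """Per-class mean profile and center-to-shoulder ratio.

    ratio = mean(center +/-``center_bp``) / mean(shoulders at +/-500-1000 bp);
    a ratio < 1 indicates a central dip (local nucleosome depletion at the
    bound site). NaN with a warning when the shoulder mean is zero.
    """
    if len(matrix.bin_centers) < 3:
        raise ValueError("matrix must have >= 3 bins")
    labels = pd.Series(class_labels).reindex(matrix.site_ids)
    cmask = np.abs(matrix.bin_centers) <= center_bp
    smask = (np.abs(matrix.bin_centers) >= shoulder_range[0]) & (
        np.abs(matrix.bin_centers) <= shoulder_range[1]
    )
    rows = []
    for cls in sorted(labels.dropna().unique()):
        sub = matrix.values[(labels == cls).to_numpy()]
        prof = sub.mean(axis=0)
        center = float(prof[cmask].mean())
        shoulder = float(prof[smask].mean())
        if shoulder == 0:
            warnings.warn(f"class {cls}: zero shoulder signal; ratio undefined")
            ratio = np.nan
        else:
            ratio = center / shoulder
        rows.append({"class": cls, "n_sites": int(sub.shape[0]),
                     "center_mean": center, "shoulder_mean": shoulder,
                     "center_shoulder_ratio": ratio})
    return pd.DataFrame(rows)


def atac_peak_site_frequency(
    atac_peak_sets_by_timepoint: Mapping[str, Sequence[GenomicInterval]],
    catalog: SiteCatalog,
) -> pd.DataFrame:
    """Fraction of ATAC peaks containing a catalog site, per first-accessible cluster.

    ATAC peaks are pooled into their own catalog; each merged peak is assigned
    to the cluster named by the first time point at which it is present, and
    the fraction overlapping (>= 1 bp) a binding-site catalog entry is
    reported per cluster.
    """
    atac_catalog = build_site_catalog(atac_peak_sets_by_timepoint, site_prefix="atac")
    ix = IntervalIndex(catalog.sites)
    tps = atac_catalog.timepoints
    rows = []
    first_tp = []
    for i in range(len(atac_catalog)):
        occ = atac_catalog.occupancy[i]
        first = next((tps[t] for t in range(len(tps)) if occ[t]), None)
        first_tp.append(first)
    first_tp = np.array(first_tp, dtype=object)
    for tp in tps:
        mask = first_tp == tp
        n = int(mask.sum())
        if n == 0:
            rows.append({"cluster": tp, "n_peaks": 0, "site_fraction": np.nan})
            continue
        hits = sum(
            1
            for i in np.flatnonzero(mask)
            if ix.any_overlap(
                atac_catalog.sites[i].chrom,
                atac_catalog.sites[i].start,
                atac_catalog.sites[i].end,
            )
        )
        rows.append({"cluster": tp, "n_peaks": n, "site_fraction": hits / n})
    return pd.DataFrame(rows)


def call_enrichment_peaks(
    coverage: Mapping[str, np.ndarray],
    background_rate: float | None = None,
    p_threshold: float = 1e-5,
    min_width: int = 100,
    window_bp: int = 100,
    step_bp: int = 50,
) -> list[GenomicInterval]:
    """Minimal Poisson enrichment peak caller over dense per-base coverage.

    Slides windows of ``window_bp`` at ``step_bp``; windows whose count has a
    Poisson upper-tail p-value < ``p_threshold`` against ``background_rate``
    (per base; genome-wide mean if None) are merged, and merged intervals of
    width >= ``min_width`` are returned. Intended for synthetic end-to-end
    runs; real analyses supply external narrowPeak calls instead.
    """
    if background_rate is None:
        tot = sum(float(np.sum(v)) for v in coverage.values())
        nbp = sum(int(np.size(v)) for v in coverage.values())
        background_rate = tot / nbp if nbp else 0.0
    if background_rate <= 0:
        background_rate = 1e-9
    mu = background_rate * window_bp
    peaks: list[GenomicInterval] = []
    for chrom in sorted(coverage):
        vals = np.asarray(coverage[chrom])
        if vals.size < window_bp:
            continue
        csum = np.concatenate([[0], np.cumsum(vals)])
        starts = np.arange(0, vals.size - window_bp + 1, step_bp)
        counts = csum[starts + window_bp] - csum[starts]
        pvals = stats.poisson.sf(counts - 1, mu)
        sig = pvals < p_threshold
        windows = [
            GenomicInterval(chrom, int(s), int(s + window_bp), score=float(c))
            for s, c in zip(starts[sig], counts[sig])
        ]
        for m in merge_intervals(windows):
            if len(m) >= min_width:
                peaks.append(m)
    return [
        GenomicInterval(p.chrom, p.start, p.end, score=p.score, name=f"peak_{i:05d}")
        for i, p in enumerate(peaks)
    ]
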