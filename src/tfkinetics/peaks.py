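"""Replicate-consensus peaks, the unified site catalog, and temporal occupancy classes.

A time course of binding-site peak calls (e.g. a pioneer factor induced at t=0
and profiled at 24 h, 72 h, and the committed pro-B stage) is reduced to a
single catalog of sites, each with a binary occupancy vector over time points.
Sites still occupied at the final (pro-B) time point are *persistent* and are
subclassed by the earliest induced time point at which they appear (gain24 /
gain72 / gainproB, or pre-existing when the locus was already accessible
before induction); sites occupied at 24 and/or 72 h but absent at pro-B are
*transient*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, merge_intervals, write_bed

__all__ = [
    "SiteCatalog",
    "replicate_consensus",
    "build_site_catalog",
    "classify_temporal",
    "motif_fraction_by_class",
    "TEMPORAL_CLASSES",
]

#: Fixed label vocabulary for temporal occupancy classes.
TEMPORAL_CLASSES = ("preexisting", "gain24", "gain72", "gainproB", "transient")
UNCLASSIFIED = "unclassified"

#: persistent = still occupied at the final stage (any gain subclass)
PERSISTENT_CLASSES = ("preexisting", "gain24", "gain72", "gainproB")


@dataclass
class SiteCatalog:
    """Unified binding-site universe with per-time-point occupancy.

    occupancy[i, t] is 1 iff merged site i overlaps a consensus peak at
    timepoints[t]. ``classes`` is filled by :func:`classify_temporal`.
    """

    sites: list[GenomicInterval]
    occupancy: np.ndarray  # (n_sites, n_timepoints) uint8
    timepoints: list[str]
    classes: dict[str, str] = field(default_factory=dict)  # site name -> label

    def __post_init__(self):
        if self.occupancy.shape != (len(self.sites), len(self.timepoints)):
            raise ValueError("occupancy shape does not match sites x timepoints")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.name for s in self.sites]

    def centers(self) -> np.ndarray:
        return np.array([s.center for s in self.sites])

    def class_array(self) -> np.ndarray:
        return np.array([self.classes.get(s.name, UNCLASSIFIED) for s in self.sites])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site_id": self.site_ids,
                "chrom": [s.chrom for s in self.sites],
                "start": [s.start for s in self.sites],
                "end": [s.end for s in self.sites],
                "center": self.centers(),
            }
        )
        for t, tp in enumerate(self.timepoints):
            df[f"occ_{tp}"] = self.occupancy[:, t]
        df["class"] = self.class_array()
        return df

    def write(self, bed_path, table_path) -> None:
        write_bed(self.sites, bed_path)
        Path(table_path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(table_path, sep="\t", index=False)


def replicate_consensus(
    replicate_peak_sets: Sequence[Sequence[GenomicInterval]],
    min_overlap_bp: int = 1,
) -> list[GenomicInterval]:
    """Peaks of replicate 1 supported by every other replicate.

    A replicate-1 peak is kept iff it shares >= ``min_overlap_bp`` bases with a
    peak in each of the remaining replicates. A single replicate is returned
    unchanged.
    """
    if not replicate_peak_sets:
        raise ValueError("need at least one replicate peak set")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    first = list(replicate_peak_sets[0])
    if len(replicate_peak_sets) == 1:
        return first
    indexes = [IntervalIndex(reps) for reps in replicate_peak_sets[1:]]
    return [
        p
        for p in first
        if all(ix.any_overlap(p.chrom, p.start, p.end, min_overlap_bp) for ix in indexes)
    ]


def build_site_catalog(
    consensus_sets_by_timepoint: Mapping[str, Sequence[GenomicInterval]],
    merge_gap_bp: int = 0,
    site_prefix: str = "site",
) -> SiteCatalog:
    """Merge per-time-point consensus peaks into one site universe.

    Peaks from all time points are pooled and merged when overlapping or within
    ``merge_gap_bp``; each merged site's occupancy bit at time t is set iff it
    overlaps any consensus peak at t.
    """
    timepoints = list(consensus_sets_by_timepoint)
    if len(timepoints) < 2:
        raise ValueError("need >= 2 time points to build a catalog")
    pooled = [p for tp in timepoints for p in consensus_sets_by_timepoint[tp]]
    merged = merge_intervals(pooled, gap_bp=merge_gap_bp)
    sites = [
        GenomicInterval(m.chrom, m.start, m.end, name=f"{site_prefix}_{i:05d}")
        for i, m in enumerate(merged)
    ]
    occ = np.zeros((len(sites), len(timepoints)), dtype=np.uint8)
    for t, tp in enumerate(timepoints):
        ix = IntervalIndex(consensus_sets_by_timepoint[tp])
        for i, s in enumerate(sites):
            if ix.any_overlap(s.chrom, s.start, s.end):
                occ[i, t] = 1
    return SiteCatalog(sites=sites, occupancy=occ, timepoints=timepoints)


def classify_temporal(
    catalog: SiteCatalog,
    accessible_0h: np.ndarray | None = None,
    induced_timepoints: Sequence[str] = ("24h", "72h"),
    final_timepoint: str = "proB",
) -> SiteCatalog:
    """Assign each site a temporal occupancy class (in place; catalog returned).

    persistent (occupied at the final stage) sites are subclassed by the first
    occupied induced time point; a site first occupied at 24 h whose locus was
    already accessible before induction is "preexisting" when an
    ``accessible_0h`` boolean vector is supplied. Sites occupied at 24 and/or
    72 h but not at the final stage are "transient". Sites occupied at no
    induced or final time point are "unclassified" and excluded downstream.

    An early (6 h) column, if present in the catalog, never changes labels:
    persistence is defined on the 24 h / 72 h / final grid.
    """
    if final_timepoint not in catalog.timepoints:
        raise ValueError(f"final time point {final_timepoint!r} missing from catalog")
    t_final = catalog.timepoints.index(final_timepoint)
    induced_idx = [
        catalog.timepoints.index(tp)
        for tp in induced_timepoints
        if tp in catalog.timepoints
    ]
    if not induced_idx:
        raise ValueError("no induced time points present in catalog")
    if accessible_0h is not None and len(accessible_0h) != len(catalog):
        raise ValueError("accessible_0h length mismatch")

    classes: dict[str, str] = {}
    for i, site in enumerate(catalog.sites):
        occ_final = bool(catalog.occupancy[i, t_final])
        occ_induced = [bool(catalog.occupancy[i, t]) for t in induced_idx]
        if occ_final:
            if any(occ_induced):
                first = induced_timepoints[occ_induced.index(True)]
                label = f"gain{first.rstrip('h')}"
                if (
                    first == induced_timepoints[0]
                    and accessible_0h is not None
                    and bool(accessible_0h[i])
                ):
                    label = "preexisting"
            else:
                label = "gainproB"
        elif any(occ_induced):
            label = "transient"
        else:
            label = UNCLASSIFIED
        classes[site.name] = label
    catalog.classes = classes
    return catalog


def class_counts(catalog: SiteCatalog) -> pd.Series:
    """Site counts per temporal class (including unclassified)."""
    labels = catalog.class_array()
    order = list(TEMPORAL_CLASSES) + [UNCLASSIFIED]
    return pd.Series(labels).value_counts().reindex(order, fill_value=0)


def motif_fraction_by_class(
    catalog: SiteCatalog, motif_hits: Sequence[GenomicInterval]
) -> pd.Series:
    """Per-class fraction of sites containing >= 1 motif-hit midpoint.

    A site "contains" a hit iff the hit midpoint lies within [start, end).
    Returns fractions indexed by class label (NaN for empty classes).
    """
    ix = IntervalIndex(catalog.sites)
    has_hit = np.zeros(len(catalog), dtype=bool)
    for hit in motif_hits:
        for j in ix.containing_point(hit.chrom, hit.center):
            has_hit[j] = True
    labels = catalog.class_array()
    out = {}
    for cls in TEMPORAL_CLASSES:
        mask = labels == cls
        out[cls] = float(has_hit[mask].mean()) if mask.any() else float("nan")
    return pd.Series(out)
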