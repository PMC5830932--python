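"""Pioneer-factor dependence of secondary-factor binding sites.

A secondary factor (Pax5-like) profiled at the committed stage is classified
per binding site by two flags: whether a pioneer-factor (EBF1-like) peak
co-occurs nearby at the committed stage, and whether the site is already
bound when the secondary factor is induced in pioneer-knockout progenitors.
"dependent" means not bound without the pioneer. Crossing the two flags gives
the four-way scheme cobound/solo x dependent/independent; accessibility flags
before induction and at the committed stage complete the picture (dependent
sites are expected to be closed before the pioneer acts).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalIndex
from .peaks import PERSISTENT_CLASSES, SiteCatalog

__all__ = [
    "classify_dependence",
    "dependence_accessibility_summary",
    "early_occupancy_overlap",
    "DEPENDENCE_LABELS",
]

DEPENDENCE_LABELS = (
    "cobound_independent",
    "cobound_dependent",
    "solo_independent",
    "solo_dependent",
)


def _label(cobound: bool, bound_without: bool) -> str:
    side = "cobound" if cobound else "solo"
    dep = "independent" if bound_without else "dependent"
    return f"{side}_{dep}"


def classify_dependence(
    secondary_sites: Sequence[GenomicInterval],
    secondary_peaks_in_knockout: Sequence[GenomicInterval],
    pioneer_peaks_final: Sequence[GenomicInterval],
    central_rpkm_0h: Mapping[str, float] | pd.Series | None = None,
    central_rpkm_final: Mapping[str, float] | pd.Series | None = None,
    min_rpkm: float = 5.0,
    cooccupancy_window_bp: int = 200,
) -> pd.DataFrame:
    """Four-way dependence classification of secondary-factor sites.

    Flags per site (the universe is the committed-stage secondary peaks):
    - ebf1_cooccupied: a pioneer peak center within +/- cooccupancy_window_bp
      of the site center;
    - bound_without_ebf1: the site overlaps (>= 1 bp) a knockout-induction
      peak; dependent = NOT bound_without_ebf1;
    - accessible_pre / accessible_final: central RPKM >= min_rpkm (NaN when
      no signal provided).

    Returns one row per site with flags and the four-way label.
    """
    sites = list(secondary_sites)
    if not sites:
        warnings.warn("empty secondary-factor site universe")
        return pd.DataFrame(
            columns=["site_id", "chrom", "center", "ebf1_cooccupied",
                     "bound_without_ebf1", "accessible_pre", "accessible_proB",
                     "label"]
        )
    ko_ix = IntervalIndex(list(secondary_peaks_in_knockout))
    pioneer_centers: dict[str, np.ndarray] = {}
    for p in pioneer_peaks_final:
        pioneer_centers.setdefault(p.chrom, []).append(p.center)
    pioneer_centers = {c: np.sort(np.array(v)) for c, v in pioneer_centers.items()}

    rows = []
    for s in sites:
        centers = pioneer_centers.get(s.chrom)
        cobound = bool(
            centers is not None
            and np.searchsorted(centers, s.center + cooccupancy_window_bp, side="right")
            > np.searchsorted(centers, s.center - cooccupancy_window_bp, side="left")
        )
        bound_without = ko_ix.any_overlap(s.chrom, s.start, s.end)
        row = {
            "site_id": s.name,
            "chrom": s.chrom,
            "center": s.center,
            "ebf1_cooccupied": cobound,
            "bound_without_ebf1": bound_without,
            "label": _label(cobound, bound_without),
        }
        for key, rpkm in (("accessible_pre", central_rpkm_0h),
                          ("accessible_proB", central_rpkm_final)):
            if rpkm is None:
                row[key] = np.nan
            else:
                v = rpkm.get(s.name) if hasattr(rpkm, "get") else rpkm[s.name]
                row[key] = bool(v >= min_rpkm) if v == v else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def dependence_accessibility_summary(
    classification: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accessibility contingency per dependence label, with Fisher tests.

    Returns (per_label, tests): per-label counts and accessible fractions
    before induction and at the committed stage (rows emitted with zeros for
    empty labels), and Fisher exact comparisons of dependent vs independent
    accessibility at each stage.
    """
    rows = []
    for label in DEPENDENCE_LABELS:
        sub = classification[classification["label"] == label]
        row = {"label": label, "n_sites": len(sub)}
        for key in ("accessible_pre", "accessible_proB"):
            vals = sub[key].dropna() if len(sub) else pd.Series(dtype=float)
            row[f"n_{key}"] = int(vals.sum()) if len(vals) else 0
            row[f"frac_{key}"] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    per_label = pd.DataFrame(rows)

    tests = []
    dep = classification[classification["label"].str.endswith("_dependent")]
    ind = classification[classification["label"].str.endswith("_independent")]
    for key in ("accessible_pre", "accessible_proB"):
        a = dep[key].dropna()
        b = ind[key].dropna()
        if len(a) == 0 or len(b) == 0:
            tests.append({"stage": key, "p_value": np.nan, "odds_ratio": np.nan})
            continue
        table = [[int(a.sum()), int(len(a) - a.sum())],
                 [int(b.sum()), int(len(b) - b.sum())]]
        odds, p = stats.fisher_exact(table)
        tests.append({"stage": key, "odds_ratio": float(odds), "p_value": float(p)})
    return per_label, pd.DataFrame(tests)


def early_occupancy_overlap(
    catalog: SiteCatalog,
    peaks_early: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Fraction of catalog sites already occupied at an early (6 h) time point.

    Overlap is >= 1 shared base with any early peak. Reported per temporal
    class plus pooled persistent/transient groups; exact counts included.
    """
    ix = IntervalIndex(list(peaks_early))
    labels = catalog.class_array()
    hit = np.array(
        [ix.any_overlap(s.chrom, s.start, s.end) for s in catalog.sites], dtype=bool
    )
    groups: dict[str, np.ndarray] = {}
    for cls in sorted(set(labels) - {"unclassified"}):
        groups[cls] = labels == cls
    groups["persistent"] = np.isin(labels, PERSISTENT_CLASSES)
    groups["transient_all"] = labels == "transient"
    rows = []
    for name, mask in groups.items():
        n = int(mask.sum())
        k = int(hit[mask].sum())
        rows.append(
            {"group": name, "n_sites": n, "n_overlapping": k,
             "fraction": k / n if n else 0.0}
        )
    return pd.DataFrame(rows)
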