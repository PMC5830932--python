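"""Tn5-protection footprinting, motif mapping, and co-occurrence enrichment.

The footprint statistic is a simplified Wellington-style score: within
accessible chromatin, a bound protein leaves a short window depleted of Tn5
insertions relative to its flanking shoulders, with the forward-strand cuts
evaluated against the upstream shoulder and reverse-strand cuts against the
downstream shoulder. Each strand contributes a binomial lower-tail p-value
for the observed interior cut count given the interior/(interior+shoulder)
length fraction; the score is the summed -log10 of the two p-values, and a
profile with an empty shoulder on either strand scores 0 (no information).

Calls are made per accessible region by taking, at each position, the best
score over a ladder of footprint widths, thresholding at an empirical
(1 - FDR) quantile of max-scores from within-region cut shuffles, and
resolving overlaps greedily by score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalIndex

__all__ = [
    "CutProfile",
    "FootprintCall",
    "MotifHit",
    "MotifOccupancySet",
    "wellington_score",
    "call_footprints",
    "scan_motifs",
    "footprint_motif_occupancy",
    "cooccurrence_enrichment",
]

LN10 = np.log(10.0)


@dataclass
class CutProfile:
    """Per-base forward/reverse Tn5 cut counts over one region."""

    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self):
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        if self.fwd.shape != self.rev.shape:
            raise ValueError("strand arrays must have equal length")
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise ValueError("cut counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.fwd)


@dataclass
class FootprintCall:
    interval: GenomicInterval
    score: float
    footprint_width: int
    shoulder_bp: int

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be >= 0")


@dataclass
class MotifHit:
    motif_id: str
    interval: GenomicInterval
    strand: str
    score: float


@dataclass
class MotifOccupancySet:
    """Motif instances at one time point with their footprinted status."""

    timepoint: str
    hits: list[MotifHit]
    footprinted: np.ndarray  # bool per hit

    def fraction(self) -> float:
        return float(self.footprinted.mean()) if len(self.hits) else np.nan

    def by_motif(self) -> pd.DataFrame:
        rows = {}
        for h, fp in zip(self.hits, self.footprinted):
            n, k = rows.get(h.motif_id, (0, 0))
            rows[h.motif_id] = (n + 1, k + int(fp))
        return pd.DataFrame(
            [{"motif_id": m, "n_instances": n, "n_footprinted": k,
              "footprinted_fraction": k / n if n else np.nan}
             for m, (n, k) in sorted(rows.items())]
        )


def wellington_score(
    cut_profile: CutProfile, fp_start: int, fp_width: int, shoulder_bp: int
) -> float:
    """Strand-aware Tn5-protection score for one candidate footprint.

    p_strand = BinomialLowerTail(N_fp; N_fp + N_shoulder, fp_width /
    (fp_width + shoulder_bp)), forward cuts against the upstream shoulder and
    reverse cuts against the downstream one; score = -log10 p_fwd - log10
    p_rev, or 0 when either shoulder holds no cuts.
    """
    if fp_start - shoulder_bp < 0 or fp_start + fp_width + shoulder_bp > len(cut_profile):
        raise IndexError("footprint plus shoulders outside profile bounds")
    f, r = cut_profile.fwd, cut_profile.rev
    nf_fp = int(f[fp_start: fp_start + fp_width].sum())
    nf_sh = int(f[fp_start - shoulder_bp: fp_start].sum())
    nr_fp = int(r[fp_start: fp_start + fp_width].sum())
    nr_sh = int(r[fp_start + fp_width: fp_start + fp_width + shoulder_bp].sum())
    if nf_sh == 0 or nr_sh == 0:
        return 0.0
    p0 = fp_width / (fp_width + shoulder_bp)
    lp_f = stats.binom.logcdf(nf_fp, nf_fp + nf_sh, p0)
    lp_r = stats.binom.logcdf(nr_fp, nr_fp + nr_sh, p0)
    return float(-(lp_f + lp_r) / LN10)


class _LogCdfCache:
    """Memoized log10 binomial lower-tail tables, keyed by (width, shoulder).

    Counts in toy-depth data are small integers, so a triangular table
    L[n, k] = log10 BinomCdf(k; n, w/(w+s)) turns millions of p-value
    evaluations into integer fancy-indexing.
    """

    def __init__(self):
        self._tables: dict[tuple[int, int], np.ndarray] = {}

    def table(self, fp_width: int, shoulder_bp: int, n_max: int) -> np.ndarray:
        key = (fp_width, shoulder_bp)
        tab = self._tables.get(key)
        if tab is None or tab.shape[0] <= n_max:
            size = max(n_max + 1, 64)
            p0 = fp_width / (fp_width + shoulder_bp)
            n = np.arange(size)[:, None]
            k = np.arange(size)[None, :]
            with np.errstate(divide="ignore"):
                tab = stats.binom.logcdf(np.minimum(k, n), n, p0) / LN10
            self._tables[key] = tab
        return self._tables[key]


def _score_region(
    fwd: np.ndarray,
    rev: np.ndarray,
    widths: Sequence[int],
    shoulder_bp: int,
    cache: _LogCdfCache,
) -> tuple[np.ndarray, np.ndarray]:
    """Max score over widths at every in-bounds start position.

    Arrays are the extended region (shoulders included); returns (scores,
    best_width) indexed by start position within the extended arrays.
    """
    L = len(fwd)
    cf = np.concatenate([[0], np.cumsum(fwd)])
    cr = np.concatenate([[0], np.cumsum(rev)])
    best = np.zeros(L, dtype=float)
    best_w = np.zeros(L, dtype=np.int64)
    for w in widths:
        starts = np.arange(shoulder_bp, L - w - shoulder_bp + 1)
        if starts.size == 0:
            continue
        nf_fp = cf[starts + w] - cf[starts]
        nf_sh = cf[starts] - cf[starts - shoulder_bp]
        nr_fp = cr[starts + w] - cr[starts]
        nr_sh = cr[starts + w + shoulder_bp] - cr[starts + w]
        n_f = nf_fp + nf_sh
        n_r = nr_fp + nr_sh
        n_max = int(max(n_f.max(initial=0), n_r.max(initial=0)))
        tab = cache.table(w, shoulder_bp, n_max)
        score = -(tab[n_f, nf_fp] + tab[n_r, nr_fp])
        score[(nf_sh == 0) | (nr_sh == 0)] = 0.0
        improved = score > best[starts]
        best[starts] = np.where(improved, score, best[starts])
        best_w[starts] = np.where(improved, w, best_w[starts])
    return best, best_w


def call_footprints(
    cut_tracks: Mapping[str, tuple[np.ndarray, np.ndarray]],
    regions: Sequence[GenomicInterval],
    widths: Sequence[int] = tuple(range(11, 26, 2)),
    shoulder_bp: int = 35,
    fdr: float = 0.01,
    n_shuffles: int = 20,
    seed: int = 0,
) -> list[FootprintCall]:
    """Call footprints in accessible regions with a shuffle-calibrated threshold.

    ``cut_tracks`` maps chrom -> (fwd, rev) dense per-base cut counts. Per
    region, each position keeps its best score over ``widths``; the score
    threshold is the (1 - fdr) quantile of per-region max scores from
    ``n_shuffles`` within-region cut shuffles (uniform multinomial
    redistribution preserving each strand's total). Overlapping candidates are
    resolved greedily by score. Deterministic for a fixed seed.
    """
    if not regions:
        return []
    rng = np.random.default_rng(seed)
    cache = _LogCdfCache()
    max_w = max(widths)

    extracted = []
    for reg in regions:
        fwd_all, rev_all = cut_tracks[reg.chrom]
        lo = max(0, reg.start - shoulder_bp)
        hi = min(len(fwd_all), reg.end + shoulder_bp)
        if hi - lo < 2 * shoulder_bp + max_w:
            extracted.append(None)
            continue
        extracted.append((reg, lo, np.asarray(fwd_all[lo:hi]), np.asarray(rev_all[lo:hi])))

    null_maxima: list[float] = []
    for item in extracted:
        if item is None:
            continue
        _, _, fwd, rev = item
        nf, nr, L = int(fwd.sum()), int(rev.sum()), len(fwd)
        for _ in range(n_shuffles):
            sf = rng.multinomial(nf, np.full(L, 1.0 / L))
            sr = rng.multinomial(nr, np.full(L, 1.0 / L))
            s, _w = _score_region(sf, sr, widths, shoulder_bp, cache)
            null_maxima.append(float(s.max(initial=0.0)))
    threshold = float(np.quantile(null_maxima, 1.0 - fdr)) if null_maxima else np.inf

    calls: list[FootprintCall] = []
    for item in extracted:
        if item is None:
            continue
        reg, lo, fwd, rev = item
        scores, best_w = _score_region(fwd, rev, widths, shoulder_bp, cache)
        cand = np.flatnonzero(scores > threshold)
        order = cand[np.argsort(-scores[cand], kind="stable")]
        taken = np.zeros(len(fwd), dtype=bool)
        for pos in order:
            w = int(best_w[pos])
            if taken[pos: pos + w].any():
                continue
            taken[pos: pos + w] = True
            calls.append(
                FootprintCall(
                    interval=GenomicInterval(
                        reg.chrom, lo + int(pos), lo + int(pos) + w,
                        score=float(scores[pos]),
                        name=f"fp_{reg.chrom}_{lo + int(pos)}",
                    ),
                    score=float(scores[pos]),
                    footprint_width=w,
                    shoulder_bp=shoulder_bp,
                )
            )
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _pwm_to_logodds(pwm: Mapping[str, Sequence[float]], background: float = 0.25,
                    eps: float = 1e-4) -> np.ndarray:
    mat = np.array([pwm[b] for b in "ACGT"], dtype=float)
    colsums = mat.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError("PWM has a zero column sum")
    if np.any(np.abs(colsums - 1.0) > 1e-6):
        raise ValueError("PWM columns must sum to 1 within 1e-6")
    return np.log2(np.maximum(mat, eps) / background)


def scan_motifs(
    sequences: Mapping[str, str],
    pwm: Mapping[str, Sequence[float]],
    log_odds_threshold: float,
    motif_id: str = "motif",
) -> list[MotifHit]:
    """Both-strand log-odds PWM scan over sequences keyed by chromosome name.

    ``pwm`` maps base -> per-position probabilities (columns sum to 1). Hits
    with log-odds >= threshold are reported; overlapping same-motif hits are
    deduplicated keeping the best score (ties: + strand, then leftmost).
    """
    lo = _pwm_to_logodds(pwm)
    w = lo.shape[1]
    raw: list[MotifHit] = []
    for chrom, seq in sequences.items():
        su = seq.upper()
        n = len(su)
        if n < w:
            continue
        codes = np.full(n, -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            codes[np.frombuffer(su.encode(), dtype=np.uint8) == ord(b)] = i
        valid = codes >= 0
        fwd_scores = np.zeros(n - w + 1)
        ok = np.ones(n - w + 1, dtype=bool)
        for off in range(w):
            c = codes[off: off + n - w + 1]
            ok &= valid[off: off + n - w + 1]
            fwd_scores += np.where(c >= 0, lo[np.clip(c, 0, 3), off], 0.0)
        # reverse strand: score of reverse complement at the same window
        lo_rc = lo[::-1, ::-1]
        rev_scores = np.zeros(n - w + 1)
        for off in range(w):
            c = codes[off: off + n - w + 1]
            rev_scores += np.where(c >= 0, lo_rc[np.clip(c, 0, 3), off], 0.0)
        for strand, scores in (("+", fwd_scores), ("-", rev_scores)):
            hits = np.flatnonzero(ok & (scores >= log_odds_threshold))
            for pos in hits:
                raw.append(
                    MotifHit(
                        motif_id,
                        GenomicInterval(chrom, int(pos), int(pos) + w,
                                        strand=strand, score=float(scores[pos]),
                                        name=motif_id),
                        strand,
                        float(scores[pos]),
                    )
                )
    # dedupe overlapping hits of the same motif, best score wins
    raw.sort(key=lambda h: (h.interval.chrom, -h.score, h.strand != "+", h.interval.start))
    kept: list[MotifHit] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for h in raw:
        spans = occupied.setdefault(h.interval.chrom, [])
        if any(h.interval.start < e and s < h.interval.end for s, e in spans):
            continue
        spans.append((h.interval.start, h.interval.end))
        kept.append(h)
    kept.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return kept


def load_jaspar_pwm(path) -> dict[str, dict[str, list[float]]]:
    """Read JASPAR-format PWM text into {motif_id: {base: probabilities}}."""
    from Bio import motifs as bio_motifs

    out = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = {b: list(m.counts[b]) for b in "ACGT"}
            totals = [sum(counts[b][i] for b in "ACGT") for i in range(m.length)]
            out[m.matrix_id or m.name] = {
                b: [counts[b][i] / totals[i] if totals[i] else 0.0 for i in range(m.length)]
                for b in "ACGT"
            }
    return out


def footprint_motif_occupancy(
    footprints_by_timepoint: Mapping[str, Sequence[FootprintCall]],
    motif_hits: Sequence[MotifHit],
) -> tuple[dict[str, MotifOccupancySet], pd.DataFrame]:
    """Footprinted status of every motif instance per time point.

    A motif instance is footprinted at t iff its midpoint lies inside a
    footprint call at t. Returns the per-time-point occupancy sets and a
    per-motif summary with footprinted fractions over time and a Fisher exact
    two-proportion comparison between consecutive time points (BH-adjusted
    across motifs and transitions).
    """
    tps = list(footprints_by_timepoint)
    occ_sets: dict[str, MotifOccupancySet] = {}
    for tp in tps:
        ix = IntervalIndex([fp.interval for fp in footprints_by_timepoint[tp]])
        flags = np.array(
            [bool(ix.containing_point(h.interval.chrom, h.interval.center))
             for h in motif_hits],
            dtype=bool,
        )
        occ_sets[tp] = MotifOccupancySet(tp, list(motif_hits), flags)

    motif_ids = sorted({h.motif_id for h in motif_hits})
    rows = []
    for m in motif_ids:
        idx = np.array([h.motif_id == m for h in motif_hits], dtype=bool)
        n = int(idx.sum())
        row = {"motif_id": m, "n_instances": n}
        for tp in tps:
            row[f"frac_{tp}"] = (
                float(occ_sets[tp].footprinted[idx].mean()) if n else np.nan
            )
        rows.append(row)
    summary = pd.DataFrame(rows)

    pvals, keys = [], []
    for m in motif_ids:
        idx = np.array([h.motif_id == m for h in motif_hits], dtype=bool)
        n = int(idx.sum())
        for a, b in zip(tps[:-1], tps[1:]):
            ka = int(occ_sets[a].footprinted[idx].sum())
            kb = int(occ_sets[b].footprinted[idx].sum())
            if n == 0:
                p = np.nan
            else:
                _, p = stats.fisher_exact([[kb, n - kb], [ka, n - ka]])
            pvals.append(p)
            keys.append((m, a, b))
    adj = np.full(len(pvals), np.nan)
    finite = ~np.isnan(pvals)
    if finite.any():
        adj[finite] = multipletests(np.array(pvals)[finite], method="fdr_bh")[1]
    for (m, a, b), p, q in zip(keys, pvals, adj):
        summary.loc[summary["motif_id"] == m, f"p_{b}_vs_{a}"] = p
        summary.loc[summary["motif_id"] == m, f"q_{b}_vs_{a}"] = q
    return occ_sets, summary


def cooccurrence_enrichment(
    occupancy_t1: MotifOccupancySet,
    occupancy_t2: MotifOccupancySet,
    window_bp: int = 200,
) -> pd.DataFrame:
    """Pairwise motif co-occurrence enrichment at t2 vs t1 within 200-bp regions.

    For each unordered motif pair {A, B}, a footprinted instance of one motif
    "co-occurs" when a footprinted instance of the other lies within
    +/- window_bp/2 of its midpoint (for A == B, a distinct instance). The 2x2
    table (co-occurring vs not, t2 vs t1) over footprinted instances gives a
    Fisher exact odds ratio and p-value, BH-adjusted across pairs; zero
    marginals get the Haldane-Anscombe +0.5 correction (flagged). Rows carry
    an average-linkage display order on the log-odds matrix.
    """
    half = window_bp // 2

    def footprinted_mids(occ: MotifOccupancySet) -> dict[str, list[tuple[str, int]]]:
        out: dict[str, list[tuple[str, int]]] = {}
        for h, fp in zip(occ.hits, occ.footprinted):
            if fp:
                out.setdefault(h.motif_id, []).append((h.interval.chrom, h.interval.center))
        return out

    def counts(mids: dict[str, list[tuple[str, int]]], a: str, b: str) -> tuple[int, int]:
        """(#co-occurring instances, #instances) pooled symmetrically."""
        pa = mids.get(a, [])
        pb = mids.get(b, [])
        by_chrom_b: dict[str, np.ndarray] = {}
        for chrom, c in pb:
            by_chrom_b.setdefault(chrom, []).append(c)
        by_chrom_b = {c: np.sort(np.array(v)) for c, v in by_chrom_b.items()}

        def near(points, targets_by_chrom, self_pair):
            k = 0
            for chrom, c in points:
                arr = targets_by_chrom.get(chrom)
                if arr is None:
                    continue
                n_near = int(
                    np.searchsorted(arr, c + half, side="right")
                    - np.searchsorted(arr, c - half, side="left")
                )
                if self_pair:
                    n_near -= 1  # the instance itself
                if n_near > 0:
                    k += 1
            return k

        if a == b:
            return near(pa, by_chrom_b, True), len(pa)
        by_chrom_a: dict[str, np.ndarray] = {}
        for chrom, c in pa:
            by_chrom_a.setdefault(chrom, []).append(c)
        by_chrom_a = {c: np.sort(np.array(v)) for c, v in by_chrom_a.items()}
        return (
            near(pa, by_chrom_b, False) + near(pb, by_chrom_a, False),
            len(pa) + len(pb),
        )

    mids1 = footprinted_mids(occupancy_t1)
    mids2 = footprinted_mids(occupancy_t2)
    motif_ids = sorted({h.motif_id for h in occupancy_t1.hits}
                       | {h.motif_id for h in occupancy_t2.hits})
    rows = []
    for i, a in enumerate(motif_ids):
        for b in motif_ids[i:]:
            co2, n2 = counts(mids2, a, b)
            co1, n1 = counts(mids1, a, b)
            if co1 == 0 or co2 == 0 or (n2 - co2) == 0 or (n1 - co1) == 0:
                odds = ((co2 + 0.5) * (n1 - co1 + 0.5)) / ((n2 - co2 + 0.5) * (co1 + 0.5))
                corrected = True
            else:
                odds = (co2 * (n1 - co1)) / ((n2 - co2) * co1)
                corrected = False
            if n1 == 0 and n2 == 0:
                p = np.nan
            else:
                _, p = stats.fisher_exact([[co2, n2 - co2], [co1, n1 - co1]])
            rows.append({"motif_a": a, "motif_b": b, "co_t2": co2, "n_t2": n2,
                         "co_t1": co1, "n_t1": n1, "odds_ratio": odds,
                         "p_value": p, "corrected": corrected})
    df = pd.DataFrame(rows)
    if not df.empty:
        finite = df["p_value"].notna()
        df["adjusted_p"] = np.nan
        if finite.any():
            df.loc[finite, "adjusted_p"] = multipletests(
                df.loc[finite, "p_value"], method="fdr_bh"
            )[1]
        # average-linkage display order on the symmetric log-odds matrix
        k = len(motif_ids)
        logm = np.zeros((k, k))
        pos = {m: i for i, m in enumerate(motif_ids)}
        for _, r in df.iterrows():
            v = np.log(max(r["odds_ratio"], 1e-6))
            logm[pos[r["motif_a"]], pos[r["motif_b"]]] = v
            logm[pos[r["motif_b"]], pos[r["motif_a"]]] = v
        if k > 2:
            from scipy.spatial.distance import pdist

            order = hierarchy.leaves_list(hierarchy.average(pdist(logm)))
        else:
            order = np.arange(k)
        rank = {motif_ids[int(j)]: r for r, j in enumerate(order)}
        df["linkage_order_a"] = df["motif_a"].map(rank)
        df["linkage_order_b"] = df["motif_b"].map(rank)
    return df
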