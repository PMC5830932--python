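"""Differential expression, site-to-gene linkage, amplitude strata, and
short time-series trajectory clustering.

Differential genes are called between the uninduced (0 h) and committed
(pro-B) states on replicate FPKM values: |log2 FC| > log2(2), p < 0.01, and
FPKM >= 1 in at least one of the two states. The default test is a moderated
t on log2(FPKM + 0.1): each gene's variance is shrunk toward the gene-wide
mean with a prior weight of ``prior_df`` degrees of freedom, which restores
power at two replicates while keeping the thresholds the analysis is defined
by; ``moderated=False`` gives the plain Welch test.

Trajectories (log2 FC vs 0 h over the induced time points) are clustered in
the style of the Short Time-series Expression Miner: genes are assigned to
the nearest of a fixed set of candidate model profiles (integer steps per
transition), profile enrichment is assessed by permuting each gene's time
order, and correlated significant profiles are merged into display clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peaks import SiteCatalog

__all__ = [
    "ExpressionTable",
    "differential_genes",
    "assign_genes_to_sites",
    "stratify_by_amplitude",
    "stem_cluster",
    "cluster_trajectories",
    "site_count_and_distance_summary",
]

PSEUDOCOUNT = 0.1


class ConfigurationError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """genes x samples FPKM matrix with sample metadata and gene coordinates."""

    values: pd.DataFrame  # index gene_id, columns sample ids
    samples: pd.DataFrame  # index sample id; columns timepoint, replicate
    gene_coords: pd.DataFrame  # index gene_id; columns chrom, strand, tss
    truth: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            tp = self.samples.loc[s, "timepoint"]
            if tp not in seen:
                seen.append(tp)
        return seen

    def columns_at(self, timepoint: str) -> list[str]:
        return [s for s in self.values.columns
                if self.samples.loc[s, "timepoint"] == timepoint]

    def replicate_means(self) -> pd.DataFrame:
        """gene x timepoint matrix of replicate-mean FPKM."""
        return pd.DataFrame(
            {tp: self.values[self.columns_at(tp)].mean(axis=1) for tp in self.timepoints}
        )

    def write(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")


def differential_genes(
    table: ExpressionTable,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    min_fpkm: float = 1.0,
    baseline: str = "0h",
    final: str = "proB",
    moderated: bool = True,
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Differential genes between baseline and final states.

    Returns one row per gene with replicate-mean FPKM at both ends, per-time-
    point log2 fold changes vs baseline (pseudocount 0.1), the test p-value,
    and ``is_de`` = |log2FC| > log2(fc_threshold) AND p < p_threshold AND
    (FPKM_baseline >= min_fpkm OR FPKM_final >= min_fpkm).
    """
    cols0 = table.columns_at(baseline)
    cols1 = table.columns_at(final)
    if len(cols0) < 2 or len(cols1) < 2:
        raise ConfigurationError(
            f"need >= 2 replicates at {baseline!r} and {final!r}"
        )
    means = table.replicate_means()
    x0 = np.log2(table.values[cols0].to_numpy() + PSEUDOCOUNT)
    x1 = np.log2(table.values[cols1].to_numpy() + PSEUDOCOUNT)
    n0, n1 = x0.shape[1], x1.shape[1]
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    v0 = x0.var(axis=1, ddof=1)
    v1 = x1.var(axis=1, ddof=1)
    delta = m1 - m0

    if moderated:
        df_g = n0 + n1 - 2
        s2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / df_g
        s2_prior = float(np.mean(s2))
        s2_mod = (prior_df * s2_prior + df_g * s2) / (prior_df + df_g)
        se = np.sqrt(s2_mod * (1.0 / n0 + 1.0 / n1))
        tstat = delta / np.maximum(se, 1e-12)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=prior_df + df_g)
    else:
        se2 = v0 / n0 + v1 / n1
        tstat = delta / np.maximum(np.sqrt(se2), 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            df_w = se2**2 / (
                (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)
            )
        df_w = np.where(np.isfinite(df_w) & (df_w > 0), df_w, n0 + n1 - 2)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_w)

    out = pd.DataFrame(index=table.values.index)
    out["fpkm_" + baseline] = means[baseline]
    out["fpkm_" + final] = means[final]
    for tp in table.timepoints:
        out[f"log2fc_{tp}"] = np.log2(
            (means[tp] + PSEUDOCOUNT) / (means[baseline] + PSEUDOCOUNT)
        )
    out["log2fc"] = out[f"log2fc_{final}"]
    out["p_value"] = pvals
    out["expressed"] = (means[baseline] >= min_fpkm) | (means[final] >= min_fpkm)
    out["is_de"] = (
        (np.abs(out["log2fc"]) > np.log2(fc_threshold))
        & (out["p_value"] < p_threshold)
        & out["expressed"]
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def assign_genes_to_sites(
    catalog: SiteCatalog,
    gene_models: pd.DataFrame,
    window_kb: float = 25.0,
) -> pd.DataFrame:
    """Nearest-TSS assignment of sites to genes within +/- ``window_kb``.

    ``gene_models`` is indexed by gene_id with columns chrom and tss. A site
    within the window of several TSSs is assigned only to the nearest (ties
    broken by lexicographically smaller gene_id). Returns one row per linked
    site: site_id, gene_id, distance (signed TSS - center), abs_distance.
    """
    window = int(window_kb * 1000)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in gene_models.groupby("chrom"):
        sub = sub.sort_values("tss")
        by_chrom[chrom] = (sub["tss"].to_numpy(), sub.index.to_numpy())
    rows = []
    for site in catalog.sites:
        if site.chrom not in by_chrom:
            continue
        tss, gids = by_chrom[site.chrom]
        d = tss - site.center
        ad = np.abs(d)
        within = ad <= window
        if not within.any():
            continue
        best = ad[within].min()
        cand = np.flatnonzero(within & (ad == best))
        gi = cand[np.argmin(gids[cand])] if len(cand) > 1 else cand[0]
        rows.append(
            {"site_id": site.name, "gene_id": gids[gi],
             "distance": int(d[gi]), "abs_distance": int(ad[gi])}
        )
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "distance", "abs_distance"])


def regulated_genes(de_table: pd.DataFrame, site_gene_map: pd.DataFrame) -> pd.Index:
    """DE genes with >= 1 assigned binding site (the factor-regulated set)."""
    bound = set(site_gene_map["gene_id"])
    de = de_table.index[de_table["is_de"]]
    return pd.Index([g for g in de if g in bound], name="gene_id")


def stratify_by_amplitude(de_table: pd.DataFrame, cutoff_fold: float = 10.0) -> pd.Series:
    """Split DE genes into stringent (>cutoff-fold) and lenient (2..cutoff-fold) strata.

    Strict inequality for the stringent stratum: a gene at exactly the cutoff
    is lenient. Indexed by DE gene; non-DE genes are absent.
    """
    de = de_table[de_table["is_de"]]
    fold = 2.0 ** np.abs(de["log2fc"])
    return pd.Series(
        np.where(fold > cutoff_fold, "stringent", "lenient"),
        index=de.index, name="amplitude_stratum",
    )


# ---------------------------------------------------------------------------
# STEM-style short time-series clustering


def _candidate_profiles(n_transitions: int, c: int) -> np.ndarray:
    """All integer-step trajectories starting at 0: cumulative sums of steps
    in {-c..c} per transition. Shape (m, n_transitions)."""
    steps = np.array(
        list(itertools.product(range(-c, c + 1), repeat=n_transitions)), dtype=float
    )
    return np.cumsum(steps, axis=1)


def _select_profiles(candidates: np.ndarray, n_profiles: int) -> np.ndarray:
    """Greedy max-min-distance subset; deterministic (ties lexicographic)."""
    m = candidates.shape[0]
    if n_profiles >= m:
        return np.arange(m)
    norms = np.linalg.norm(candidates, axis=1)
    order = np.lexsort(candidates.T[::-1])  # lexicographic candidate order
    lex_rank = np.empty(m, dtype=np.int64)
    lex_rank[order] = np.arange(m)
    first = np.flatnonzero(norms == norms.max())
    selected = [int(first[np.argmin(lex_rank[first])])]
    d = np.linalg.norm(candidates - candidates[selected[0]], axis=1)
    for _ in range(n_profiles - 1):
        best = np.flatnonzero(d == d.max())
        pick = int(best[np.argmin(lex_rank[best])])
        selected.append(pick)
        d = np.minimum(d, np.linalg.norm(candidates - candidates[pick], axis=1))
    return np.array(sorted(selected))


def _similarity(genes: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Pearson similarity gene x profile on vectors with the 0 h point prepended.

    Zero-variance vectors: two flats are perfectly similar; a flat against a
    non-flat is maximally dissimilar.
    """
    g = np.concatenate([np.zeros((genes.shape[0], 1)), genes], axis=1)
    p = np.concatenate([np.zeros((profiles.shape[0], 1)), profiles], axis=1)
    gc = g - g.mean(axis=1, keepdims=True)
    pc = p - p.mean(axis=1, keepdims=True)
    gn = np.linalg.norm(gc, axis=1)
    pn = np.linalg.norm(pc, axis=1)
    sim = np.zeros((g.shape[0], p.shape[0]))
    nz_g = gn > 1e-12
    nz_p = pn > 1e-12
    if nz_g.any() and nz_p.any():
        sim[np.ix_(nz_g, nz_p)] = (
            gc[nz_g] @ pc[nz_p].T / np.outer(gn[nz_g], pn[nz_p])
        )
    # flat-vs-flat: similarity 1; flat-vs-nonflat: -2 (never preferred)
    sim[np.ix_(~nz_g, ~nz_p)] = 1.0
    sim[np.ix_(~nz_g, nz_p)] = -2.0
    sim[np.ix_(nz_g, ~nz_p)] = -2.0
    return sim


def stem_cluster(
    de_gene_profiles: pd.DataFrame,
    c: int = 2,
    n_model_profiles: int = 6,
    n_permutations: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    merge_corr: float = 0.7,
    label_prefix: str = "P",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign trajectories to model profiles and test profile enrichment.

    ``de_gene_profiles``: genes x ordered induced time points, log2 FC vs 0 h.
    Candidate model profiles are integer-step trajectories (steps in {-c..c})
    starting at 0; ``n_model_profiles`` are kept by greedy max-min-distance
    selection and each gene goes to the Pearson-nearest profile (the implicit
    0 h point included). The default profile count is matched to the
    4-point grid: beyond ~6 profiles the greedy set contains pairs whose
    trajectories correlate above the merge threshold, i.e. duplicates of the
    same shape family rather than new resolvable shapes. Profile significance compares the observed member
    count with its expectation under per-gene time-order permutations
    (binomial upper tail, Bonferroni over profiles). Significant profiles
    whose trajectories correlate >= ``merge_corr`` are merged into display
    clusters, labelled by decreasing size.

    Returns (assignments, profiles): per-gene profile_id/cluster_label and the
    per-profile table (trajectory, member count, expected count, p-values).
    """
    if de_gene_profiles.shape[1] < 2:
        raise ConfigurationError("need >= 3 time points (>= 2 induced) to cluster")
    X = de_gene_profiles.to_numpy(dtype=float)
    n_genes, n_t = X.shape
    rng = np.random.default_rng(seed)

    candidates = _candidate_profiles(n_t, c)
    keep = _select_profiles(candidates, n_model_profiles)
    profiles = candidates[keep]
    m = profiles.shape[0]

    sim = _similarity(X, profiles)
    assigned = sim.argmax(axis=1)  # ties -> lowest profile index
    observed = np.bincount(assigned, minlength=m)

    # permutation null: shuffle each gene's time order (0 h point included),
    # re-reference to the permuted first point, re-assign
    full = np.concatenate([np.zeros((n_genes, 1)), X], axis=1)
    perms = list(itertools.permutations(range(n_t + 1)))
    if len(perms) > n_permutations:
        idx = rng.choice(len(perms), size=n_permutations, replace=False)
        perms = [perms[i] for i in sorted(idx)]
    expected = np.zeros(m)
    for perm in perms:
        Y = full[:, perm]
        Y = Y[:, 1:] - Y[:, [0]]
        expected += np.bincount(
            _similarity(Y, profiles).argmax(axis=1), minlength=m
        )
    expected /= len(perms)

    p_profile = np.array(
        [
            stats.binom.sf(observed[j] - 1, n_genes, min(1.0, expected[j] / n_genes))
            if expected[j] > 0
            else (1.0 if observed[j] == 0 else 0.0)
            for j in range(m)
        ]
    )
    p_bonf = np.minimum(1.0, p_profile * m)
    significant = p_bonf < alpha

    # merge correlated significant profiles into display clusters
    labels = np.full(m, "", dtype=object)
    sig_idx = np.flatnonzero(significant)
    if sig_idx.size:
        corr = np.corrcoef(
            np.concatenate([np.zeros((m, 1)), profiles], axis=1)[sig_idx]
        )
        corr = np.atleast_2d(corr)
        parent = list(range(sig_idx.size))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a in range(sig_idx.size):
            for b in range(a + 1, sig_idx.size):
                if corr[a, b] >= merge_corr:
                    parent[find(a)] = find(b)
        comp: dict[int, list[int]] = {}
        for a in range(sig_idx.size):
            comp.setdefault(find(a), []).append(a)
        sizes = {
            root: int(observed[sig_idx[members]].sum())
            for root, members in comp.items()
        }
        for rank, root in enumerate(
            sorted(comp, key=lambda r: (-sizes[r], min(comp[r]))), start=1
        ):
            for a in comp[root]:
                labels[sig_idx[a]] = f"{label_prefix}{rank}"

    profile_table = pd.DataFrame(
        {
            "profile_id": np.arange(m),
            "trajectory": [tuple(p) for p in profiles],
            "n_genes": observed,
            "expected_genes": expected,
            "p_value": p_profile,
            "p_bonferroni": p_bonf,
            "significant": significant,
            "cluster_label": labels,
        }
    )
    assignments = pd.DataFrame(
        {
            "gene_id": de_gene_profiles.index,
            "profile_id": assigned,
            "similarity": sim[np.arange(n_genes), assigned],
            "cluster_label": labels[assigned],
            "profile_significant": significant[assigned],
        }
    ).set_index("gene_id")
    return assignments, profile_table


def cluster_trajectories(
    de_table: pd.DataFrame,
    timepoints: Sequence[str] = ("24h", "72h", "proB"),
    **stem_kwargs,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Cluster up- and down-regulated DE genes separately (labels U*/D*)."""
    cols = [f"log2fc_{tp}" for tp in timepoints]
    de = de_table[de_table["is_de"]]
    out = []
    profile_tables = {}
    for direction, prefix in (("up", "U"), ("down", "D")):
        sub = de[de["direction"] == direction]
        if sub.empty:
            continue
        prof = sub[cols].rename(columns=dict(zip(cols, timepoints)))
        assign, ptable = stem_cluster(prof, label_prefix=prefix, **stem_kwargs)
        assign["direction"] = direction
        out.append(assign)
        profile_tables[direction] = ptable
    assignments = pd.concat(out) if out else pd.DataFrame()
    return assignments, profile_tables


def site_count_and_distance_summary(
    site_gene_map: pd.DataFrame,
    de_table: pd.DataFrame,
    unchanged_fold: float = 1.5,
    min_fpkm: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sites-per-gene and nearest-site distance by regulation group.

    Groups: up- and down-regulated DE genes and an unchanged control set
    (|FC| < unchanged_fold, FPKM >= min_fpkm at both ends). Group differences
    are Mann-Whitney U tests against the unchanged set, BH-adjusted.

    Returns (per_gene, tests).
    """
    counts = site_gene_map.groupby("gene_id").size()
    nearest = site_gene_map.groupby("gene_id")["abs_distance"].min()

    fpkm_cols = [c for c in de_table.columns if c.startswith("fpkm_")]
    unchanged = de_table[
        (np.abs(de_table["log2fc"]) < np.log2(unchanged_fold))
        & (de_table[fpkm_cols] >= min_fpkm).all(axis=1)
    ].index
    groups = {
        "up": de_table.index[(de_table["is_de"]) & (de_table["direction"] == "up")],
        "down": de_table.index[(de_table["is_de"]) & (de_table["direction"] == "down")],
        "unchanged": unchanged,
    }
    rows = []
    for name, genes in groups.items():
        for g in genes:
            rows.append(
                {"gene_id": g, "group": name,
                 "n_sites": int(counts.get(g, 0)),
                 "nearest_distance": float(nearest.get(g, np.nan))}
            )
    per_gene = pd.DataFrame(rows)

    tests = []
    base = per_gene[per_gene["group"] == "unchanged"]
    for name in ("up", "down"):
        sub = per_gene[per_gene["group"] == name]
        for metric in ("n_sites", "nearest_distance"):
            a = sub[metric].dropna()
            b = base[metric].dropna()
            if len(a) == 0 or len(b) == 0:
                tests.append({"group": name, "metric": metric, "p_value": np.nan,
                              "missing": True})
                continue
            _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            tests.append({"group": name, "metric": metric, "p_value": float(p),
                          "missing": False})
    tests = pd.DataFrame(tests)
    ok = tests["p_value"].notna()
    tests["adjusted_p"] = np.nan
    if ok.any():
        tests.loc[ok, "adjusted_p"] = multipletests(
            tests.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    return per_gene, tests
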