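"""Planted-truth benchmarks: run each stage on synthetic data and score it.

Each function regenerates its inputs from a seed at the study's stated
conditions (site counts, depths, noise levels), runs the corresponding
analysis, and returns the measured recovery statistics. Used by the
acceptance tests and the acceptance script; none of these functions read
anything from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dependency import classify_dependence, dependence_accessibility_summary, early_occupancy_overlap
from .expression import (
    ExpressionTable,
    cluster_trajectories,
    differential_genes,
    stem_cluster,
    stratify_by_amplitude,
)
from .footprints import call_footprints
from .intervals import GenomicInterval, IntervalIndex
from .methylation import methylation_dynamics, site_methylation
from .peaks import SiteCatalog, build_site_catalog, classify_temporal, motif_fraction_by_class
from .synthetic import (
    CLASS_OCCUPANCY,
    EXPRESSION_TEMPLATES,
    NoiseModel,
    SyntheticGenome,
    TIMEPOINTS,
    generate_dependency_scenario,
    generate_genome,
    generate_methylome,
    generate_timecourse_peaks,
)

__all__ = [
    "truth_catalog",
    "temporal_recovery",
    "footprint_benchmark",
    "methylation_recovery",
    "de_benchmark",
    "stem_benchmark",
    "dependence_benchmark",
    "early_overlap_benchmark",
]


def truth_catalog(genome: SyntheticGenome, width: int = 200) -> SiteCatalog:
    """Noise-free catalog straight from the planted sites (truth labels)."""
    sites = [
        GenomicInterval(s.chrom, max(0, s.center - width // 2),
                        s.center + width // 2, name=s.site_id)
        for s in genome.sites
    ]
    tps = [tp for tp in TIMEPOINTS if tp != "0h"]
    occ = np.zeros((len(sites), len(tps)), dtype=np.uint8)
    for i, s in enumerate(genome.sites):
        for t, tp in enumerate(tps):
            occ[i, t] = tp in CLASS_OCCUPANCY[s.true_class]
    cat = SiteCatalog(sites=sites, occupancy=occ, timepoints=tps)
    cat.classes = {s.site_id: s.true_class for s in genome.sites}
    return cat


def temporal_recovery(
    seed: int,
    n_sites: int = 500,
    dropout: float = 0.05,
    n_replicates: int = 2,
    replicate_rule: str = "pooled",
) -> dict:
    """Five-class temporal label recovery on noisy peak calls.

    Builds the catalog from simulated ChIP peaks (occupancy from pooled
    replicate evidence by default), classifies, and scores each planted site:
    correct iff its center falls in a catalog site carrying its true class.
    """
    genome = generate_genome(n_sites=n_sites, seed=seed)
    noise = NoiseModel(peak_dropout_prob=dropout, seed=seed + 101)
    chip = generate_timecourse_peaks(genome, noise, TIMEPOINTS, n_replicates, "chip")
    atac = generate_timecourse_peaks(genome, noise, TIMEPOINTS, n_replicates, "atac")

    def sets_for(peaks, tp):
        reps = [peaks[(tp, f"rep{r + 1}")] for r in range(n_replicates)]
        if replicate_rule == "pooled":
            return [p for rep in reps for p in rep]
        from .peaks import replicate_consensus

        return replicate_consensus(reps)

    catalog = build_site_catalog(
        {tp: sets_for(chip, tp) for tp in TIMEPOINTS if tp != "0h"}
    )
    ix0 = IntervalIndex(sets_for(atac, "0h"))
    accessible_0h = np.array(
        [ix0.any_overlap(s.chrom, s.start, s.end) for s in catalog.sites]
    )
    classify_temporal(catalog, accessible_0h=accessible_0h)

    cix = IntervalIndex(catalog.sites)
    labels = catalog.class_array()
    correct = 0
    for s in genome.sites:
        hits = cix.containing_point(s.chrom, s.center)
        if hits and labels[hits[0]] == s.true_class:
            correct += 1
    motif_frac = motif_fraction_by_class(
        catalog,
        [GenomicInterval(s.chrom, s.center - 7, s.center + 7)
         for s in genome.sites if s.has_canonical_motif],
    )
    return {
        "accuracy": correct / len(genome.sites),
        "n_sites": len(genome.sites),
        "n_catalog": len(catalog),
        "catalog": catalog,
        "genome": genome,
        "motif_fraction_by_class": motif_frac,
    }


def atac_frequency_benchmark(seed: int, n_sites: int = 500) -> dict:
    """Recovery of planted site-containing fractions in ATAC-peak clusters.

    ATAC peaks pooled by first-accessible stage contain a binding site with
    planted cluster fractions (~0.9 at 24 h down to ~0.42 at the committed
    stage); measured against the truth catalog.
    """
    from .signal import atac_peak_site_frequency

    genome = generate_genome(n_sites=n_sites, seed=seed)
    noise = NoiseModel(peak_dropout_prob=0.0, seed=seed + 505)
    atac = generate_timecourse_peaks(genome, noise, TIMEPOINTS, 1, "atac")
    catalog = truth_catalog(genome)
    freq = atac_peak_site_frequency(
        {tp: atac[(tp, "rep1")] for tp in TIMEPOINTS}, catalog
    ).set_index("cluster")
    return {
        "site_fraction_24h": float(freq.loc["24h", "site_fraction"]),
        "site_fraction_proB": float(freq.loc["proB", "site_fraction"]),
        "table": freq,
    }


def footprint_benchmark(
    seed: int,
    n_true: int = 500,
    n_null: int = 500,
    coverage: float = 30.0,
    region_bp: int = 200,
    fp_width: int = 15,
    shoulder_bp: int = 35,
    protection: float = 0.15,
    fdr: float = 0.01,
    n_shuffles: int = 20,
) -> dict:
    """Planted-footprint sensitivity and empirical FDR.

    ``coverage`` is the mean per-base cut coverage (both strands combined) in
    accessible chromatin, i.e. 30 means a 30x cut pile-up outside footprints.
    True regions carry a centered footprint of ``fp_width`` (interior rate
    ``protection`` x shoulder rate); null regions are uniformly accessible at
    the shoulder rate. Sensitivity = fraction of true regions with a call
    overlapping the planted footprint; empirical FDR = calls in null regions
    / all calls.
    """
    rng = np.random.default_rng(seed)
    rate = coverage / 2.0  # per strand per base
    gap = 200
    span = region_bp + gap
    total = n_true + n_null
    chrom_len = total * span + 2 * gap
    fwd = np.zeros(chrom_len, dtype=np.int64)
    rev = np.zeros(chrom_len, dtype=np.int64)
    regions, truth_fp = [], []
    for i in range(total):
        start = gap + i * span
        end = start + region_bp
        is_true = i < n_true
        rates = np.full(region_bp, rate)
        if is_true:
            c = region_bp // 2
            lo = c - fp_width // 2
            rates[lo: lo + fp_width] = protection * rate
            truth_fp.append((start + lo, start + lo + fp_width))
        else:
            truth_fp.append(None)
        fwd[start:end] = rng.poisson(rates)
        rev[start:end] = rng.poisson(rates)
        regions.append(GenomicInterval("chrSim", start, end, name=f"reg_{i}"))
    calls = call_footprints(
        {"chrSim": (fwd, rev)}, regions,
        shoulder_bp=shoulder_bp, fdr=fdr, n_shuffles=n_shuffles, seed=seed + 7,
    )
    # attribute each call to its region by position
    call_region = [(c.interval.start - gap) // span for c in calls]
    hit = np.zeros(n_true, dtype=bool)
    n_null_calls = 0
    for c, ri in zip(calls, call_region):
        if ri < n_true:
            lo, hi = truth_fp[ri]
            if c.interval.start < hi and lo < c.interval.end:
                hit[ri] = True
        else:
            n_null_calls += 1
    n_calls = len(calls)
    return {
        "sensitivity": float(hit.mean()),
        "empirical_fdr": n_null_calls / n_calls if n_calls else 0.0,
        "n_calls": n_calls,
        "n_true": n_true,
        "n_null": n_null,
    }


def methylation_recovery(seed: int, n_sites: int = 200, coverage: float = 30.0) -> dict:
    """Planted demethylation kinetics as class medians.

    Half the sites follow the persistent profile (0.8, 0.8, 0.65, 0.2), half
    the transient profile (flat after 72 h); every site is LMR-associated so
    the +/-100-bp windows carry dense CpGs.
    """
    genome = generate_genome(
        n_sites=n_sites, seed=seed,
        class_proportions={"gain24": 0.5, "transient": 0.5},
        lmr_prob=1.0,
    )
    noise = NoiseModel(meth_coverage=coverage, seed=seed + 202)
    meth = generate_methylome(genome, noise)
    catalog = truth_catalog(genome)
    site_meth = {tp: site_methylation(meth[tp], catalog) for tp in meth}
    cloud, summary = methylation_dynamics(site_meth, catalog, lmr_set=None)
    summary = summary.set_index("class")
    return {
        "persistent_delta_proB_72h": float(summary.loc["persistent", "delta_proB_72h"]),
        "persistent_delta_72h_24h": float(summary.loc["persistent", "delta_72h_24h"]),
        "transient_delta_proB_72h": float(summary.loc["transient", "delta_proB_72h"]),
        "n_sites": int(cloud.shape[0]),
        "cloud": cloud,
        "summary": summary,
    }


def make_de_table(
    seed: int,
    n_genes: int = 500,
    n_de: int = 100,
    effect_fold: float = 4.0,
    sigma: float = 0.25,
    n_low: int = 50,
    n_replicates: int = 2,
    timepoints=("0h", "24h", "72h", "proB"),
) -> ExpressionTable:
    """Planted differential-expression table (no genome needed).

    ``n_de`` genes change by ``effect_fold`` between 0 h and the final stage
    (half up, half down, ramping linearly over induced time points); ``n_low``
    additional low-expression genes (FPKM < 1 at both ends) also change, to
    exercise the expression filter; the rest are null. Truth in
    ``table.truth``.
    """
    rng = np.random.default_rng(seed)
    tps = list(timepoints)
    induced = tps[1:]
    effect = np.log2(effect_fold)
    rows = []
    gene_ids = [f"g{j:04d}" for j in range(n_genes + n_low)]
    samples = [(tp, f"rep{r + 1}") for tp in tps for r in range(n_replicates)]
    values = np.zeros((len(gene_ids), len(samples)))
    for j, gid in enumerate(gene_ids):
        if j < n_de:
            kind = "de_up" if j % 2 == 0 else "de_down"
            base = 2.0 ** rng.normal(3.0, 0.5)
        elif j < n_genes:
            kind = "null"
            base = 2.0 ** rng.normal(3.0, 0.5)
        else:
            kind = "low"
            # stays below FPKM 1 at both ends even after the planted fold
            # change and replicate noise
            base = float(rng.uniform(0.02, 0.12))
        ramp = np.linspace(1.0 / len(induced), 1.0, len(induced))
        lfc = {tp: 0.0 for tp in tps}
        if kind in ("de_up", "de_down", "low"):
            sign = -1.0 if kind == "de_down" else 1.0
            for tp, f in zip(induced, ramp):
                lfc[tp] = sign * effect * f
        for sj, (tp, rep) in enumerate(samples):
            values[j, sj] = base * 2.0 ** (lfc[tp] + rng.normal(0.0, sigma))
        rows.append({"gene_id": gid, "kind": kind})
    frame = pd.DataFrame(values, index=gene_ids,
                         columns=[f"{tp}_{rep}" for tp, rep in samples])
    meta = pd.DataFrame(
        {"sample": frame.columns, "timepoint": [tp for tp, _ in samples],
         "replicate": [rep for _, rep in samples]}
    ).set_index("sample")
    coords = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": "chr1", "strand": "+",
         "tss": 1000 + 5000 * np.arange(len(gene_ids))}
    ).set_index("gene_id")
    table = ExpressionTable(values=frame, samples=meta, gene_coords=coords)
    table.truth = pd.DataFrame(rows).set_index("gene_id")
    return table


def de_benchmark(seed: int, n_seeds: int = 10, **table_kwargs) -> dict:
    """DE sensitivity / false positives over repeated planted tables."""
    sens, fps, low_called = [], [], []
    for k in range(n_seeds):
        table = make_de_table(seed + k, **table_kwargs)
        de = differential_genes(table)
        truth = table.truth["kind"]
        is_de = de["is_de"]
        true_de = truth.isin(["de_up", "de_down"])
        sens.append(float(is_de[true_de].mean()))
        fps.append(int(is_de[truth == "null"].sum()))
        low_called.append(int(is_de[truth == "low"].sum()))
    return {
        "sensitivity_mean": float(np.mean(sens)),
        "sensitivity_min": float(np.min(sens)),
        "false_positives_mean": float(np.mean(fps)),
        "false_positives_max": int(np.max(fps)),
        "low_expression_called": int(np.sum(low_called)),
        "n_seeds": n_seeds,
    }


def stem_benchmark(
    seed: int,
    n_genes: int = 500,
    sigma: float = 0.3,
    templates: dict[str, tuple[float, ...]] | None = None,
) -> dict:
    """Trajectory-profile recovery for the five planted templates.

    A gene is correctly assigned iff it lands on the same model profile as its
    noiseless template. Up and down templates are clustered separately, as in
    the analysis itself.
    """
    templates = dict(templates or EXPRESSION_TEMPLATES)
    rng = np.random.default_rng(seed)
    names = sorted(templates)
    assign_truth = [names[i % len(names)] for i in range(n_genes)]
    X = np.array([templates[t] for t in assign_truth], dtype=float)
    X += rng.normal(0.0, sigma, size=X.shape)
    profiles = pd.DataFrame(X, columns=["24h", "72h", "proB"],
                            index=[f"g{j:04d}" for j in range(n_genes)])
    up_templates = {t for t in names if templates[t][-1] > 0}

    correct = 0
    n_sig_profiles = 0
    for direction_up in (True, False):
        members = [j for j, t in enumerate(assign_truth)
                   if (t in up_templates) == direction_up]
        if not members:
            continue
        sub = profiles.iloc[members]
        assign, ptable = stem_cluster(sub, seed=seed + 11)
        # reference assignment of the clean templates through the same model set
        clean = pd.DataFrame(
            [templates[t] for t in names if (t in up_templates) == direction_up],
            columns=["24h", "72h", "proB"],
            index=[t for t in names if (t in up_templates) == direction_up],
        )
        ref, _ = stem_cluster(pd.concat([clean, sub]), seed=seed + 11)
        ref_profile = {t: ref.loc[t, "profile_id"] for t in clean.index}
        for j, g in zip(members, sub.index):
            if assign.loc[g, "profile_id"] == ref_profile[assign_truth[j]]:
                correct += 1
        n_sig_profiles += int(ptable["significant"].sum())
    return {
        "profile_accuracy": correct / n_genes,
        "n_genes": n_genes,
        "n_significant_profiles": n_sig_profiles,
    }


def stem_null_benchmark(seed: int, n_seeds: int = 5, n_genes: int = 200) -> dict:
    """Time-permuted null: count seeds with zero significant profiles.

    Null genes have exchangeable absolute log-expression over the four stages
    (a time-permuted trajectory), re-referenced to the first stage — exactly
    the null hypothesis the profile-enrichment permutation test encodes.
    """
    zero = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + k)
        abs_expr = rng.normal(0.0, 1.0, size=(n_genes, 4))
        X = abs_expr[:, 1:] - abs_expr[:, [0]]
        profiles = pd.DataFrame(X, columns=["24h", "72h", "proB"],
                                index=[f"g{j:04d}" for j in range(n_genes)])
        _, ptable = stem_cluster(profiles, seed=seed + 17 + k)
        if int(ptable["significant"].sum()) == 0:
            zero += 1
    return {"seeds_with_zero_significant": zero, "n_seeds": n_seeds}


def dependence_benchmark(seed: int, n_secondary: int = 400) -> dict:
    """Planted dependence-fraction recovery for cobound secondary sites."""
    genome = generate_genome(seed=seed)
    noise = NoiseModel(peak_dropout_prob=0.0, seed=seed + 303)
    scen = generate_dependency_scenario(genome, noise, n_secondary=n_secondary)
    cls = classify_dependence(
        scen["secondary_sites"], scen["knockout_peaks"], scen["pioneer_peaks"],
        central_rpkm_0h=scen["rpkm_0h"], central_rpkm_final=scen["rpkm_final"],
    )
    cobound = cls[cls["ebf1_cooccupied"]]
    frac_dep = float((~cobound["bound_without_ebf1"]).mean()) if len(cobound) else np.nan
    per_label, fisher = dependence_accessibility_summary(cls)
    per_label = per_label.set_index("label")
    dep_pre = per_label.loc[
        ["cobound_dependent", "solo_dependent"], ["n_accessible_pre", "n_sites"]
    ].sum()
    return {
        "cobound_dependent_fraction": frac_dep,
        "n_cobound": int(len(cobound)),
        "dependent_accessible_pre_fraction": float(
            dep_pre["n_accessible_pre"] / dep_pre["n_sites"]
        ),
        "independent_accessible_pre_fraction": float(
            per_label.loc["cobound_independent", "frac_accessible_pre"]
        ),
        "classification": cls,
        "per_label": per_label,
        "fisher": fisher,
    }


def early_overlap_benchmark(seed: int, n_sites: int = 500) -> dict:
    """Recovery of planted 6-h occupancy fractions (persistent vs transient)."""
    genome = generate_genome(n_sites=n_sites, seed=seed)
    noise = NoiseModel(peak_dropout_prob=0.0, seed=seed + 404)
    tps = ("0h", "6h", "24h", "72h", "proB")
    chip = generate_timecourse_peaks(genome, noise, tps, n_replicates=1, assay="chip")
    catalog = truth_catalog(genome)
    early = early_occupancy_overlap(catalog, chip[("6h", "rep1")]).set_index("group")
    return {
        "persistent_6h_fraction": float(early.loc["persistent", "fraction"]),
        "transient_6h_fraction": float(early.loc["transient_all", "fraction"]),
        "table": early,
    }
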