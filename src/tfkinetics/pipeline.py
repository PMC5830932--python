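"""End-to-end orchestration of the synthetic time-course analysis.

Stage order mirrors the assay panel: binding peaks -> accessibility signal ->
methylation -> footprints -> expression -> dependence. Each stage writes its
tables under the run directory and registers row counts and checksums in a
JSON manifest; re-running with the same master seed reproduces byte-identical
outputs. Stages whose inputs are unavailable are skipped and logged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, validate_config
from .dependency import (
    classify_dependence,
    dependence_accessibility_summary,
    early_occupancy_overlap,
)
from .expression import (
    assign_genes_to_sites,
    cluster_trajectories,
    differential_genes,
    regulated_genes,
    site_count_and_distance_summary,
    stratify_by_amplitude,
)
from .footprints import (
    MotifHit,
    call_footprints,
    cooccurrence_enrichment,
    footprint_motif_occupancy,
)
from .intervals import GenomicInterval, IntervalIndex
from .methylation import call_lmrs, methylation_dynamics, site_methylation
from .peaks import build_site_catalog, class_counts, classify_temporal, replicate_consensus
from .signal import (
    SignalTrack,
    atac_peak_site_frequency,
    central_depletion_profile,
    classify_accessibility,
    compute_signal_matrix,
    estimate_background_rpkm,
)
from .synthetic import (
    NoiseModel,
    generate_cut_counts,
    generate_dependency_scenario,
    generate_expression,
    generate_genome,
    generate_methylome,
    generate_timecourse_peaks,
)

STAGES = ("peaks", "signal", "methylation", "footprints", "expression", "dependency")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir, stages=None) -> dict:
    """Run the configured stages and return the manifest (also written as JSON).

    Synthetic mode regenerates all inputs deterministically from the master
    seed, so any stage subset can be re-run in isolation with identical
    results.
    """
    issues = validate_config(config)
    if issues:
        raise PipelineError("configuration invalid: " + "; ".join(issues))
    stages = list(STAGES if stages is None else stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = config.settings
    if not s["synthetic"]["enabled"]:
        raise PipelineError(
            "only synthetic mode is orchestrated end-to-end; run stage functions "
            "directly on external inputs"
        )

    manifest: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "stage_seeds": {k: config.stage_seed(k) for k in
                        ("genome", "noise", "footprints", "stem", "dependency")},
        "config": s,
        "stages": {},
        "outputs": {},
    }
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, sep="\t", index=True)
        written.append(p)
        return p

    timepoints = list(s["timepoints"])
    if s["include_6h"] and "6h" not in timepoints:
        timepoints = timepoints[:1] + ["6h"] + timepoints[1:]
    noise = NoiseModel(
        peak_dropout_prob=s["noise"]["peak_dropout_prob"],
        signal_depth=s["noise"]["signal_depth"],
        background_rate=s["noise"]["background_rate"],
        meth_coverage=s["noise"]["meth_coverage"],
        expr_dispersion=s["noise"]["expr_dispersion"],
        seed=config.stage_seed("noise"),
    )
    genome = generate_genome(
        n_chroms=s["synthetic"]["n_chroms"],
        chrom_len=s["synthetic"]["chrom_len"],
        n_genes=s["synthetic"]["n_genes"],
        n_sites=s["synthetic"]["n_sites"],
        seed=config.stage_seed("genome"),
        lmr_prob=s["synthetic"]["lmr_prob"],
    )
    genome.write_truth(outdir / "truth.json")
    written.append(outdir / "truth.json")
    n_reps = s["synthetic"]["n_replicates"]

    chip = generate_timecourse_peaks(genome, noise, timepoints, n_reps, assay="chip")
    atac = generate_timecourse_peaks(genome, noise, timepoints, n_reps, assay="atac")

    def consensus_by_tp(peaksets):
        return {
            tp: replicate_consensus(
                [peaksets[(tp, f"rep{r + 1}")] for r in range(n_reps)],
                min_overlap_bp=s["peaks"]["min_overlap_bp"],
            )
            for tp in timepoints
        }

    def pooled_by_tp(peaksets):
        return {
            tp: [p for r in range(n_reps) for p in peaksets[(tp, f"rep{r + 1}")]]
            for tp in timepoints
        }

    chip_consensus = consensus_by_tp(chip)
    atac_consensus = consensus_by_tp(atac)
    rule = s["peaks"].get("replicate_rule", "pooled")
    chip_occupancy = pooled_by_tp(chip) if rule == "pooled" else chip_consensus
    atac_occupancy = pooled_by_tp(atac) if rule == "pooled" else atac_consensus

    # ------------------------------------------------------------------ peaks
    catalog = build_site_catalog(
        {tp: chip_occupancy[tp] for tp in timepoints if tp != "0h"},
        merge_gap_bp=s["peaks"]["merge_gap_bp"],
    )
    atac0 = IntervalIndex(atac_occupancy.get("0h", []))
    accessible_0h = np.array(
        [atac0.any_overlap(site.chrom, site.start, site.end) for site in catalog.sites]
    )
    classify_temporal(catalog, accessible_0h=accessible_0h)
    if "peaks" in stages:
        catalog.write(outdir / "catalog.bed", outdir / "catalog.tsv")
        written += [outdir / "catalog.bed", outdir / "catalog.tsv"]
        counts = class_counts(catalog)
        emit(counts.rename("n_sites").to_frame(), "class_counts.tsv")
        manifest["stages"]["peaks"] = {
            "n_sites": len(catalog),
            "class_counts": {k: int(v) for k, v in counts.items()},
        }

    # ----------------------------------------------------------------- signal
    cuts = generate_cut_counts(genome, noise, timepoints)
    tracks = {tp: SignalTrack.from_cut_tracks(cuts[tp]) for tp in timepoints}
    if "signal" in stages:
        matrices = {
            tp: compute_signal_matrix(
                tracks[tp], catalog, s["signal"]["window_bp"], s["signal"]["bin_bp"]
            )
            for tp in timepoints
        }
        bg = estimate_background_rpkm(tracks["0h"], catalog)
        acc = classify_accessibility(
            {tp: matrices[tp] for tp in timepoints if tp != "6h"},
            catalog,
            center_bp=s["signal"]["center_bp"],
            gain_fold=s["signal"]["gain_fold"],
            min_rpkm=s["signal"]["min_rpkm"],
            background_rpkm=bg,
        )
        emit(acc.to_frame(), "accessibility_classes.tsv")
        prof = central_depletion_profile(matrices["proB"], acc)
        emit(prof.set_index("class"), "central_depletion_proB.tsv")
        freq = atac_peak_site_frequency(atac_consensus, catalog)
        emit(freq.set_index("cluster"), "atac_peak_site_frequency.tsv")
        manifest["stages"]["signal"] = {
            "background_rpkm": float(bg),
            "accessibility_counts": {k: int(v) for k, v in
                                     acc.value_counts().items()},
        }

    # ------------------------------------------------------------ methylation
    if "methylation" in stages:
        meth = generate_methylome(genome, noise, timepoints)
        lmrs = call_lmrs(
            meth["proB"],
            low_band=tuple(s["methylation"]["low_band"]),
            min_cpgs=s["methylation"]["min_cpgs"],
            max_gap_bp=s["methylation"]["max_gap_bp"],
        )
        lmrs.write(outdir / "lmrs_proB.bed")
        written.append(outdir / "lmrs_proB.bed")
        site_meth = {
            tp: site_methylation(meth[tp], catalog, s["methylation"]["window_bp"])
            for tp in meth
        }
        cloud, summary = methylation_dynamics(
            site_meth, catalog, lmrs,
            association_bp=s["methylation"]["association_bp"],
        )
        emit(cloud.set_index("site_id"), "methylation_cloud.tsv")
        emit(summary.set_index("class"), "methylation_deltas.tsv")
        manifest["stages"]["methylation"] = {
            "n_lmrs": len(lmrs), "n_cloud_sites": len(cloud)
        }

    # ------------------------------------------------------------- footprints
    if "footprints" in stages:
        fp_by_tp = {}
        for tp in timepoints:
            if tp == "6h":
                continue
            regions = [
                GenomicInterval(site.chrom, max(0, site.center - 100), site.center + 100,
                                name=site.name)
                for site in catalog.sites
            ]
            fp_by_tp[tp] = call_footprints(
                cuts[tp], regions,
                widths=tuple(s["footprints"]["widths"]),
                shoulder_bp=s["footprints"]["shoulder_bp"],
                fdr=s["footprints"]["fdr"],
                n_shuffles=s["footprints"]["n_shuffles"],
                seed=config.stage_seed("footprints"),
            )
        # planted motif universe: the canonical motif at flagged sites plus an
        # invariant CTCF-like control at background positions
        rng = np.random.default_rng(config.stage_seed("footprints") + 1)
        motif_hits = [
            MotifHit("EBF1", GenomicInterval(site.chrom, site.center - 7,
                                             site.center + 7, name="EBF1"),
                     "+", 10.0)
            for site in genome.sites if site.has_canonical_motif
        ]
        chrom0 = next(iter(genome.chrom_sizes))
        for i in range(100):
            pos = int(rng.integers(5000, genome.chrom_sizes[chrom0] - 5000))
            motif_hits.append(
                MotifHit("CTCF", GenomicInterval(chrom0, pos, pos + 19, name="CTCF"),
                         "+", 8.0)
            )
        occ_sets, occupancy = footprint_motif_occupancy(fp_by_tp, motif_hits)
        emit(occupancy.set_index("motif_id"), "motif_occupancy.tsv")
        cooc = cooccurrence_enrichment(
            occ_sets["0h"], occ_sets["proB"],
            window_bp=s["footprints"]["cooccurrence_window_bp"],
        )
        emit(cooc.set_index(["motif_a", "motif_b"]), "cooccurrence_0h_proB.tsv")
        manifest["stages"]["footprints"] = {
            "n_footprints": {tp: len(v) for tp, v in fp_by_tp.items()}
        }

    # ------------------------------------------------------------- expression
    if "expression" in stages:
        table = generate_expression(genome, noise, timepoints, n_reps)
        de = differential_genes(
            table,
            fc_threshold=s["expression"]["fc_threshold"],
            p_threshold=s["expression"]["p_threshold"],
            min_fpkm=s["expression"]["min_fpkm"],
        )
        strata = stratify_by_amplitude(de, cutoff_fold=s["expression"]["cutoff_fold"])
        link = assign_genes_to_sites(
            catalog, table.gene_coords, window_kb=s["expression"]["window_kb"]
        )
        reg = regulated_genes(de, link)
        induced = [tp for tp in timepoints if tp not in ("0h", "6h")]
        assignments, _profiles = cluster_trajectories(
            de, timepoints=induced,
            c=s["expression"]["stem"]["c"],
            n_model_profiles=s["expression"]["stem"]["n_model_profiles"],
            n_permutations=s["expression"]["stem"]["n_permutations"],
            seed=config.stage_seed("stem"),
        )
        per_gene, tests = site_count_and_distance_summary(link, de)
        de_out = de.copy()
        de_out["amplitude_stratum"] = strata.reindex(de.index)
        de_out["factor_regulated"] = de.index.isin(reg)
        emit(de_out, "differential_genes.tsv")
        emit(link.set_index("site_id"), "site_gene_map.tsv")
        if not assignments.empty:
            emit(assignments, "trajectory_clusters.tsv")
        emit(per_gene.set_index("gene_id"), "site_count_summary.tsv")
        emit(tests.set_index(["group", "metric"]), "site_count_tests.tsv")
        manifest["stages"]["expression"] = {
            "n_de": int(de["is_de"].sum()),
            "n_regulated": int(len(reg)),
            "strata": {k: int(v) for k, v in strata.value_counts().items()},
        }

    # -------------------------------------------------------------- dependency
    if "dependency" in stages:
        dep_noise = NoiseModel(
            peak_dropout_prob=0.0,
            seed=config.stage_seed("dependency"),
        )
        scen = generate_dependency_scenario(
            genome, dep_noise,
            n_secondary=s["dependency"]["n_secondary"],
            cobound_frac=s["dependency"]["cobound_frac"],
            dependent_frac_cobound=s["dependency"]["dependent_frac_cobound"],
            preaccessible_frac_independent=s["dependency"]["preaccessible_frac_independent"],
            cooccupancy_window_bp=s["dependency"]["cooccupancy_window_bp"],
        )
        cls = classify_dependence(
            scen["secondary_sites"], scen["knockout_peaks"], scen["pioneer_peaks"],
            central_rpkm_0h=scen["rpkm_0h"], central_rpkm_final=scen["rpkm_final"],
            cooccupancy_window_bp=s["dependency"]["cooccupancy_window_bp"],
        )
        per_label, fisher = dependence_accessibility_summary(cls)
        emit(cls.set_index("site_id"), "dependence_classification.tsv")
        emit(per_label.set_index("label"), "dependence_summary.tsv")
        emit(fisher.set_index("stage"), "dependence_fisher.tsv")
        if s["include_6h"]:
            early = early_occupancy_overlap(catalog, chip_consensus.get("6h", []))
            emit(early.set_index("group"), "early_occupancy.tsv")
        manifest["stages"]["dependency"] = {
            "label_counts": {k: int(v) for k, v in
                             cls["label"].value_counts().items()},
        }

    manifest["outputs"] = {
        p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
        for p in sorted(set(written))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
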