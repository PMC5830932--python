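"""DE calling, site-gene linkage, amplitude strata, trajectory clustering."""

import numpy as np
import pandas as pd
import pytest

from tfkinetics.benchmarks import make_de_table
from tfkinetics.expression import (
    ConfigurationError,
    ExpressionTable,
    assign_genes_to_sites,
    differential_genes,
    regulated_genes,
    site_count_and_distance_summary,
    stem_cluster,
    stratify_by_amplitude,
)
from tfkinetics.intervals import GenomicInterval
from tfkinetics.peaks import SiteCatalog


def small_table(fpkm_by_gene, timepoints=("0h", "proB"), n_reps=2):
    """fpkm_by_gene: gene -> {tp: mean FPKM} (replicates identical)."""
    genes = list(fpkm_by_gene)
    samples = [(tp, f"rep{r+1}") for tp in timepoints for r in range(n_reps)]
    values = pd.DataFrame(
        [[fpkm_by_gene[g][tp] for tp, _ in samples] for g in genes],
        index=genes, columns=[f"{tp}_{rep}" for tp, rep in samples],
    )
    meta = pd.DataFrame({"sample": values.columns,
                         "timepoint": [tp for tp, _ in samples],
                         "replicate": [r for _, r in samples]}).set_index("sample")
    coords = pd.DataFrame({"gene_id": genes, "chrom": "chr1", "strand": "+",
                           "tss": np.arange(len(genes)) * 10_000}).set_index("gene_id")
    return ExpressionTable(values=values, samples=meta, gene_coords=coords)


class TestDifferentialGenes:
    def test_low_expression_filtered(self):
        t = small_table({"g1": {"0h": 0.3, "proB": 0.8}})
        de = differential_genes(t)
        assert not de.loc["g1", "is_de"]
        assert not de.loc["g1", "expressed"]

    def test_no_fold_change_not_de(self):
        t = small_table({"g1": {"0h": 2.0, "proB": 2.0}})
        de = differential_genes(t)
        assert de.loc["g1", "log2fc"] == pytest.approx(0.0)
        assert not de.loc["g1", "is_de"]

    def test_requires_replicates(self):
        t = small_table({"g1": {"0h": 2.0, "proB": 2.0}}, n_reps=1)
        with pytest.raises(ConfigurationError):
            differential_genes(t)

    def test_planted_sensitivity_and_specificity(self):
        """100 true DE at 4x, sigma 0.25, 2 replicates: near-perfect recovery."""
        from tfkinetics.benchmarks import de_benchmark

        r = de_benchmark(11, n_seeds=3)
        assert r["sensitivity_min"] >= 0.95
        assert r["false_positives_max"] <= 5
        assert r["low_expression_called"] == 0

    def test_type_one_control_on_null(self):
        """Null tables: DE count stays within 2x of the p-threshold expectation."""
        n_fp = []
        for seed in range(10):
            t = make_de_table(seed + 50, n_de=0, n_low=0, n_genes=300)
            de = differential_genes(t, moderated=False)
            n_fp.append(int(de["is_de"].sum()))
        # |log2FC|>1 at sigma=0.25 already removes nearly everything; the
        # p<0.01 bound caps the rest
        assert np.mean(n_fp) <= 2 * 0.01 * 300


class TestStrata:
    def test_boundaries(self):
        t = small_table({
            "pdgfrb": {"0h": 73.0, "proB": 1.0},
            "cebpb": {"0h": 9.8, "proB": 1.0},
            "edge": {"0h": 10.0, "proB": 1.0},
        })
        # shift FPKMs so pseudocount barely matters: use large values
        t.values *= 100
        de = differential_genes(t)
        de["is_de"] = True  # strata are defined on DE genes
        de["log2fc"] = np.log2(np.array([1 / 73.0, 1 / 9.8, 1 / 10.0]))
        strata = stratify_by_amplitude(de)
        assert strata["pdgfrb"] == "stringent"
        assert strata["cebpb"] == "lenient"
        assert strata["edge"] == "lenient"  # exactly 10-fold is lenient

    def test_partition_of_de_genes(self):
        table = make_de_table(3)
        de = differential_genes(table)
        strata = stratify_by_amplitude(de)
        assert set(strata.index) == set(de.index[de["is_de"]])


def catalog_with(centers):
    sites = [GenomicInterval("chr1", c - 100, c + 100, name=f"s{i}")
             for i, c in enumerate(centers)]
    return SiteCatalog(sites=sites,
                       occupancy=np.ones((len(sites), 3), dtype=np.uint8),
                       timepoints=["24h", "72h", "proB"])


class TestAssignGenesToSites:
    def gene_models(self, tss_by_gene):
        return pd.DataFrame(
            {"gene_id": list(tss_by_gene), "chrom": "chr1", "strand": "+",
             "tss": list(tss_by_gene.values())}
        ).set_index("gene_id")

    def test_within_window_linked(self):
        gm = self.gene_models({"gA": 50_000})
        out = assign_genes_to_sites(catalog_with([60_000]), gm)
        assert out.iloc[0]["gene_id"] == "gA"
        assert out.iloc[0]["abs_distance"] == 10_000

    def test_nearest_gene_only(self):
        gm = self.gene_models({"gA": 50_000, "gB": 64_000})
        out = assign_genes_to_sites(catalog_with([60_000]), gm)
        assert out["gene_id"].tolist() == ["gB"]

    def test_outside_window_unlinked(self):
        gm = self.gene_models({"gA": 100_000})
        out = assign_genes_to_sites(catalog_with([130_001]), gm)
        assert out.empty

    def test_tie_breaks_lexicographic(self):
        gm = self.gene_models({"gB": 40_000, "gA": 60_000})
        out = assign_genes_to_sites(catalog_with([50_000]), gm)
        assert out["gene_id"].tolist() == ["gA"]

    def test_matches_bruteforce_nearest(self, rng):
        tss = {f"g{i:03d}": int(t) for i, t in
               enumerate(rng.integers(0, 2_000_000, size=150))}
        gm = self.gene_models(tss)
        centers = [int(c) for c in rng.integers(0, 2_000_000, size=200)]
        out = assign_genes_to_sites(catalog_with(centers), gm).set_index("site_id")
        for i, c in enumerate(centers):
            dists = {g: abs(t - c) for g, t in tss.items() if abs(t - c) <= 25_000}
            sid = f"s{i}"
            if not dists:
                assert sid not in out.index
            else:
                best = min(dists.values())
                expect = min(g for g, d in dists.items() if d == best)
                assert out.loc[sid, "gene_id"] == expect

    def test_regulated_genes_subset_of_de(self):
        table = make_de_table(5)
        de = differential_genes(table)
        cat = catalog_with([1000, 5000, 200_000])
        link = assign_genes_to_sites(cat, table.gene_coords)
        reg = regulated_genes(de, link)
        assert set(reg) <= set(de.index[de["is_de"]])


class TestStemCluster:
    def profiles(self, rows, names=None):
        return pd.DataFrame(rows, columns=["24h", "72h", "proB"],
                            index=names or [f"g{i}" for i in range(len(rows))])

    def test_exact_model_profiles_fully_recovered(self):
        assign, ptable = stem_cluster(
            self.profiles([[2, 4, 6]] * 10 + [[0, 0, 2]] * 10), seed=1
        )
        by_gene = assign["profile_id"]
        assert by_gene.iloc[:10].nunique() == 1
        assert by_gene.iloc[10:].nunique() == 1
        assert by_gene.iloc[0] != by_gene.iloc[10]
        assert assign["similarity"].iloc[:10].min() == pytest.approx(1.0)

    def test_determinism_and_order_invariance(self, rng):
        X = rng.normal(0, 1, size=(60, 3))
        p1 = self.profiles(X)
        a1, t1 = stem_cluster(p1, seed=5)
        a2, t2 = stem_cluster(p1, seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        perm = rng.permutation(60)
        a3, _ = stem_cluster(p1.iloc[perm], seed=5)
        pd.testing.assert_series_equal(
            a1["profile_id"].sort_index(), a3["profile_id"].sort_index()
        )

    def test_too_few_timepoints(self):
        with pytest.raises(ConfigurationError):
            stem_cluster(pd.DataFrame({"24h": [1.0, 2.0]}), seed=1)

    def test_planted_template_recovery(self):
        from tfkinetics.benchmarks import stem_benchmark

        r = stem_benchmark(2)
        assert r["profile_accuracy"] >= 0.90

    def test_null_calibration(self):
        from tfkinetics.benchmarks import stem_null_benchmark

        r = stem_null_benchmark(2)
        assert r["seeds_with_zero_significant"] >= 4


class TestSiteCountSummary:
    def test_counts_and_planted_difference(self, rng):
        """Up-regulated genes planted with 3 sites vs 1 for unchanged ->
        significant Mann-Whitney difference."""
        genes = [f"g{i:03d}" for i in range(120)]
        de = pd.DataFrame(index=genes)
        de["log2fc"] = [2.5 if i < 60 else 0.0 for i in range(120)]
        de["p_value"] = 1e-6
        de["is_de"] = de["log2fc"].abs() > 1
        de["direction"] = np.where(de["log2fc"] > 0, "up", "down")
        de["fpkm_0h"] = 10.0
        de["fpkm_proB"] = 10.0
        rows = []
        for i, g in enumerate(genes):
            n_sites = 3 if i < 60 else 1
            for k in range(n_sites):
                rows.append({"site_id": f"s{i}_{k}", "gene_id": g,
                             "distance": 1000 * (k + 1),
                             "abs_distance": 1000 * (k + 1)})
        link = pd.DataFrame(rows)
        per_gene, tests = site_count_and_distance_summary(link, de)
        up_counts = per_gene[per_gene["group"] == "up"]["n_sites"]
        assert (up_counts == 3).all()
        t = tests.set_index(["group", "metric"])
        assert t.loc[("up", "n_sites"), "adjusted_p"] < 0.05

    def test_empty_group_marked_missing(self):
        de = pd.DataFrame({
            "log2fc": [2.5], "p_value": [1e-6], "is_de": [True],
            "direction": ["up"], "fpkm_0h": [10.0], "fpkm_proB": [10.0],
        }, index=["g0"])
        link = pd.DataFrame(columns=["site_id", "gene_id", "distance", "abs_distance"])
        per_gene, tests = site_count_and_distance_summary(link, de)
        t = tests.set_index(["group", "metric"])
        assert bool(t.loc[("down", "n_sites"), "missing"])
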