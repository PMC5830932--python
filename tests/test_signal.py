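"""RPKM matrices, accessibility clustering, depletion profiles, enrichment caller."""

import numpy as np
import pytest

from tfkinetics.intervals import GenomicInterval
from tfkinetics.peaks import SiteCatalog
from tfkinetics.signal import (
    SignalMatrix,
    SignalTrack,
    atac_peak_site_frequency,
    call_enrichment_peaks,
    central_depletion_profile,
    classify_accessibility,
    compute_signal_matrix,
)


def catalog_at(centers, width=200, timepoints=("24h", "72h", "proB"), occupied=True):
    sites = [
        GenomicInterval("chr1", c - width // 2, c + width // 2, name=f"s{i}")
        for i, c in enumerate(centers)
    ]
    occ = np.full((len(sites), len(timepoints)), 1 if occupied else 0, dtype=np.uint8)
    return SiteCatalog(sites=sites, occupancy=occ, timepoints=list(timepoints))


class TestSignalMatrix:
    def test_rpkm_formula(self):
        """1 fragment in a 50-bp bin at 1e6 total fragments -> RPKM 20."""
        track = SignalTrack({"chr1": np.array([5010])}, total_mapped_fragments=10**6)
        cat = catalog_at([5000])
        m = compute_signal_matrix(track, cat, window_bp=3000, bin_bp=50)
        j = np.flatnonzero(m.bin_centers == 25.0)[0]  # bin [5000, 5050)
        assert m.values[0, j] == pytest.approx(20.0)
        assert m.values.sum() == pytest.approx(20.0)

    def test_normalization_linearity(self):
        mids = {"chr1": np.sort(np.random.default_rng(0).integers(0, 10_000, 200))}
        cat = catalog_at([5000])
        m1 = compute_signal_matrix(SignalTrack(dict(mids), 10**6), cat)
        m2 = compute_signal_matrix(SignalTrack(dict(mids), 2 * 10**6), cat)
        assert np.allclose(m1.values, 2 * m2.values)

    def test_matches_naive_recount_oracle(self, rng):
        """10 sites x 120 bins equal a per-bin recount to 1e-9 relative tolerance."""
        mids = np.sort(rng.integers(0, 200_000, size=5000))
        track = SignalTrack({"chr1": mids.copy()}, total_mapped_fragments=123_457)
        centers = rng.integers(10_000, 190_000, size=10)
        cat = catalog_at(centers)
        m = compute_signal_matrix(track, cat, window_bp=3000, bin_bp=50)
        assert m.values.shape == (10, 120)
        scale = 1e9 / (50 * 123_457)
        for i, c in enumerate(centers):
            for j in range(120):
                lo = c - 3000 + 50 * j
                count = int(((mids >= lo) & (mids < lo + 50)).sum())
                assert m.values[i, j] == pytest.approx(count * scale, rel=1e-9)

    def test_rpkm_conservation(self, rng):
        """Non-overlapping windows: back-transformed matrix sum equals the
        fragment count inside the windows (midpoint counting is additive)."""
        mids = np.sort(rng.integers(0, 500_000, size=20_000))
        track = SignalTrack({"chr1": mids.copy()}, total_mapped_fragments=len(mids))
        centers = np.arange(10_000, 490_000, 20_000)
        cat = catalog_at(centers)
        m = compute_signal_matrix(track, cat, window_bp=3000, bin_bp=50)
        back = m.values.sum() * 50 * len(mids) / 1e9
        inside = sum(
            int(((mids >= c - 3000) & (mids < c + 3000)).sum()) for c in centers
        )
        assert back == pytest.approx(inside, rel=1e-9)

    def test_edge_truncation_flagged(self):
        track = SignalTrack({"chr1": np.array([100])}, 1000,
                            chrom_sizes={"chr1": 10_000})
        cat = catalog_at([500])
        m = compute_signal_matrix(track, cat)
        assert m.truncated[0]

    def test_empty_track_warns(self):
        track = SignalTrack({"chr1": np.array([], dtype=np.int64)}, 1)
        with pytest.warns(UserWarning, match="empty"):
            m = compute_signal_matrix(track, catalog_at([5000]))
        assert (m.values == 0).all()


def matrix_with_central(central_levels, site_ids=None, bins=120, bin_bp=50):
    """Build a SignalMatrix whose central +/-500 bp means equal given levels."""
    n = len(central_levels)
    site_ids = site_ids or [f"s{i}" for i in range(n)]
    centers = -3000 + bin_bp * np.arange(bins) + bin_bp / 2
    values = np.zeros((n, bins))
    for i, lvl in enumerate(central_levels):
        values[i, np.abs(centers) <= 500] = lvl
    return SignalMatrix(site_ids, centers, values, 3000, bin_bp)


class TestClassifyAccessibility:
    def test_preexisting_rule(self):
        cat = catalog_at([5000], occupied=True)
        mats = {
            "0h": matrix_with_central([8.0]),
            "24h": matrix_with_central([9.0]),
            "72h": matrix_with_central([9.0]),
            "proB": matrix_with_central([9.0]),
        }
        labels = classify_accessibility(mats, cat, min_rpkm=5.0)
        assert labels["s0"] == "preexisting"

    def test_gain24_threshold_logic(self):
        cat = catalog_at([5000], occupied=False)
        cat.occupancy[:, :] = 1
        mats = {
            "0h": matrix_with_central([0.5]),
            "24h": matrix_with_central([6.0]),
            "72h": matrix_with_central([7.0]),
            "proB": matrix_with_central([8.0]),
        }
        labels = classify_accessibility(mats, cat, min_rpkm=5.0, gain_fold=2.0)
        assert labels["s0"] == "gain24"

    def test_transient_and_unclassified(self):
        cat = catalog_at([5000, 9000], occupied=False)
        mats = {
            "0h": matrix_with_central([0.5, 0.5]),
            "24h": matrix_with_central([8.0, 0.6]),
            "72h": matrix_with_central([8.0, 0.6]),
            "proB": matrix_with_central([0.4, 0.7]),
        }
        labels = classify_accessibility(mats, cat, min_rpkm=5.0)
        assert labels["s0"] == "transient"
        assert labels["s1"] == "unclassified"

    def test_planted_recovery(self):
        """>= 90% of planted accessibility classes recovered at default noise."""
        from tfkinetics.benchmarks import truth_catalog
        from tfkinetics.synthetic import (
            CLASS_ACCESSIBILITY,
            NoiseModel,
            generate_cut_counts,
            generate_genome,
        )
        from tfkinetics.signal import estimate_background_rpkm

        genome = generate_genome(n_sites=300, seed=21)
        noise = NoiseModel(seed=21)
        cuts = generate_cut_counts(genome, noise)
        cat = truth_catalog(genome)
        tracks = {tp: SignalTrack.from_cut_tracks(cuts[tp]) for tp in cuts}
        mats = {tp: compute_signal_matrix(tracks[tp], cat) for tp in tracks}
        bg = estimate_background_rpkm(tracks["0h"], cat)
        labels = classify_accessibility(mats, cat, min_rpkm="auto", background_rpkm=bg)
        truth = np.array([s.true_class for s in genome.sites])
        assert (labels.to_numpy() == truth).mean() >= 0.90


class TestDepletionProfile:
    def test_flat_ratio_one(self):
        m = SignalMatrix(["s0"], -3000 + 50 * np.arange(120) + 25,
                         np.full((1, 120), 4.0), 3000, 50)
        prof = central_depletion_profile(m, {"s0": "x"})
        assert prof["center_shoulder_ratio"].iloc[0] == pytest.approx(1.0)

    def test_planted_bimodal_ratio(self, rng):
        centers = -3000 + 50 * np.arange(120) + 25
        base = np.full(120, 10.0)
        base[np.abs(centers) <= 100] = 5.0  # planted 0.5 center/shoulder
        values = np.vstack([base + rng.normal(0, 0.3, 120) for _ in range(50)])
        m = SignalMatrix([f"s{i}" for i in range(50)], centers,
                         np.clip(values, 0, None), 3000, 50)
        prof = central_depletion_profile(m, {f"s{i}": "dip" for i in range(50)})
        assert prof["center_shoulder_ratio"].iloc[0] == pytest.approx(0.50, abs=0.05)

    def test_zero_shoulder_missing(self):
        centers = -3000 + 50 * np.arange(120) + 25
        values = np.zeros((1, 120))
        values[0, np.abs(centers) <= 100] = 1.0
        m = SignalMatrix(["s0"], centers, values, 3000, 50)
        with pytest.warns(UserWarning, match="shoulder"):
            prof = central_depletion_profile(m, {"s0": "x"})
        assert np.isnan(prof["center_shoulder_ratio"].iloc[0])


class TestAtacPeakSiteFrequency:
    def test_extremes(self):
        sites = catalog_at([1000, 5000])
        peaks = {
            "24h": [GenomicInterval("chr1", 900, 1100)],
            "proB": [GenomicInterval("chr1", 4900, 5100)],
        }
        out = atac_peak_site_frequency(peaks, sites).set_index("cluster")
        assert out.loc["24h", "site_fraction"] == 1.0
        far = {
            "24h": [GenomicInterval("chr1", 40_000, 40_200)],
            "proB": [GenomicInterval("chr1", 50_000, 50_200)],
        }
        out = atac_peak_site_frequency(far, sites).set_index("cluster")
        assert out.loc["24h", "site_fraction"] == 0.0

    def test_planted_cluster_fractions_recovered(self):
        """Planted ~0.9 / ~0.42 site fractions in the 24 h / committed-stage
        ATAC clusters recovered within 0.05."""
        from tfkinetics.benchmarks import atac_frequency_benchmark

        r = atac_frequency_benchmark(2)
        assert r["site_fraction_24h"] == pytest.approx(0.90, abs=0.05)
        assert r["site_fraction_proB"] == pytest.approx(0.42, abs=0.05)


class TestEnrichmentCaller:
    def test_uniform_background_no_peaks(self):
        """Expected false-positive count < 1 over the toy genome; verified
        over 20 seeds."""
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cov = rng.poisson(0.5, size=200_000)
            total += len(call_enrichment_peaks({"chr1": cov}, background_rate=0.5,
                                               p_threshold=1e-5))
        assert total <= 2

    def test_planted_enrichment_recovered(self):
        rng = np.random.default_rng(3)
        cov = rng.poisson(0.5, size=100_000)
        cov[40_000:40_300] = rng.poisson(5.0, size=300)
        peaks = call_enrichment_peaks({"chr1": cov}, background_rate=0.5,
                                      p_threshold=1e-5)
        assert len(peaks) == 1
        assert abs(peaks[0].start - 40_000) <= 100
        assert abs(peaks[0].end - 40_300) <= 100

    def test_empty_track(self):
        assert call_enrichment_peaks({"chr1": np.zeros(10_000)},
                                     background_rate=0.5) == []
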