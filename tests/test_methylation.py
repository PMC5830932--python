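"""Methylation track parsing, LMR calling, window means, demethylation dynamics."""

import numpy as np
import pandas as pd
import pytest

from tfkinetics.intervals import GenomicInterval
from tfkinetics.methylation import (
    MethylationTrack,
    call_lmrs,
    methylation_dynamics,
    read_methylation,
    site_methylation,
    write_methylation,
)
from tfkinetics.peaks import SiteCatalog


def track_from(rows):
    """rows: list of (chrom, pos, frac, cov)."""
    data = {}
    for chrom in {r[0] for r in rows}:
        sub = sorted(r for r in rows if r[0] == chrom)
        data[chrom] = (
            np.array([r[1] for r in sub], dtype=np.int64),
            np.array([r[2] for r in sub], dtype=float),
            np.array([r[3] for r in sub], dtype=np.int64),
        )
    return MethylationTrack(data)


def catalog_at(centers):
    sites = [GenomicInterval("chr1", c - 100, c + 100, name=f"s{i}")
             for i, c in enumerate(centers)]
    occ = np.ones((len(sites), 3), dtype=np.uint8)
    return SiteCatalog(sites=sites, occupancy=occ, timepoints=["24h", "72h", "proB"])


class TestReadMethylation:
    def test_parse_and_units(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t1000\t75.0\t12\nchr1\t1100\t20.0\t3\n")
        t = read_methylation(p, min_coverage=5)
        pos, frac, cov = t.data["chr1"]
        assert pos.tolist() == [1000] and frac.tolist() == [0.75] and cov.tolist() == [12]
        assert t.n_dropped == 1

    def test_percent_out_of_range(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr1\t1000\t140.0\t12\n")
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            read_methylation(p)

    def test_unsorted_positions_named_chrom(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chr2\t1100\t50.0\t12\nchr2\t1000\t50.0\t12\n")
        with pytest.raises(ValueError, match="chr2"):
            read_methylation(p)

    def test_roundtrip(self, tmp_path):
        t = track_from([("chr1", 1000, 0.75, 12), ("chr1", 1200, 0.4, 8)])
        write_methylation(t, tmp_path / "out.tsv")
        back = read_methylation(tmp_path / "out.tsv")
        assert np.allclose(back.data["chr1"][1], t.data["chr1"][1])


class TestCallLmrs:
    def test_basic_run(self):
        rows = [("chr1", 1000 + 30 * i, 0.2, 10) for i in range(5)]
        rows += [("chr1", 5000, 0.9, 10)]
        lmrs = call_lmrs(track_from(rows))
        assert len(lmrs) == 1
        assert lmrs.regions[0].meta["n_cpgs"] == 5

    def test_min_cpgs(self):
        rows = [("chr1", 1000 + 30 * i, 0.2, 10) for i in range(3)]
        assert len(call_lmrs(track_from(rows), min_cpgs=4)) == 0

    def test_matches_exhaustive_oracle(self, rng):
        """Calls on a 200-CpG toy track equal a brute-force run scan."""
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=200, replace=False))
        frac = rng.uniform(0, 1, size=200)
        cov = rng.integers(5, 40, size=200)
        track = MethylationTrack({"chr1": (pos.astype(np.int64), frac, cov)})
        lmrs = call_lmrs(track, low_band=(0.10, 0.50), min_cpgs=4, max_gap_bp=250)

        # oracle: maximal runs of frac<0.5 with gaps<=250, then filter
        expected = []
        i = 0
        while i < 200:
            if frac[i] >= 0.5:
                i += 1
                continue
            j = i
            while j + 1 < 200 and frac[j + 1] < 0.5 and pos[j + 1] - pos[j] <= 250:
                j += 1
            run = frac[i: j + 1]
            if len(run) >= 4 and 0.10 <= run.mean() <= 0.50:
                expected.append((int(pos[i]) - 1, int(pos[j])))
            i = j + 1
        assert [(r.start, r.end) for r in lmrs.regions] == expected

    def test_no_overlap_and_band_invariants(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=500, replace=False))
        frac = rng.beta(0.8, 1.2, size=500)
        track = MethylationTrack(
            {"chr1": (pos.astype(np.int64), frac, np.full(500, 10, dtype=np.int64))}
        )
        lmrs = call_lmrs(track)
        for a, b in zip(lmrs.regions[:-1], lmrs.regions[1:]):
            assert a.end <= b.start
        for r in lmrs.regions:
            assert r.meta["n_cpgs"] >= lmrs.min_cpgs
            assert lmrs.low_band[0] <= r.meta["mean_meth"] <= lmrs.low_band[1]

    def test_empty_track_errors(self):
        with pytest.raises(ValueError, match="empty"):
            call_lmrs(MethylationTrack({}))


class TestSiteMethylation:
    def test_coverage_weighted_mean(self):
        t = track_from([("chr1", 960, 0.8, 10), ("chr1", 1040, 0.4, 30)])
        out = site_methylation(t, catalog_at([1000]))
        assert out["s0"] == pytest.approx(0.50)

    def test_empty_window_missing(self):
        t = track_from([("chr1", 5000, 0.8, 10)])
        out = site_methylation(t, catalog_at([1000]))
        assert np.isnan(out["s0"])

    def test_bounded_by_contributors(self, rng):
        rows = [("chr1", int(p), float(f), int(c))
                for p, f, c in zip(np.sort(rng.choice(20_000, 300, replace=False)) + 1,
                                   rng.uniform(0, 1, 300), rng.integers(1, 50, 300))]
        t = track_from(rows)
        cat = catalog_at(list(rng.integers(200, 19_800, size=30)))
        out = site_methylation(t, cat)
        for site in cat.sites:
            pos, frac, cov = t.window("chr1", site.center + 1 - 100, site.center + 1 + 100)
            if len(frac) == 0:
                assert np.isnan(out[site.name])
            else:
                assert frac.min() - 1e-12 <= out[site.name] <= frac.max() + 1e-12

    def test_matches_bruteforce_window_scan(self, rng):
        rows = [("chr1", int(p), float(f), int(c))
                for p, f, c in zip(np.sort(rng.choice(50_000, 800, replace=False)) + 1,
                                   rng.uniform(0, 1, 800), rng.integers(1, 50, 800))]
        t = track_from(rows)
        centers = rng.integers(500, 49_500, size=50)
        out = site_methylation(t, catalog_at(list(centers)))
        for i, c in enumerate(centers):
            sel = [(f, cv) for _, p, f, cv in rows if c + 1 - 100 <= p <= c + 1 + 100]
            if not sel:
                assert np.isnan(out[f"s{i}"])
            else:
                w = sum(f * cv for f, cv in sel) / sum(cv for _, cv in sel)
                assert out[f"s{i}"] == pytest.approx(w, rel=1e-9)


class TestMethylationDynamics:
    def test_identical_timepoints_zero_deltas(self):
        cat = catalog_at([1000, 3000])
        cat.classes = {"s0": "gain24", "s1": "transient"}
        m = pd.Series({"s0": 0.5, "s1": 0.7})
        cloud, summary = methylation_dynamics({"0h": m, "72h": m, "proB": m}, cat)
        assert (summary.filter(like="delta_") == 0).all().all()

    def test_class_ordering_when_planted(self):
        """Persistent sites end lower than transient ones when planted so."""
        from tfkinetics.benchmarks import methylation_recovery

        r = methylation_recovery(3)
        cloud = r["cloud"]
        pers = cloud[cloud["class"] == "gain24"]["m_proB"].median()
        trans = cloud[cloud["class"] == "transient"]["m_proB"].median()
        assert pers < trans
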