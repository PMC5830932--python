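"""Wellington-style protection score, footprint calling, motif scan/occupancy,
and pairwise co-occurrence enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tfkinetics.footprints import (
    CutProfile,
    FootprintCall,
    MotifHit,
    call_footprints,
    cooccurrence_enrichment,
    footprint_motif_occupancy,
    scan_motifs,
    wellington_score,
)
from tfkinetics.intervals import GenomicInterval


def oracle_score(fwd, rev, start, width, shoulder):
    """Independent direct binomial-CDF evaluation."""
    nf_fp = fwd[start: start + width].sum()
    nf_sh = fwd[start - shoulder: start].sum()
    nr_fp = rev[start: start + width].sum()
    nr_sh = rev[start + width: start + width + shoulder].sum()
    if nf_sh == 0 or nr_sh == 0:
        return 0.0
    p0 = width / (width + shoulder)
    return float(
        -np.log10(stats.binom.cdf(nf_fp, nf_fp + nf_sh, p0))
        - np.log10(stats.binom.cdf(nr_fp, nr_fp + nr_sh, p0))
    )


class TestWellingtonScore:
    def test_fully_protected_example(self):
        """0 interior cuts vs 20-cut shoulders, width 11, shoulder 35."""
        fwd = np.zeros(81, dtype=int)
        rev = np.zeros(81, dtype=int)
        fwd[:35] = [1] * 20 + [0] * 15
        rev[46:] = [1] * 20 + [0] * 15
        prof = CutProfile(fwd, rev)
        expected = -2 * np.log10(stats.binom.cdf(0, 20, 11 / 46))
        assert wellington_score(prof, 35, 11, 35) == pytest.approx(expected, rel=1e-9)

    def test_uniform_smaller_than_depleted(self, rng):
        L = 101
        uniform = CutProfile(rng.poisson(2, L), rng.poisson(2, L))
        depleted_f = rng.poisson(2, L)
        depleted_r = rng.poisson(2, L)
        depleted_f[40:55] = 0
        depleted_r[40:55] = 0
        s_uni = wellington_score(uniform, 40, 15, 35)
        s_dep = wellington_score(CutProfile(depleted_f, depleted_r), 40, 15, 35)
        assert s_dep > s_uni

    def test_all_zero_profile(self):
        prof = CutProfile(np.zeros(100, dtype=int), np.zeros(100, dtype=int))
        assert wellington_score(prof, 40, 15, 35) == 0.0

    def test_bounds_error(self):
        prof = CutProfile(np.ones(50, dtype=int), np.ones(50, dtype=int))
        with pytest.raises(IndexError):
            wellington_score(prof, 10, 15, 35)

    def test_matches_oracle_on_random_profiles(self, rng):
        """1000 random profiles agree with the direct CDF oracle to 1e-9."""
        for _ in range(1000):
            width = int(rng.choice([11, 15, 21, 25]))
            shoulder = int(rng.choice([20, 35, 50]))
            L = width + 2 * shoulder + int(rng.integers(0, 40))
            fwd = rng.poisson(rng.uniform(0, 3), L)
            rev = rng.poisson(rng.uniform(0, 3), L)
            start = int(rng.integers(shoulder, L - width - shoulder + 1))
            got = wellington_score(CutProfile(fwd, rev), start, width, shoulder)
            assert got == pytest.approx(oracle_score(fwd, rev, start, width, shoulder),
                                        rel=1e-9, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(1, 40))
    def test_monotone_in_depletion(self, k1, k2, shoulder_cuts):
        """Fewer interior cuts (shoulders fixed) never decreases the score."""
        lo, hi = sorted((k1, k2))
        scores = []
        for k in (hi, lo):
            fwd = np.zeros(85, dtype=int)
            rev = np.zeros(85, dtype=int)
            fwd[0:35] = np.repeat([1, 0], [min(shoulder_cuts, 35), 35 - min(shoulder_cuts, 35)])
            rev[50:85] = fwd[0:35][::-1]
            fwd[35:50][:k] = 1
            rev[35:50][:k] = 1
            scores.append(wellington_score(CutProfile(fwd, rev), 35, 15, 35))
        assert scores[1] >= scores[0] - 1e-12


class TestCallFootprints:
    def test_empty_regions(self):
        assert call_footprints({"c": (np.zeros(10, int), np.zeros(10, int))}, []) == []

    def test_calls_never_overlap(self):
        from tfkinetics.benchmarks import footprint_benchmark

        r = footprint_benchmark(5, n_true=60, n_null=60)
        assert r["sensitivity"] >= 0.9

    def test_no_overlap_and_null_calibration(self):
        rng = np.random.default_rng(9)
        L = 100_000
        fwd = rng.poisson(5.0, L)
        rev = rng.poisson(5.0, L)
        regions = [GenomicInterval("c", s, s + 200) for s in range(100, L - 300, 400)]
        calls = call_footprints({"c": (fwd, rev)}, regions, fdr=0.01, seed=3)
        for a, b in zip(calls[:-1], calls[1:]):
            assert a.interval.end <= b.interval.start
        # exchangeable null: the per-region family-wise call rate stays near
        # the nominal FDR (<= 2x, plus counting slack for small expectations)
        regions_with_calls = len({c.interval.start // 400 for c in calls})
        assert regions_with_calls <= 2 * 0.01 * len(regions) + 3


class TestScanMotifs:
    PWM = {
        "A": [0.97, 0.01, 0.01, 0.97],
        "C": [0.01, 0.97, 0.01, 0.01],
        "G": [0.01, 0.01, 0.97, 0.01],
        "T": [0.01, 0.01, 0.01, 0.01],
    }  # consensus ACGA

    def test_consensus_max_score(self):
        hits = scan_motifs({"chr1": "TTTTACGATTTT"}, self.PWM, 4.0)
        assert len(hits) == 1
        assert hits[0].interval.start == 4 and hits[0].strand == "+"
        assert hits[0].score == pytest.approx(4 * np.log2(0.97 / 0.25))

    def test_reverse_complement_same_score(self):
        fwd = scan_motifs({"c": "TTTTACGATTTT"}, self.PWM, 4.0)
        rc = scan_motifs({"c": "TTTTTCGTTTTT"}, self.PWM, 4.0)
        assert len(rc) == 1 and rc[0].strand == "-"
        assert rc[0].score == pytest.approx(fwd[0].score)

    def test_matches_exhaustive_oracle(self, rng):
        """Hit set equals a per-position rescoring oracle on a 2-kb sequence."""
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        thresh = 5.0
        hits = scan_motifs({"c": seq}, self.PWM, thresh)
        lo = {b: np.log2(np.maximum(np.array(self.PWM[b]), 1e-4) / 0.25)
              for b in "ACGT"}
        comp = str.maketrans("ACGT", "TGCA")
        expected = []
        for pos in range(len(seq) - 3):
            win = seq[pos: pos + 4]
            s_fwd = sum(lo[b][i] for i, b in enumerate(win))
            s_rev = sum(lo[b][i] for i, b in enumerate(win.translate(comp)[::-1]))
            if s_fwd >= thresh:
                expected.append((pos, "+", s_fwd))
            if s_rev >= thresh:
                expected.append((pos, "-", s_rev))
        # oracle-side dedup: greedy by score over overlapping windows
        expected.sort(key=lambda x: (-x[2], x[1] != "+", x[0]))
        kept = []
        for pos, strand, s in expected:
            if all(abs(pos - q[0]) >= 4 for q in kept):
                kept.append((pos, strand, s))
        kept.sort()
        assert [(h.interval.start, h.strand) for h in hits] == [
            (p, st_) for p, st_, _ in kept
        ]

    def test_pwm_validation(self):
        bad = {b: [0.0] * 4 for b in "ACGT"}
        with pytest.raises(ValueError, match="zero column"):
            scan_motifs({"c": "ACGT"}, bad, 1.0)
        off = {"A": [0.5] * 4, "C": [0.2] * 4, "G": [0.2] * 4, "T": [0.2] * 4}
        with pytest.raises(ValueError, match="sum to 1"):
            scan_motifs({"c": "ACGT"}, off, 1.0)


def fp(chrom, start, end):
    return FootprintCall(GenomicInterval(chrom, start, end), 5.0, end - start, 35)


def hit(motif, center, chrom="c"):
    return MotifHit(motif, GenomicInterval(chrom, center - 5, center + 5, name=motif),
                    "+", 8.0)


class TestMotifOccupancy:
    def test_no_footprints_zero_fraction(self):
        hits = [hit("EBF1", 100), hit("EBF1", 500)]
        occ, summary = footprint_motif_occupancy({"0h": [], "24h": [fp("c", 95, 110)]},
                                                 hits)
        row = summary.set_index("motif_id").loc["EBF1"]
        assert row["frac_0h"] == 0.0
        assert row["frac_24h"] == 0.5

    def test_counts_match_bruteforce(self, rng):
        hits = [hit("M", int(c)) for c in rng.integers(100, 50_000, size=150)]
        fps = [fp("c", int(s), int(s) + 20) for s in rng.integers(0, 50_000, size=80)]
        occ, _ = footprint_motif_occupancy({"t": fps}, hits)
        flags = occ["t"].footprinted
        for h, flag in zip(hits, flags):
            mid = h.interval.center
            expected = any(f.interval.start <= mid < f.interval.end for f in fps)
            assert bool(flag) == expected

    def test_constitutive_motif_not_significant(self):
        """A CTCF-like motif footprinted everywhere shows no significant change."""
        hits = [hit("CTCF", 1000 * i + 500) for i in range(40)]
        fps = [fp("c", 1000 * i + 490, 1000 * i + 515) for i in range(40)]
        _, summary = footprint_motif_occupancy({"0h": fps, "24h": fps, "proB": fps},
                                               hits)
        qcols = [c for c in summary.columns if c.startswith("q_")]
        assert (summary[qcols] > 0.05).all().all()


class TestCooccurrence:
    def test_identical_sets_odds_one(self):
        hits = [hit("A", 100), hit("B", 150), hit("A", 5000)]
        from tfkinetics.footprints import MotifOccupancySet

        occ = MotifOccupancySet("t", hits, np.array([True, True, True]))
        df = cooccurrence_enrichment(occ, occ).set_index(["motif_a", "motif_b"])
        pair = df.loc[("A", "B")]
        assert pair["odds_ratio"] == pytest.approx(1.0, abs=0.01)

    def test_planted_pair_enriched(self, rng):
        """A-B co-occurrence planted only at t2 -> OR > 1 and q < 0.05;
        an unrelated pair stays null."""
        from tfkinetics.footprints import MotifOccupancySet

        hits, foot1, foot2 = [], [], []
        for i in range(120):
            base = 2000 * i + 1000
            hits.append(hit("A", base))
            hits.append(hit("B", base + 50))       # within 100 bp of A
            hits.append(hit("C", base + 700))      # far from everything
        n = len(hits)
        foot1 = np.zeros(n, dtype=bool)
        foot2 = np.ones(n, dtype=bool)
        # at t1 only A and C are footprinted (B closed): no A-B co-occurrence
        for j, h in enumerate(hits):
            foot1[j] = h.motif_id in ("A", "C")
        occ1 = MotifOccupancySet("t1", hits, foot1)
        occ2 = MotifOccupancySet("t2", hits, foot2)
        df = cooccurrence_enrichment(occ1, occ2).set_index(["motif_a", "motif_b"])
        ab = df.loc[("A", "B")]
        assert ab["odds_ratio"] > 1 and ab["adjusted_p"] < 0.05
        ac = df.loc[("A", "C")]
        assert ac["adjusted_p"] > 0.05

    def test_counts_match_distance_oracle(self, rng):
        from tfkinetics.footprints import MotifOccupancySet

        hits = [hit(m, int(c)) for m, c in zip(
            rng.choice(["A", "B"], size=100), rng.integers(0, 20_000, size=100))]
        flags = rng.random(100) < 0.7
        occ = MotifOccupancySet("t", hits, flags)
        df = cooccurrence_enrichment(occ, occ, window_bp=200).set_index(
            ["motif_a", "motif_b"])
        mids = [(h.motif_id, h.interval.center) for h, f in zip(hits, flags) if f]

        def brute(a, b):
            k = 0
            for m, c in mids:
                if m != a:
                    continue
                near = [
                    1 for m2, c2 in mids
                    if m2 == b and abs(c2 - c) <= 100 and not (m2 == m and c2 == c)
                ]
                if a == b:
                    near = [1 for m2, c2 in mids if m2 == b and c2 != c and abs(c2 - c) <= 100]
                if near:
                    k += 1
            return k

        assert df.loc[("A", "B"), "co_t2"] == brute("A", "B") + brute("B", "A")
        assert df.loc[("A", "A"), "co_t2"] == brute("A", "A")
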