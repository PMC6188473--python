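"""Peak annotation, conservation summaries, and SNP overlap vs oracles."""

import numpy as np
import pandas as pd
import pytest

from crosscell.io import GeneModel, new_peak_set
from crosscell.peaks import (assign_peaks, compare_groups,
                             filter_differential_peaks,
                             metagene_conservation, peak_conservation,
                             promoter_window, region_signal_fpkm, snp_overlap)
from crosscell.simulate import simulate_gene_models


def track_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def random_track(rng, chrom="chr1", lo=0, hi=200_000, n=200):
    starts = np.sort(rng.choice(np.arange(lo, hi, 50), size=n, replace=False))
    ends = starts + rng.integers(10, 50, n)
    return track_frame([(chrom, int(s), int(e), float(rng.random()))
                        for s, e in zip(starts, ends)])


def per_base_mean_oracle(track, chrom, start, end):
    """Naive per-base expansion of the run-length track (missing = 0)."""
    scores = np.zeros(end - start)
    for r in track.itertuples():
        if r.chrom != chrom:
            continue
        for pos in range(max(r.start, start), min(r.end, end)):
            scores[pos - start] = r.score
    return scores.mean()


class TestPromoterWindows:
    def test_plus_strand_window(self):
        m = GeneModel("g", "chr1", "+", 5000, 9000)
        assert promoter_window(m) == (4000, 5101)

    def test_minus_strand_window_mirrored(self):
        m = GeneModel("g", "chr1", "-", 5000, 9000)  # tss = 8999
        assert promoter_window(m) == (8899, 9999 + 1)

    def test_width_is_1101_unless_clipped(self):
        m = GeneModel("g", "chr1", "+", 5000, 9000)
        lo, hi = promoter_window(m)
        assert hi - lo == 1101
        near = GeneModel("g2", "chr1", "+", 300, 2000)
        lo, hi = promoter_window(near)
        assert lo == 0  # clipped at the contig start


class TestAssignPeaks:
    def _gene(self):
        return GeneModel("g", "chr1", "+", 5000, 9000)

    def test_promoter_overlap_examples(self):
        peaks = new_peak_set(["chr1", "chr1"], [4900, 5200], [5400, 5600],
                            ["prom", "body"])
        out = assign_peaks(peaks, [self._gene()])
        # [4900,5400) overlaps the window [4000,5101) -> promoter
        assert out.iloc[0]["category"] == "promoter"
        # [5200,5600) is inside the gene span but past the window -> body
        assert out.iloc[1]["category"] == "gene_body"
        assert (out["gene_id"] == "g").all()

    def test_no_overlap_is_other(self):
        peaks = new_peak_set(["chr1"], [20_000], [20_500], ["far"])
        out = assign_peaks(peaks, [self._gene()])
        assert out.iloc[0]["category"] == "other"

    def test_unknown_contig_warns_and_stays_other(self):
        peaks = new_peak_set(["chrUn"], [10], [20], ["p"])
        with pytest.warns(UserWarning, match="unknown contig"):
            out = assign_peaks(peaks, [self._gene()])
        assert out.iloc[0]["category"] == "other"

    def test_two_windows_resolved_to_nearer_tss(self):
        a = GeneModel("a", "chr1", "+", 10_000, 15_000)   # tss 10000
        b = GeneModel("b", "chr1", "-", 3_000, 9_500)     # tss 9499
        # peak overlapping both promoter windows, closer to b's TSS
        peaks = new_peak_set(["chr1"], [9_400], [9_650], ["p"])
        out = assign_peaks(peaks, [a, b])
        assert out.iloc[0]["gene_id"] == "b"

    def test_matches_bruteforce_scan_on_random_fixtures(self):
        rng = np.random.default_rng(31)
        models = simulate_gene_models(60, seed=5)
        spans = np.array([[m.start, m.end] for m in models])
        lo, hi = spans.min() - 2000, spans.max() + 2000
        starts = rng.integers(lo, hi, 300)
        peaks = new_peak_set(["chr1"] * 300 + ["chr2"] * 0,
                             starts, starts + rng.integers(50, 800, 300),
                             [f"p{i}" for i in range(300)])
        chr1_models = [m for m in models if m.chrom == "chr1"]
        out = assign_peaks(peaks, chr1_models)
        for i, row in out.iterrows():
            s, e = row["start"], row["end"]
            prom_hits = []
            for m in chr1_models:
                wlo, whi = promoter_window(m)
                if s < whi and wlo < e:
                    d = 0 if s <= m.tss < e else min(abs(s - m.tss),
                                                     abs(m.tss - (e - 1)))
                    prom_hits.append((d, m.gene_id))
            if prom_hits:
                assert row["category"] == "promoter"
                assert row["gene_id"] == min(prom_hits)[1]
                continue
            body_hits = []
            for m in chr1_models:
                ov = min(e, m.end) - max(s, m.start)
                if ov >= 1:
                    d = 0 if s <= m.tss < e else min(abs(s - m.tss),
                                                     abs(m.tss - (e - 1)))
                    body_hits.append((-ov, d, m.gene_id))
            if body_hits:
                assert row["category"] == "gene_body"
                assert row["gene_id"] == min(body_hits)[2]
            else:
                assert row["category"] == "other"

    def test_categories_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(32)
        models = simulate_gene_models(30, seed=6)
        starts = rng.integers(0, 300_000, 100)
        peaks = new_peak_set(["chr1"] * 100, starts,
                             starts + rng.integers(50, 500, 100),
                             [f"p{i}" for i in range(100)])
        out = assign_peaks(peaks, [m for m in models if m.chrom == "chr1"])
        assert out["category"].isin(["promoter", "gene_body", "other"]).all()


class TestConservation:
    def test_constant_track(self):
        track = track_frame([("chr1", 0, 1000, 0.8)])
        peaks = new_peak_set(["chr1", "chr1"], [10, 500], [110, 900],
                             ["a", "b"])
        assert np.allclose(peak_conservation(track, peaks), 0.8)

    def test_half_zero_half_one(self):
        track = track_frame([("chr1", 0, 50, 0.0), ("chr1", 50, 100, 1.0)])
        peaks = new_peak_set(["chr1"], [0], [100], ["p"])
        assert peak_conservation(track, peaks).iloc[0] == pytest.approx(0.5)

    def test_uncovered_bases_score_zero(self):
        track = track_frame([("chr1", 0, 50, 1.0)])
        peaks = new_peak_set(["chr1"], [0], [100], ["p"])
        assert peak_conservation(track, peaks).iloc[0] == pytest.approx(0.5)

    def test_matches_per_base_oracle_on_random_tracks(self):
        rng = np.random.default_rng(33)
        track = random_track(rng)
        starts = rng.integers(0, 190_000, 40)
        peaks = new_peak_set(["chr1"] * 40, starts,
                             starts + rng.integers(20, 400, 40),
                             [f"p{i}" for i in range(40)])
        means = peak_conservation(track, peaks)
        for i, row in peaks.iterrows():
            assert means.iloc[i] == pytest.approx(per_base_mean_oracle(
                track, "chr1", row["start"], row["end"]))

    def test_means_stay_in_unit_interval(self):
        rng = np.random.default_rng(34)
        track = random_track(rng)
        starts = rng.integers(0, 190_000, 30)
        peaks = new_peak_set(["chr1"] * 30, starts, starts + 100,
                             [f"p{i}" for i in range(30)])
        means = peak_conservation(track, peaks)
        assert ((means >= 0) & (means <= 1)).all()


class TestRegionSignal:
    def test_uniform_coverage_equal_regions(self):
        cov = track_frame([("chr1", 0, 10_000, 3.0)])
        regions = new_peak_set(["chr1", "chr1"], [100, 5000], [600, 5500],
                               ["a", "b"])
        vals = region_signal_fpkm(cov, regions)
        assert vals.iloc[0] == pytest.approx(vals.iloc[1])

    def test_empty_region_gives_zero(self):
        cov = track_frame([("chr1", 0, 100, 5.0)])
        regions = new_peak_set(["chr1"], [5000], [5500], ["far"])
        assert region_signal_fpkm(cov, regions).iloc[0] == 0.0

    def test_doubling_coverage_invariant(self):
        rng = np.random.default_rng(35)
        cov = random_track(rng)
        cov["score"] = cov["score"] + 0.1
        regions = new_peak_set(["chr1"] * 5, [0, 100, 5000, 9000, 20_000],
                               [90, 700, 5600, 9900, 21_000],
                               list("abcde"))
        v1 = region_signal_fpkm(cov, regions)
        cov2 = cov.copy()
        cov2["score"] = cov2["score"] * 2
        assert np.allclose(v1, region_signal_fpkm(cov2, regions))

    def test_zero_total_rejected(self):
        cov = track_frame([("chr1", 0, 100, 0.0)])
        with pytest.raises(ValueError, match="zero total"):
            region_signal_fpkm(cov, new_peak_set(["chr1"], [0], [10], ["p"]))


class TestCompareGroups:
    def test_identical_groups_give_half(self):
        vals = np.array([0.3, 0.5, 0.7])
        cmp_ = compare_groups(vals, vals.copy())
        assert cmp_.statistic == 0.0
        assert cmp_.pvalue == 0.5

    def test_planted_contrast_yields_tiny_p(self):
        rng = np.random.default_rng(36)
        a = rng.normal(0.4, 0.1, 100)
        b = rng.normal(0.6, 0.1, 100)
        cmp_ = compare_groups(a, b, alternative="less")
        assert cmp_.pvalue < 1e-6
        assert cmp_.median_a < cmp_.median_b

    def test_swapped_groups_with_reversed_alternative(self):
        rng = np.random.default_rng(37)
        a = rng.normal(0.4, 0.1, 30)
        b = rng.normal(0.5, 0.15, 30)
        p1 = compare_groups(a, b, alternative="less").pvalue
        p2 = compare_groups(b, a, alternative="greater").pvalue
        assert p1 == pytest.approx(p2)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups([0.5], [0.4, 0.6])


class TestMetagene:
    def test_constant_track_gives_constant_profile(self):
        track = track_frame([("chr1", 0, 100_000, 0.7)])
        rng = np.random.default_rng(38)
        starts = rng.integers(0, 90_000, 20)
        peaks = new_peak_set(["chr1"] * 20, starts,
                             starts + rng.integers(120, 900, 20),
                             [f"p{i}" for i in range(20)])
        prof = metagene_conservation(track, peaks, n_bins=50)
        assert np.allclose(prof, 0.7)

    def test_center_enriched_track_peaks_in_interior_bins(self):
        rows = []
        peaks_rows = ([], [], [])
        for k in range(10):
            s = k * 2000
            rows += [("chr1", s, s + 300, 0.2),
                     ("chr1", s + 300, s + 700, 0.9),
                     ("chr1", s + 700, s + 1000, 0.2)]
            peaks_rows[0].append(s)
            peaks_rows[1].append(s + 1000)
            peaks_rows[2].append(f"p{k}")
        track = track_frame(rows)
        peaks = new_peak_set(["chr1"] * 10, peaks_rows[0], peaks_rows[1],
                             peaks_rows[2])
        prof = metagene_conservation(track, peaks, n_bins=10)
        assert prof[4] > prof[0] and prof[5] > prof[9]

    def test_single_peak_profile_equals_binned_scores(self):
        track = track_frame([("chr1", 0, 50, 0.1), ("chr1", 50, 100, 0.9)])
        peaks = new_peak_set(["chr1"], [0], [100], ["p"])
        prof = metagene_conservation(track, peaks, n_bins=2)
        assert np.allclose(prof, [0.1, 0.9])

    def test_empty_peak_set_rejected(self):
        track = track_frame([("chr1", 0, 10, 0.5)])
        with pytest.raises(ValueError, match="empty"):
            metagene_conservation(track, new_peak_set([], [], [], []))


class TestDifferentialPeakFilter:
    def test_strict_boundary(self):
        df = new_peak_set(["chr1"] * 3, [0, 100, 200], [50, 150, 250],
                          ["a", "b", "c"])
        df["fold_change"] = [2.0, 2.1, -2.5]
        out = filter_differential_peaks(df)
        assert list(out["peak_id"]) == ["b", "c"]

    def test_empty_input_empty_output(self):
        df = new_peak_set([], [], [], [])
        df["fold_change"] = pd.Series(dtype=float)
        assert len(filter_differential_peaks(df)) == 0


class TestSNPOverlap:
    def _snps(self, positions):
        return pd.DataFrame({"chrom": "chr1", "start": positions,
                             "end": [p + 1 for p in positions],
                             "snp_id": [f"rs{p}" for p in positions]})

    def test_containment_and_half_open_boundary(self):
        peaks = new_peak_set(["chr1"], [100], [200], ["pk"])
        per_snp, _ = snp_overlap(self._snps([150, 200]), peaks)
        assert list(per_snp["snp_id"]) == ["rs150"]

    def test_counts_match_allpairs_oracle(self):
        rng = np.random.default_rng(39)
        starts = rng.integers(0, 50_000, 80)
        peaks = new_peak_set(["chr1"] * 80, starts,
                             starts + rng.integers(50, 600, 80),
                             [f"p{i}" for i in range(80)])
        positions = rng.integers(0, 55_000, 120)
        per_snp, summary = snp_overlap(self._snps(list(positions)), peaks)
        expected = sum(
            int(s <= pos < e)
            for pos in positions
            for s, e in zip(peaks["start"], peaks["end"]))
        assert len(per_snp) == expected
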