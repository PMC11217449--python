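"""EHH / iES / XP-EHH machinery and the windowed peak caller."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syncerus import (
    HaplotypeMatrix,
    IntervalSet,
    ParameterError,
    ScanResult,
    UndefinedProfileError,
    call_sweep_peaks,
    ehh_profile,
    integrate_ies,
    make_site_table,
    overlap_loci,
    site_ehh_curves,
    smooth_scores,
    xpehh_scan,
)
from syncerus.sweep import top_smoothed_location
from syncerus.simulate import SweepConfig, sim_sweep_pair


def hap_matrix(rows, pos=None, contig="1"):
    H = np.asarray(rows, dtype=np.uint8)
    m = H.shape[1]
    if pos is None:
        pos = np.arange(m) * 10_000
    sites = make_site_table([contig] * m, pos, ["A"] * m, ["G"] * m)
    return HaplotypeMatrix(haplotypes=H, sites=sites,
                           contig_lengths={contig: int(max(pos)) + 10_000})


def brute_force_ehh(H, carriers, core, x, direction):
    """Fraction of carrier pairs identical over the interval core..x."""
    lo, hi = (x, core) if direction == "left" else (core, x)
    segs = [tuple(H[c, lo:hi + 1]) for c in carriers]
    n = len(segs)
    same = sum(1 for a, b in itertools.combinations(segs, 2) if a == b)
    return same / (n * (n - 1) / 2)


class TestEhhProfile:
    def test_core_value_is_one(self, rng):
        H = rng.integers(0, 2, size=(10, 20)).astype(np.uint8)
        H[:, 10] = [0, 1] * 5
        prof = ehh_profile(hap_matrix(H), core=10, allele=1, direction="right")
        assert prof.ehh[0] == 1.0

    def test_identical_carriers_stay_at_one(self):
        H = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.uint8), (4, 1))
        prof = ehh_profile(hap_matrix(H), core=2, allele=0, direction="right")
        assert np.all(prof.ehh == 1.0)
        assert len(prof.ehh) == 3  # core plus two sites rightward

    def test_six_carriers_worked_example(self):
        # carriers split 4/2 at the next site, then 2/2/2
        H = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 1],
            [1, 0, 1],
            [1, 1, 0],
            [1, 1, 0],
        ], dtype=np.uint8)
        prof = ehh_profile(hap_matrix(H), core=0, allele=1, direction="right",
                           truncation=0.0)
        assert prof.ehh[1] == pytest.approx(7 / 15)   # (C(4,2)+C(2,2))/C(6,2)
        assert prof.ehh[2] == pytest.approx(3 / 15)
        # brute force agrees
        assert prof.ehh[1] == pytest.approx(
            brute_force_ehh(H, range(6), 0, 1, "right"))
        assert prof.ehh[2] == pytest.approx(
            brute_force_ehh(H, range(6), 0, 2, "right"))

    def test_fewer_than_two_carriers_rejected(self):
        H = np.zeros((4, 5), dtype=np.uint8)
        H[0, 2] = 1
        with pytest.raises(UndefinedProfileError):
            ehh_profile(hap_matrix(H), core=2, allele=1, direction="left")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 10).map(lambda k: 2 * k),
           st.integers(5, 50))
    def test_matches_brute_force_pair_counting(self, seed, n_hap, n_sites):
        """EHH equals exhaustive pair-identity counting on random instances."""
        r = np.random.default_rng(seed)
        H = (r.random((n_hap, n_sites)) < 0.5).astype(np.uint8)
        core = int(r.integers(0, n_sites))
        for allele in (0, 1):
            carriers = np.flatnonzero(H[:, core] == allele)
            if len(carriers) < 2:
                continue
            for direction in ("left", "right"):
                prof = ehh_profile(hap_matrix(H), core=core, allele=allele,
                                   direction=direction, truncation=0.0,
                                   max_extend_cm=1e9)
                for i, x in enumerate(prof.site_indices):
                    assert prof.ehh[i] == pytest.approx(
                        brute_force_ehh(H, carriers, core, int(x), direction))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_non_increasing(self, seed):
        r = np.random.default_rng(seed)
        H = (r.random((12, 30)) < r.uniform(0.2, 0.8)).astype(np.uint8)
        core = int(r.integers(0, 30))
        for allele in (0, 1):
            if (H[:, core] == allele).sum() < 2:
                continue
            prof = ehh_profile(hap_matrix(H), core=core, allele=allele,
                               direction="right", truncation=0.0)
            assert np.all(np.diff(prof.ehh) <= 1e-12)


class TestIntegrateIes:
    def test_rectangle_area(self):
        # EHH == 1 for exactly 1 cM on each side -> iES = 2.0
        pos = np.array([0, 500_000, 1_000_000, 1_500_000, 2_000_000])
        H = np.tile(np.array([0, 0, 1, 0, 0], dtype=np.uint8), (4, 1))
        H[2:, :] = [1, 1, 0, 1, 1]
        hm = hap_matrix(H, pos=pos)
        left = ehh_profile(hm, core=2, allele=1, direction="left", truncation=0.0)
        right = ehh_profile(hm, core=2, allele=1, direction="right", truncation=0.0)
        assert integrate_ies(left, right) == pytest.approx(2.0)

    def test_immediate_truncation_gives_near_zero(self, rng):
        H = rng.integers(0, 2, size=(20, 9)).astype(np.uint8)
        H[:, 4] = [0, 1] * 10  # polymorphic core, random flanks
        hm = hap_matrix(H)
        left = ehh_profile(hm, core=4, allele=1, direction="left", truncation=0.9)
        right = ehh_profile(hm, core=4, allele=1, direction="right", truncation=0.9)
        assert integrate_ies(left, right) <= 0.05

    def test_trapezoid_matches_fine_grid_riemann(self, rng):
        ha, _, _ = sim_sweep_pair(SweepConfig(seed=5, n_sites=200, n_haplotypes=20))
        left, right = site_ehh_curves(ha, 100, truncation=0.0)
        total = integrate_ies(left, right)
        oracle = 0.0
        for prof in (left, right):
            x = np.abs(prof.cm - prof.cm[0])
            grid = np.linspace(0, x[-1], 200_001)
            oracle += np.interp(grid, x, prof.ehh).sum() * (x[-1] / 200_000)
        assert total == pytest.approx(oracle, abs=1e-4)


class TestXpehhScan:
    def test_identical_populations_give_zero_raw(self, rng):
        H = rng.integers(0, 2, size=(12, 60)).astype(np.uint8)
        hm = hap_matrix(H)
        scan = xpehh_scan(hm, hap_matrix(H.copy()))
        assert np.allclose(scan.table["raw"], 0.0)

    def test_swapping_populations_negates_raw(self):
        ha, hb, _ = sim_sweep_pair(SweepConfig(seed=9, n_sites=150, n_haplotypes=16))
        s1 = xpehh_scan(ha, hb)
        s2 = xpehh_scan(hb, ha)
        assert np.allclose(s1.table["raw"], -s2.table["raw"], atol=1e-12)

    def test_standardized_scores_have_zero_mean_unit_sd(self):
        ha, hb, _ = sim_sweep_pair(SweepConfig(seed=3, n_sites=300, n_haplotypes=20))
        scan = xpehh_scan(ha, hb)
        s = scan.table["std"].to_numpy()
        assert abs(s.mean()) < 1e-6
        assert abs(s.std(ddof=0) - 1) < 1e-6

    def test_sweep_localized_single_replicate(self):
        ha, hb, truth = sim_sweep_pair(SweepConfig(seed=1))
        scan = xpehh_scan(ha, hb)
        contig, bp = top_smoothed_location(scan, window_snps=50)
        assert abs(bp - truth["core_bp"]) <= 50_000


def make_scan(scores, pos=None, contig="1"):
    scores = np.asarray(scores, dtype=float)
    if pos is None:
        pos = np.arange(len(scores)) * 1000
    table = pd.DataFrame({"contig": contig, "pos": pos, "ies_a": 1.0,
                          "ies_b": 1.0, "raw": scores, "std": scores})
    return ScanResult(table=table)


def peak_oracle(scores, pos, w, enter, exit):
    """Independent window-mean crossing computation (plain loops)."""
    means = [np.mean(scores[i:i + w]) for i in range(len(scores) - w + 1)]
    above = [abs(m) >= exit for m in means]
    peaks, i = [], 0
    while i < len(means):
        if above[i]:
            j = i
            while j + 1 < len(means) and above[j + 1]:
                j += 1
            if any(abs(means[k]) > enter for k in range(i, j + 1)):
                peaks.append((int(pos[i]), int(pos[j + w - 1]) + 1))
            i = j + 1
        else:
            i += 1
    # merge overlaps
    merged = []
    for s, e in peaks:
        if merged and s < merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


class TestPeakCaller:
    def test_all_zero_scores_give_no_peaks(self):
        assert call_sweep_peaks(make_scan(np.zeros(500)), window_snps=100).empty

    def test_constant_high_plateau_spans_scored_snps(self):
        scan = make_scan(np.full(400, 5.0))
        peaks = call_sweep_peaks(scan, window_snps=100, enter=4, exit=2)
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert p["start"] == 0 and p["end"] == 399 * 1000 + 1
        assert p["n_snps"] == 400

    def test_crafted_vector_matches_window_mean_oracle(self):
        scores = np.concatenate([
            np.zeros(400), np.full(500, 3.0), np.full(1200, 5.0),
            np.full(500, 3.0), np.zeros(400)])
        pos = np.arange(len(scores)) * 1000
        peaks = call_sweep_peaks(make_scan(scores), window_snps=1000,
                                 enter=4.0, exit=2.0)
        oracle = peak_oracle(scores, pos, 1000, 4.0, 2.0)
        assert len(oracle) == 1
        assert list(zip(peaks["start"], peaks["end"])) == oracle

    def test_negative_peaks_detected_by_absolute_value(self):
        scores = np.concatenate([np.zeros(200), np.full(300, -5.0), np.zeros(200)])
        peaks = call_sweep_peaks(make_scan(scores), window_snps=100,
                                 enter=4.0, exit=2.0)
        oracle = peak_oracle(scores, np.arange(700) * 1000, 100, 4.0, 2.0)
        assert list(zip(peaks["start"], peaks["end"])) == oracle

    def test_translation_invariance_of_boundaries(self):
        scores = np.concatenate([np.zeros(150), np.full(200, 6.0), np.zeros(150)])
        pos = np.arange(500) * 777
        p1 = call_sweep_peaks(make_scan(scores, pos), window_snps=100)
        p2 = call_sweep_peaks(make_scan(scores, pos + 12345), window_snps=100)
        assert np.array_equal(p2["start"] - 12345, p1["start"])
        assert np.array_equal(p2["end"] - 12345, p1["end"])

    def test_short_contig_skipped(self):
        assert call_sweep_peaks(make_scan(np.full(50, 9.0)), window_snps=100).empty

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 5000))
    def test_random_vectors_match_oracle(self, seed):
        r = np.random.default_rng(seed)
        # blocky random score vector exercising entry/exit crossings
        blocks = [np.full(r.integers(20, 120), r.choice([-6, -3, 0, 3, 6]))
                  for _ in range(8)]
        scores = np.concatenate(blocks).astype(float)
        pos = np.arange(len(scores)) * 100
        peaks = call_sweep_peaks(make_scan(scores, pos), window_snps=50,
                                 enter=4.0, exit=2.0)
        oracle = peak_oracle(scores, pos, 50, 4.0, 2.0)
        assert list(zip(peaks["start"], peaks["end"])) == oracle


class TestOverlapLoci:
    def make_peaks(self, rows):
        return pd.DataFrame(rows, columns=["contig", "start", "end",
                                           "max_abs_smoothed", "n_snps"])

    def test_disjoint_and_contained(self):
        peaks = self.make_peaks([("1", 100, 200, 5.0, 10),
                                 ("1", 1000, 2000, 6.0, 50)])
        genes = IntervalSet(pd.DataFrame(
            [("1", 300, 400, "gA"), ("1", 1200, 1300, "gB")],
            columns=["contig", "start", "end", "name"]))
        out = overlap_loci(peaks, genes)
        assert out["features"].tolist() == [[], ["gB"]]

    def test_unknown_contig_rejected(self):
        peaks = self.make_peaks([("chrZ", 0, 10, 5.0, 1)])
        genes = IntervalSet(pd.DataFrame([("1", 0, 5, "g")],
                                         columns=["contig", "start", "end", "name"]))
        with pytest.raises(ParameterError, match="chrZ"):
            overlap_loci(peaks, genes)

    def test_random_peaks_match_quadratic_oracle(self, rng):
        peaks = self.make_peaks([
            ("1", int(s), int(s) + int(rng.integers(50, 500)), 5.0, 10)
            for s in rng.integers(0, 100_000, 20)])
        genes_df = pd.DataFrame(
            [("1", int(s), int(s) + int(rng.integers(100, 800)), f"g{i}")
             for i, s in enumerate(rng.integers(0, 100_000, 50))],
            columns=["contig", "start", "end", "name"])
        second_df = pd.DataFrame(
            [("1", int(s), int(s) + 300) for s in rng.integers(0, 100_000, 10)],
            columns=["contig", "start", "end"])
        out = overlap_loci(peaks, IntervalSet(genes_df),
                           second=IntervalSet(second_df))
        for _, row in out.iterrows():
            expected = sorted(
                g["name"] for _, g in genes_df.iterrows()
                if g["start"] < row["end"] and row["start"] < g["end"])
            assert row["features"] == expected
            exp2 = any(s["start"] < row["end"] and row["start"] < s["end"]
                       for _, s in second_df.iterrows())
            assert row["in_second"] == exp2
        expected_genes = sorted({g for f, s in zip(out["features"], out["in_second"])
                                 if s for g in f})
        assert out.attrs["second_genes"] == expected_genes
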