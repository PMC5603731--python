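"""Interval analytics: overlap, TSS annotation, profiles, multivalence."""

import numpy as np
import pandas as pd
import pytest

from cgireader.intervals import (
    annotate_tss,
    call_nmis,
    classify_de,
    classify_expression,
    enrichment_matrix,
    group_difference_test,
    metaprofile,
    multivalence_index,
    overlap_venn,
    percentile_bins,
    rank_correlation,
)
from cgireader.simulate import GenomeSimParams, simulate_genome
from conftest import make_track, random_interval_set


def ivs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def brute_force_hits(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """O(n*m) all-pairs >= 1 bp intersection oracle."""
    hits = np.zeros(len(a), dtype=bool)
    for i, (ca, sa, ea) in enumerate(
        zip(a["chrom"], a["start"], a["end"])
    ):
        for cb, sb, eb in zip(b["chrom"], b["start"], b["end"]):
            if ca == cb and sa < eb and sb < ea:
                hits[i] = True
                break
    return hits


class TestOverlapVenn:
    def test_hand_enumeration(self):
        peaks = ivs([("c", 0, 10), ("c", 20, 30), ("c", 50, 60)])
        nmis = ivs([("c", 5, 15), ("c", 25, 35)])
        v = overlap_venn(peaks, nmis)
        assert (v.peaks_overlapping, v.peaks_only) == (2, 1)
        assert (v.nmis_overlapped, v.nmis_only) == (2, 0)
        assert v.frac_peaks_at_nmis == pytest.approx(2 / 3)
        assert v.frac_nmis_occupied == pytest.approx(1.0)

    def test_identical_and_disjoint(self):
        a = ivs([("c", 0, 10), ("c", 20, 30)])
        assert overlap_venn(a, a.copy()).frac_peaks_at_nmis == 1.0
        b = ivs([("c", 100, 110)])
        v = overlap_venn(a, b)
        assert v.frac_peaks_at_nmis == 0.0 and v.frac_nmis_occupied == 0.0

    def test_adjacent_intervals_do_not_overlap(self):
        """Half-open: [0,10) and [10,20) share no base."""
        v = overlap_venn(ivs([("c", 0, 10)]), ivs([("c", 10, 20)]))
        assert v.peaks_overlapping == 0

    def test_empty_set_fractions_undefined(self):
        v = overlap_venn(ivs([]), ivs([("c", 0, 10)]))
        assert np.isnan(v.frac_peaks_at_nmis)
        assert v.frac_nmis_occupied == 0.0

    def test_counts_conserve_and_match_brute_force(self, rng):
        for _ in range(50):
            peaks = random_interval_set(rng, int(rng.integers(1, 25)))
            nmis = random_interval_set(rng, int(rng.integers(1, 20)))
            v = overlap_venn(peaks, nmis)
            assert v.peaks_overlapping + v.peaks_only == len(peaks)
            assert v.nmis_overlapped + v.nmis_only == len(nmis)
            assert v.peaks_overlapping == brute_force_hits(peaks, nmis).sum()
            assert v.nmis_overlapped == brute_force_hits(nmis, peaks).sum()


class TestAnnotateTss:
    def test_boundary_convention(self):
        nmis = ivs([("c", 0, 10)])
        inside = pd.DataFrame({"chrom": ["c"], "pos": [5], "strand": ["+"]})
        at_end = pd.DataFrame({"chrom": ["c"], "pos": [10], "strand": ["+"]})
        assert annotate_tss(nmis, inside, [True]).has_tss[0]
        assert not annotate_tss(nmis, at_end, [True]).has_tss[0]

    def test_two_by_two_percentages(self):
        nmis = ivs([("c", 0, 10), ("c", 20, 30), ("c", 40, 50), ("c", 60, 70)])
        tss = pd.DataFrame(
            {"chrom": ["c", "c"], "pos": [5, 45], "strand": ["+", "-"]}
        )
        ann = annotate_tss(nmis, tss, bound=[True, True, False, False])
        assert ann.pct_tss_bound == pytest.approx(50.0)
        assert ann.pct_tss_unbound == pytest.approx(50.0)
        assert ann.table.loc["bound", "tss"] == 1
        assert ann.table.to_numpy().sum() == 4

    def test_window_extension(self):
        nmis = ivs([("c", 100, 110)])
        tss = pd.DataFrame({"chrom": ["c"], "pos": [95], "strand": ["+"]})
        assert not annotate_tss(nmis, tss, [True], window=0).has_tss[0]
        assert annotate_tss(nmis, tss, [True], window=10).has_tss[0]


class TestMetaprofile:
    def test_uniform_track_flat_profile(self):
        track = make_track(np.full(100, 3.3))
        anchors = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [2000, 5000, 8000],
             "strand": ["+", "-", "+"]}
        )
        prof = metaprofile(track, anchors, flank=1000, n_bins=10)
        assert np.allclose(prof["mean"], 3.3)
        assert np.all(prof["n_anchors"] == 3)

    def test_step_signal_around_anchor(self):
        """Track 0 before the anchor, 10 after: left half 0, right half 10."""
        vals = np.zeros(100)
        vals[50:] = 10.0
        track = make_track(vals, bin_size=100)
        anchors = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [5000], "strand": ["+"]}
        )
        prof = metaprofile(track, anchors, flank=2000, n_bins=8)
        assert np.allclose(prof["mean"][:4], 0.0)
        assert np.allclose(prof["mean"][4:], 10.0)

    def test_minus_strand_orientation(self):
        """Mirror-symmetric anchors on opposite strands contribute equally."""
        vals = np.zeros(100)
        vals[50:] = 10.0
        track = make_track(vals, bin_size=100)
        plus = metaprofile(
            track,
            pd.DataFrame({"chrom": ["chr1"], "pos": [5000], "strand": ["+"]}),
            flank=2000, n_bins=8,
        )
        minus = metaprofile(
            track,
            pd.DataFrame({"chrom": ["chr1"], "pos": [5000], "strand": ["-"]}),
            flank=2000, n_bins=8,
        )
        assert np.allclose(minus["mean"], plus["mean"][::-1])

    def test_out_of_coverage_anchor_excluded(self):
        track = make_track(np.ones(10))
        anchors = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [500, 10**6],
             "strand": ["+", "+"]}
        )
        prof = metaprofile(track, anchors, flank=200, n_bins=4)
        assert prof.attrs["excluded_anchors"] == 1
        assert np.all(prof["n_anchors"] == 1)


class TestPercentileBins:
    def test_equal_population(self):
        bins = percentile_bins(np.arange(1, 11), 5)
        assert np.array_equal(bins, np.repeat([0, 1, 2, 3, 4], 2))

    def test_shift_invariance(self, rng):
        v = rng.uniform(0, 1, 57)
        assert np.array_equal(
            percentile_bins(v, 7), percentile_bins(v + 100.0, 7)
        )

    def test_ties_stable_order(self):
        bins = percentile_bins(np.array([1.0, 1.0, 2.0, 3.0]), 2)
        assert np.array_equal(bins, [0, 0, 1, 1])
        assert np.bincount(bins).tolist() == [2, 2]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            percentile_bins(np.ones(10), 2)


class TestMultivalenceIndex:
    def _matrix(self, model, strength, seed, n_nmis=500, noise=True):
        g = simulate_genome(
            GenomeSimParams(
                n_nmis=n_nmis, occupancy_model=model,
                multivalence_strength=strength, count_noise=noise, seed=seed,
            )
        )
        return enrichment_matrix(g.tracks, g.nmis)

    def test_exact_proportionality_gives_zero(self):
        m = self._matrix("monovalent", 0.0, seed=1, n_nmis=200, noise=False)
        res = multivalence_index(m, signal="ip", rng=0)
        assert res.index == 0.0
        assert not res.is_multivalent

    def test_multivalent_generator_monotone_ratio(self):
        m = self._matrix("multivalent", 2.0, seed=2, n_nmis=200, noise=False)
        res = multivalence_index(m, signal="ip", rng=0)
        assert res.index == pytest.approx(1.0)
        assert res.is_multivalent
        assert np.all(np.diff(res.ratio) > 0)

    def test_relative_enrichment_normalized_to_max(self):
        m = self._matrix("multivalent", 2.0, seed=3, n_nmis=200)
        res = multivalence_index(m, signal="ip", rng=0)
        rel = res.relative_enrichment
        assert rel.max().max() == pytest.approx(1.0)
        assert (rel.to_numpy() >= 0).all() and (rel.to_numpy() <= 1 + 1e-12).all()

    def test_permuted_signal_within_null_band(self, rng):
        """Destroying the H3K4me3 link puts the index inside the band."""
        m = self._matrix("multivalent", 2.0, seed=4, n_nmis=300)
        inside = 0
        n_trials = 20
        for t in range(n_trials):
            perm = m.copy()
            perm["ip"] = rng.permutation(perm["ip"].to_numpy())
            res = multivalence_index(perm, signal="ip", rng=t)
            inside += not res.is_multivalent
        assert inside >= 0.95 * n_trials

    def test_missing_column_and_small_input_rejected(self):
        m = self._matrix("monovalent", 0.0, seed=5, n_nmis=120)
        with pytest.raises(KeyError):
            multivalence_index(m, signal="nope")
        with pytest.raises(ValueError):
            multivalence_index(m, signal="ip", n_bins=50)


class TestStatistics:
    def test_rank_correlation_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rank_correlation(x, x) == 1.0
        assert rank_correlation(x, -x) == -1.0
        assert rank_correlation(x, [1.0, 3.0, 2.0, 4.0]) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            rank_correlation(x, np.ones(4))

    def test_mann_whitney_exact_extreme(self):
        """Fully separated n=3 groups: U=0, exact two-sided p = 2/20."""
        p = group_difference_test([1, 2, 3], [10, 11, 12], mode="mann_whitney")
        assert p == pytest.approx(0.1)

    def test_wilcoxon_zero_differences_error(self):
        with pytest.raises(ValueError):
            group_difference_test(
                [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="wilcoxon_signed_rank"
            )

    def test_wilcoxon_detects_paired_shift(self, rng):
        a = rng.normal(0, 1, 30)
        p = group_difference_test(a, a + 2.0, mode="wilcoxon_signed_rank")
        assert p < 1e-4

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            group_difference_test([1, 2], [3, 4], mode="bogus")


class TestClassifiers:
    def test_de_thresholds(self):
        lfc_cut = np.log2(1.5)
        table = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d", "e", "f"],
                "log2fc": [-1.0, -0.5, 1.0, lfc_cut, -lfc_cut, 2.0],
                "fdr": [0.001, 0.001, 0.02, 0.01, 0.01, np.nan],
            }
        )
        out = classify_de(table)
        assert list(out["class"]) == [
            "down",             # clears both gates
            "not_significant",  # |FC| ~1.41 < 1.5
            "not_significant",  # FDR 0.02 > 0.01
            "up",               # boundary inclusive
            "down",             # boundary inclusive
            "flagged",          # missing FDR
        ]
        counts = out.attrs["counts"]
        assert counts == {"down": 2, "up": 1, "not_significant": 2, "flagged": 1}
        assert sum(counts.values()) == len(table)

    def test_de_row_order_invariance(self, rng):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "log2fc": rng.normal(0, 1, 200),
                "fdr": rng.uniform(0, 1, 200),
            }
        )
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert classify_de(table).attrs["counts"] == \
            classify_de(shuffled).attrs["counts"]

    def test_de_fdr_range_validated(self):
        table = pd.DataFrame(
            {"gene": ["a"], "log2fc": [1.0], "fdr": [1.5]}
        )
        with pytest.raises(ValueError):
            classify_de(table)

    @pytest.mark.parametrize(
        "value, label",
        [(-3.0, "lowly_expressed"), (-2.5, "expressed"), (0.0, "expressed"),
         (-2.5001, "lowly_expressed")],
    )
    def test_expression_threshold_strict(self, value, label):
        assert classify_expression(value) == label


class TestCallNmis:
    def test_threshold_and_merge(self):
        vals = np.array([0.0, 5.0, 5.0, 0.0, 0.0, 5.0, 0.0])
        track = make_track(vals, bin_size=100)
        out = call_nmis(track, threshold=1.0)
        assert list(zip(out["start"], out["end"])) == [(100, 300), (500, 600)]
        merged = call_nmis(track, threshold=1.0, gap_max=300)
        assert list(zip(merged["start"], merged["end"])) == [(100, 600)]
        wide_only = call_nmis(track, threshold=1.0, min_width=150)
        assert list(zip(wide_only["start"], wide_only["end"])) == [(100, 300)]
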