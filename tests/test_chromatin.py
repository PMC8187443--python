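"""Chromatin-module tests: domain segmentation, quartile labels, IncRatio
against a brute-force oracle, eigen correlation and anchor profiles."""

import numpy as np
import pandas as pd
import pytest

from rerepkit import chromatin, simcore
from rerepkit.errors import (InvalidConfigError, RerepKitError,
                             TooFewDomainsError, UndefinedCorrelationError)
from rerepkit.io import track_from_values

from conftest import random_intervals


def brute_force_overlaps(sample, reference):
    """O(n^2) all-pairs oracle: sample intervals touching >= 1 reference."""
    n = 0
    for s in sample.itertuples(index=False):
        for r in reference.itertuples(index=False):
            if s.chrom == r.chrom and s.start < r.end and r.start < s.end:
                n += 1
                break
    return n


class TestSegmentDomains:
    def test_flat_zero_track_yields_nothing(self):
        track = track_from_values(np.zeros(100))
        assert len(chromatin.segment_domains(track)) == 0

    def test_single_block_yields_one_domain_with_max_height(self):
        v = np.zeros(100)
        v[40:50] = [1, 2, 3, 9, 3, 2, 1, 1, 1, 1]
        d = chromatin.segment_domains(track_from_values(v, bin_width=1000), 0.5)
        assert len(d) == 1
        row = d.intervals.iloc[0]
        assert (row["start"], row["end"]) == (40_000, 50_000)
        assert row["peak_height"] == 9

    def test_sub_min_gap_blocks_merge(self):
        v = np.zeros(60)
        v[10:15] = 5
        v[17:22] = 7
        merged = chromatin.segment_domains(track_from_values(v, bin_width=1000),
                                           0.5, min_gap_bp=3000)
        assert len(merged) == 1
        assert merged.intervals.iloc[0]["peak_height"] == 7
        split = chromatin.segment_domains(track_from_values(v, bin_width=1000),
                                          0.5, min_gap_bp=1000)
        assert len(split) == 2

    def test_min_size_filter_drops_short_domains(self):
        v = np.zeros(50)
        v[5] = 9
        v[20:30] = 9
        d = chromatin.segment_domains(track_from_values(v, bin_width=1000),
                                      0.5, min_size_bp=5000)
        assert len(d) == 1

    def test_domains_cover_exactly_above_threshold_runs(self):
        rng = np.random.default_rng(0)
        v = rng.random(300)
        track = track_from_values(v, bin_width=100)
        d = chromatin.segment_domains(track, 0.7)
        covered = np.zeros(300, dtype=bool)
        for row in d.intervals.itertuples(index=False):
            covered[row.start // 100:row.end // 100] = True
        np.testing.assert_array_equal(covered, v > np.quantile(v, 0.7))


class TestQuartileStratify:
    def make(self, heights):
        iv = pd.DataFrame({"chrom": "chr1",
                           "start": np.arange(len(heights)) * 1000,
                           "end": np.arange(len(heights)) * 1000 + 500,
                           "peak_height": heights,
                           "size_bp": 500})
        return chromatin.DomainSet(iv)

    def test_eight_distinct_heights_split_two_per_group(self):
        d = chromatin.quartile_stratify(self.make([8, 7, 6, 5, 4, 3, 2, 1.0]))
        labels = d.intervals["quartile"].tolist()
        assert labels == ["high", "high", "mid-high", "mid-high",
                          "mid-low", "mid-low", "low", "low"]

    def test_ties_broken_by_coordinate(self):
        d = chromatin.quartile_stratify(self.make([5.0] * 8))
        counts = d.intervals["quartile"].value_counts()
        assert set(counts) == {2}
        assert d.intervals.iloc[0]["quartile"] == "high"

    def test_labels_invariant_under_input_permutation(self):
        rng = np.random.default_rng(1)
        base = self.make(rng.random(20))
        ref = chromatin.quartile_stratify(base).intervals.sort_values("start")
        for _ in range(20):
            shuffled = chromatin.DomainSet(
                base.intervals.sample(frac=1, random_state=rng.integers(1 << 30))
                .reset_index(drop=True))
            got = chromatin.quartile_stratify(shuffled).intervals.sort_values("start")
            assert got["quartile"].tolist() == ref["quartile"].tolist()

    def test_too_few_domains_rejected(self):
        with pytest.raises(TooFewDomainsError):
            chromatin.quartile_stratify(self.make([1, 2, 3.0]))


class TestIncRatio:
    def test_formula_on_known_counts(self):
        sample = pd.DataFrame({"chrom": "c", "start": [0, 100, 200, 300],
                               "end": [50, 150, 250, 350]})
        reference = pd.DataFrame({"chrom": "c",
                                  "start": [10, 120, 500, 600, 700, 800],
                                  "end": [20, 130, 510, 610, 710, 810]})
        rep = chromatin.inc_ratio(sample, reference)
        assert rep.n_overlaps == 2
        assert rep.inc_ratio == pytest.approx(2 / 10)

    def test_disjoint_sets_give_zero(self):
        a = pd.DataFrame({"chrom": "c", "start": [0], "end": [10]})
        b = pd.DataFrame({"chrom": "c", "start": [20], "end": [30]})
        assert chromatin.inc_ratio(a, b).inc_ratio == 0.0

    def test_sweep_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            sample = random_intervals(rng, 100)
            reference = random_intervals(rng, 100)
            rep = chromatin.inc_ratio(sample, reference)
            assert rep.n_overlaps == brute_force_overlaps(sample, reference)

    def test_bound_reached_when_every_sample_interval_overlaps(self):
        # overlaps are counted once per sample interval, so the upper bound
        # of the ratio is |sample| / (|sample| + |reference|)
        sample = pd.DataFrame({"chrom": "c", "start": [0, 10], "end": [5, 15]})
        reference = pd.DataFrame({"chrom": "c", "start": [0], "end": [20]})
        rep = chromatin.inc_ratio(sample, reference)
        assert rep.inc_ratio == pytest.approx(
            rep.size_sample / (rep.size_sample + rep.size_reference))
        rng = np.random.default_rng(9)
        for _ in range(5):
            r = chromatin.inc_ratio(random_intervals(rng, 50), random_intervals(rng, 30))
            assert r.inc_ratio <= r.size_sample / (r.size_sample + r.size_reference)

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame({"chrom": "c", "start": [10], "end": [10]})
        ok = pd.DataFrame({"chrom": "c", "start": [0], "end": [1]})
        with pytest.raises(RerepKitError):
            chromatin.inc_ratio(bad, ok)


class TestEigenCorrelation:
    def test_affine_tracks_correlate_perfectly(self):
        x = track_from_values(np.arange(50, dtype=float))
        y = track_from_values(3.0 * np.arange(50) + 7)
        assert chromatin.eigen_correlation(x, y).pearson_r == pytest.approx(1.0)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(3)
        x = track_from_values(rng.standard_normal(1000))
        y = track_from_values(rng.standard_normal(1000))
        # null SD of r is ~ 1/sqrt(n)
        assert abs(chromatin.eigen_correlation(x, y).pearson_r) < 0.1

    def test_group_summary_uses_box_convention(self):
        rng = np.random.default_rng(4)
        x = track_from_values(rng.random(400))
        y = track_from_values(rng.standard_normal(400))
        summary = chromatin.eigen_correlation(x, y).group_summary
        assert summary["n"].sum() == 400
        assert (summary["q25"] <= summary["median"]).all()
        assert (summary["median"] <= summary["q75"]).all()
        assert (summary["whisker_low"] <= summary["q25"]).all()
        assert (summary["whisker_high"] >= summary["q75"]).all()

    def test_constant_track_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            chromatin.eigen_correlation(track_from_values(np.ones(10)),
                                        track_from_values(np.arange(10.0)))


class TestAnchorProfile:
    def test_constant_signal_gives_flat_profile(self):
        signal = track_from_values(np.full(200, 7.0), bin_width=1000)
        prof = chromatin.anchor_profile(signal, np.array([50_000, 100_000]), 5000)
        np.testing.assert_allclose(prof.mean_profile, 7.0)
        np.testing.assert_allclose(prof.anchor_scores, 7.0)

    def test_impulse_at_anchors_peaks_at_center(self):
        v = np.zeros(200)
        anchors = np.array([50, 120, 170]) * 1000
        v[[50, 120, 170]] = 1.0
        prof = chromatin.anchor_profile(track_from_values(v, bin_width=1000),
                                        anchors, 5000)
        center = len(prof.offsets_bp) // 2
        assert prof.mean_profile[center] == pytest.approx(1.0)
        assert prof.mean_profile[0] == pytest.approx(0.0)

    def test_profile_length_matches_flank(self):
        signal = track_from_values(np.zeros(100), bin_width=1000)
        prof = chromatin.anchor_profile(signal, np.array([50_000]), 7000)
        assert len(prof.mean_profile) == 2 * 7 + 1

    def test_out_of_track_anchors_counted(self):
        signal = track_from_values(np.zeros(100), bin_width=1000)
        prof = chromatin.anchor_profile(signal, np.array([50_000, 10_000_000]), 5000)
        assert prof.n_clipped == 1

    def test_shuffled_signal_profile_flat_within_three_ses(self):
        rng = np.random.default_rng(5)
        v = rng.permutation(np.concatenate([np.zeros(900), np.ones(100)]))
        anchors = rng.choice(1000, 60, replace=False) * 1000
        prof = chromatin.anchor_profile(track_from_values(v, bin_width=1000),
                                        anchors, 10_000)
        grand = np.nanmean(prof.mean_profile)
        se = np.nanstd(v) / np.sqrt(60)
        assert np.all(np.abs(prof.mean_profile - grand) < 3 * se + 1e-12)

    def test_flank_below_one_bin_rejected(self):
        signal = track_from_values(np.zeros(10), bin_width=1000)
        with pytest.raises(InvalidConfigError):
            chromatin.anchor_profile(signal, np.array([5000]), 500)


class TestLicensingSkewProfile:
    def test_early_origins_carry_more_licensing_signal(self, genome, origins):
        signal = track_from_values(simcore.licensing_track(genome, origins, seed=6))
        t = genome.timing[genome.bin_of(origins.positions)]
        groups = np.where(t < 0.33, "Very Early",
                          np.where(t > 0.66, "Very Late", "Mid"))
        prof = chromatin.anchor_profile(signal, origins.positions, 50_000,
                                        groups=groups,
                                        group_names=["Very Early", "Mid", "Very Late"],
                                        n_random=len(origins), seed=7)
        assert prof.group_scores["Very Early"] > prof.group_scores["Very Late"]
        assert np.nanmean(prof.random_scores) < prof.group_scores["Very Late"]
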