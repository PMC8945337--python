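"""Segmentation, window energies, group profiles, joint z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filmsense.features import (
    EnergySeries,
    GroupProfile,
    group_mean_profile,
    segment_mean_energy,
    segment_signal,
    stack_common_segments,
    window_energy,
    zscore_joint,
)
from filmsense.io import SignalRecord


def make_record(minutes, fs=10.0, value=1.0):
    n = int(round(minutes * 60 * fs))
    return SignalRecord(np.full(n, value), fs, "ECG", "S01", "caffeine")


class TestSegmentSignal:
    def test_fifty_minutes_gives_ten_segments(self):
        assert len(segment_signal(make_record(50.0))) == 10

    def test_partial_trailing_segment_dropped(self):
        # 48.3-min session: 9 whole 5-min segments, 3.3 min dropped
        assert len(segment_signal(make_record(48.3))) == 9

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="min"):
            segment_signal(make_record(4.0))

    def test_segments_are_contiguous_and_non_overlapping(self):
        rec = SignalRecord(np.arange(18000, dtype=float), 10.0, "ECG", "S", "placebo")
        segs = segment_signal(rec)
        flat = np.concatenate(segs)
        np.testing.assert_array_equal(flat, rec.samples[: flat.size])


class TestWindowEnergy:
    def test_constant_signal_energy(self):
        # 5 s of ones at 100 Hz: EN = 500 per window
        series = window_energy(np.ones(3000), fs=100.0, window_s=5.0)
        np.testing.assert_array_equal(series.energies, np.full(6, 500.0))

    def test_zero_signal_zero_energy(self):
        series = window_energy(np.zeros(1000), fs=50.0, window_s=5.0)
        assert np.all(series.energies == 0.0)

    def test_sine_energy_matches_analytic_mean_square(self):
        # amplitude A over whole periods: EN ~ A^2 N / 2
        fs, amp, freq = 100.0, 2.0, 2.0  # 10 cycles per 5-s window
        t = np.arange(0, 20.0, 1 / fs)
        x = amp * np.sin(2 * np.pi * freq * t)
        series = window_energy(x, fs, window_s=5.0)
        expected = amp**2 * 500 / 2
        np.testing.assert_allclose(series.energies, expected, rtol=0.01)

    def test_window_longer_than_segment_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            window_energy(np.ones(10), fs=10.0, window_s=5.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_total_energy_conserved_across_windows(self, seed):
        # sum of window energies + dropped-remainder energy = total energy
        x = np.random.default_rng(seed).normal(size=937)
        fs, window_s = 10.0, 3.0
        series = window_energy(x, fs, window_s=window_s)
        w = int(window_s * fs)
        used = series.energies.size * w
        remainder_energy = np.sum(x[used:] ** 2)
        total = np.sum(x**2)
        assert series.energies.sum() + remainder_energy == pytest.approx(
            total, rel=1e-12
        )
        assert np.all(series.energies >= 0.0)


class TestMeansAndProfiles:
    def test_segment_mean_examples(self):
        s = EnergySeries(np.array([1.0, 2.0, 3.0]), 0, 5.0)
        assert segment_mean_energy(s) == 2.0
        assert segment_mean_energy(EnergySeries(np.array([7.5]), 0, 5.0)) == 7.5
        assert segment_mean_energy(EnergySeries(np.full(9, 4.2), 0, 5.0)) == 4.2

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            segment_mean_energy(EnergySeries(np.array([]), 0, 5.0))

    def test_single_subject_profile_is_its_segment_means(self):
        means = np.array([1.0, 4.0, 2.0])
        prof = group_mean_profile(means, "caffeine")
        np.testing.assert_array_equal(prof.points, means)

    def test_two_subject_mean(self):
        m = np.array([[1.0, 2.0, 3.0], [3.0, 4.0, 5.0]])
        prof = group_mean_profile(m, "caffeine")
        np.testing.assert_array_equal(prof.points, [2.0, 3.0, 4.0])

    def test_profile_invariant_to_subject_order(self, rng):
        m = rng.normal(size=(6, 10)) ** 2
        a = group_mean_profile(m, "caffeine").points
        b = group_mean_profile(m[::-1], "caffeine").points
        np.testing.assert_allclose(a, b, rtol=1e-15)

    def test_ragged_subjects_truncated_to_common_minimum(self):
        rows = [np.arange(10.0), np.arange(8.0)]
        stacked = stack_common_segments(rows)
        assert stacked.shape == (2, 8)


class TestZscoreJoint:
    def test_pooled_mean_zero_sd_one(self, rng):
        a = GroupProfile(rng.normal(5, 2, 10), "caffeine")
        b = GroupProfile(rng.normal(3, 1, 10), "placebo")
        za, zb = zscore_joint(a, b)
        pooled = np.concatenate([za.points, zb.points])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
        assert pooled.std() == pytest.approx(1.0, abs=1e-9)
        assert za.zscored and zb.zscored

    def test_constant_profiles_map_to_plus_minus_one(self):
        # population-sd convention: pooled mean 1, sd 1 -> profiles at -1, +1
        a = GroupProfile(np.zeros(10), "placebo")
        b = GroupProfile(np.full(10, 2.0), "caffeine")
        za, zb = zscore_joint(a, b)
        np.testing.assert_allclose(za.points, -1.0, atol=1e-12)
        np.testing.assert_allclose(zb.points, 1.0, atol=1e-12)

    def test_location_invariance(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        za1, zb1 = zscore_joint(GroupProfile(a, "caffeine"), GroupProfile(b, "placebo"))
        za2, zb2 = zscore_joint(
            GroupProfile(a + 7.3, "caffeine"), GroupProfile(b + 7.3, "placebo")
        )
        np.testing.assert_allclose(za1.points, za2.points, atol=1e-9)
        np.testing.assert_allclose(zb1.points, zb2.points, atol=1e-9)

    def test_between_group_ordering_preserved(self, rng):
        a = GroupProfile(rng.normal(size=10), "caffeine")
        b = GroupProfile(rng.normal(size=10), "placebo")
        za, zb = zscore_joint(a, b)
        for i in range(10):
            for j in range(10):
                assert (a.points[i] > b.points[j]) == (za.points[i] > zb.points[j])

    def test_identical_points_rejected(self):
        a = GroupProfile(np.ones(5), "caffeine")
        b = GroupProfile(np.ones(5), "placebo")
        with pytest.raises(ValueError, match="standard deviation"):
            zscore_joint(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            zscore_joint(
                GroupProfile(np.ones(5), "caffeine"), GroupProfile(np.zeros(4), "placebo")
            )
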