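"""Noise estimation, normalisation, start search and trimming rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsalign.preprocess import (
    PatternEntry,
    PeakPattern,
    PreprocessConfig,
    channel_stats,
    find_start_25plex,
    find_start_generic,
    find_start_target,
    local_peaks,
    normalise_channel,
    raw_transform,
    trim,
)
from fsalign.trace_io import TraceRecord


def _triangle(length, apex, height, half_width=5):
    """Symmetric triangular peak, zeros elsewhere."""
    x = np.arange(length, dtype=float)
    y = height * np.clip(1 - np.abs(x - apex) / half_width, 0, None)
    return y


def _record(ch1, *others):
    channels = [np.asarray(ch1, dtype=float)]
    for o in others:
        channels.append(np.asarray(o, dtype=float))
    while len(channels) < 4:
        channels.append(np.zeros_like(channels[0]))
    return TraceRecord(channels=channels, model="3100")


class TestChannelStats:
    def test_sparse_peak_channel(self):
        st_ = channel_stats([0, 0, 0, 0, 100, 200, 100, 0, 0, 0], 200)
        assert st_.avg_all == pytest.approx(40.0)
        assert st_.noise == pytest.approx(0.0)
        assert st_.avg_signal == pytest.approx(40.0)
        assert st_.scale_factor == pytest.approx(0.2)

    def test_channel_with_baseline(self):
        st_ = channel_stats([20, 0, 20, 0, 100, 200, 100, 0, 20, 0], 100)
        assert st_.avg_all == pytest.approx(46.0)
        assert st_.noise == pytest.approx(60 / 7)
        assert st_.avg_signal == pytest.approx(46 - 60 / 7)
        assert st_.scale_factor == pytest.approx((46 - 60 / 7) / 100)

    def test_flat_channel_has_empty_below_mean_subset(self):
        st_ = channel_stats([7, 7, 7, 7], 100)
        assert st_.avg_all == 7.0
        assert st_.noise == 0.0
        assert st_.avg_signal == 7.0

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError, match="empty channel"):
            channel_stats([], 100)


class TestNormaliseChannel:
    def test_scaling_by_stats(self):
        ch = [0, 0, 0, 0, 100, 200, 100, 0, 0, 0]
        out = normalise_channel(ch, channel_stats(ch, 200))
        assert np.allclose(out, [0, 0, 0, 0, 500, 1000, 500, 0, 0, 0])

    def test_identity_when_noise_zero_and_unit_scale(self):
        from fsalign.preprocess import ChannelStats

        ch = np.array([5.0, 1.0, 9.0])
        out = normalise_channel(ch, ChannelStats(5.0, 0.0, 5.0, 1.0))
        assert np.array_equal(out, ch)

    def test_sub_noise_points_zeroed_then_scaled(self):
        ch = [20, 0, 20, 0, 100, 200, 100, 0, 20, 0]
        stats = channel_stats(ch, 100)
        out = normalise_channel(ch, stats)
        assert out[1] == 0 and out[3] == 0  # zeros below noise stay zero
        assert out[0] == pytest.approx(20 / stats.scale_factor)
        assert out[0] == pytest.approx(53.435, abs=0.01)
        assert out[4] == pytest.approx(267.18, abs=0.01)
        assert out[5] == pytest.approx(534.35, abs=0.01)

    def test_all_zero_channel_flagged_flat(self):
        ch = np.zeros(8)
        stats = channel_stats(ch, 100)
        with pytest.warns(UserWarning, match="flat channel"):
            out = normalise_channel(ch, stats)
        assert np.array_equal(out, np.zeros(8))

    @settings(max_examples=50, deadline=None)
    @given(
        channel=st.lists(st.integers(0, 5000), min_size=2, max_size=200),
        optimal=st.sampled_from([50, 100, 200, 400, 800]),
    )
    def test_normalisation_identities(self, channel, optimal):
        """avg_signal / scale_factor recovers the optimal value exactly, and
        no normalised point lies strictly between 0 and noise / scale."""
        stats = channel_stats(channel, optimal)
        if stats.scale_factor == 0:
            return
        assert stats.avg_signal / stats.scale_factor == pytest.approx(optimal, rel=1e-9)
        out = normalise_channel(channel, stats)
        floor = stats.noise / stats.scale_factor
        assert not np.any((out > 0) & (out < floor))


class TestRawTransform:
    def test_identity_matrix_leaves_channels(self):
        rec = _record(_triangle(50, 20, 100))
        rec.model = "310"
        rec.matrix = np.eye(4)
        out = raw_transform(rec)
        for a, b in zip(rec.channels, out.channels):
            assert np.allclose(a, b)

    def test_matrix_multiplication_per_scan(self):
        mat = np.zeros((4, 4))
        mat[0, 0] = 2.0
        rec = TraceRecord(
            channels=[np.array([10.0]), np.array([20.0]), np.array([30.0]), np.array([40.0])],
            model="310",
            matrix=mat,
        )
        out = raw_transform(rec)
        assert [int(c[0]) for c in out.channels] == [20, 0, 0, 0]

    def test_negative_products_clamped(self):
        mat = np.eye(4)
        mat[1, 1] = -1.0
        rec = TraceRecord(
            channels=[np.array([1.0]), np.array([5.0]), np.array([0.0]), np.array([0.0])],
            model="310",
            matrix=mat,
        )
        assert raw_transform(rec).channels[1][0] == 0

    def test_unknown_model_passes_through_with_warning(self):
        rec = _record(_triangle(30, 10, 80))
        rec.model = "unknown"
        with pytest.warns(UserWarning, match="unknown instrument model"):
            out = raw_transform(rec)
        for a, b in zip(rec.channels, out.channels):
            assert np.array_equal(a, b)

    def test_bad_matrix_rejected(self):
        rec = _record(_triangle(30, 10, 80))
        rec.model = "310"
        rec.matrix = np.eye(3)
        with pytest.raises(ValueError, match="bad matrix"):
            raw_transform(rec)


class TestStartSearch:
    def test_first_peak_of_channel_one(self):
        rec = _record(_triangle(300, 120, 300))
        assert find_start_generic(rec) == 120

    def test_sub_threshold_peak_skipped(self):
        ch1 = _triangle(200, 40, 30) + _triangle(200, 90, 400)
        assert find_start_generic(_record(ch1)) == 90

    def test_all_zero_channel_fails(self):
        with pytest.raises(ValueError, match="no start peak found"):
            find_start_generic(_record(np.zeros(100)))

    def test_pattern_skips_isolated_early_spike(self):
        pattern = PeakPattern([PatternEntry(1, 100, 50), PatternEntry(2, 100, None)])
        ch1 = _triangle(400, 60, 300) + _triangle(400, 150, 300)
        ch2 = _triangle(400, 170, 250)
        assert find_start_25plex(_record(ch1, ch2), pattern) == 150

    def test_pattern_immediate_match(self):
        pattern = PeakPattern([PatternEntry(1, 100, 50), PatternEntry(2, 100, None)])
        rec = _record(_triangle(200, 30, 300), _triangle(200, 45, 250))
        assert find_start_25plex(rec, pattern) == 30

    def test_pattern_not_found_without_second_channel_peak(self):
        pattern = PeakPattern([PatternEntry(1, 100, 50), PatternEntry(2, 100, None)])
        with pytest.raises(ValueError, match="pattern not found"):
            find_start_25plex(_record(_triangle(200, 30, 300)), pattern)

    def test_target_identical_to_reference(self, default_config):
        rec = _record(_triangle(600, 250, 300))
        ref_start = find_start_generic(rec, default_config)
        assert find_start_target(ref_start, rec, default_config) == ref_start

    def test_peak_beyond_window_not_found(self, default_config):
        ref_start = 100
        offset = default_config.start_search_window + 50
        rec = _record(_triangle(600, ref_start + offset, 300))
        with pytest.raises(ValueError, match="no start peak in window"):
            find_start_target(ref_start, rec, default_config)

    def test_spurious_early_spike_ignored_with_pattern(self, default_config):
        """A noise spike far ahead of the real data must not hijack the
        start point when the real pattern lies within the guided window."""
        pattern = PeakPattern([PatternEntry(1, 100, 50), PatternEntry(2, 100, None)])
        ch1 = _triangle(700, 10, 500) + _triangle(700, 310, 300)
        ch2 = _triangle(700, 340, 250)
        rec = _record(ch1, ch2)
        assert find_start_target(300, rec, default_config, pattern) == 310

    @settings(max_examples=30, deadline=None)
    @given(ref_start=st.integers(0, 300), apex=st.integers(5, 900))
    def test_found_start_never_exceeds_window(self, ref_start, apex):
        rec = _record(_triangle(1000, apex, 300))
        cfg = PreprocessConfig()
        try:
            found = find_start_target(ref_start, rec, cfg)
        except ValueError:
            return
        assert found <= ref_start + cfg.start_search_window


class TestTrim:
    def test_blank_suffix_removed(self):
        ch2 = np.zeros(120)
        ch2[79] = 60
        ch1 = np.full(120, 20.0)
        ch1[:79] = 49
        rec = _record(ch1, ch2)
        out = trim(rec, 0)
        assert out.n_scans == 80
        assert out.trim_span == (0, 80)

    def test_value_exactly_at_threshold_retained(self):
        ch1 = np.zeros(50)
        ch1[10] = 200
        ch1[-1] = 50  # strict "less than": exactly 50 stops trimming
        out = trim(_record(ch1), 0)
        assert out.n_scans == 50

    def test_no_blank_suffix_is_identity(self):
        ch1 = np.full(40, 60.0)
        out = trim(_record(ch1), 0)
        assert out.n_scans == 40
        assert np.array_equal(out.channels[0], ch1)

    def test_entirely_blank_trace_rejected(self):
        with pytest.raises(ValueError, match="entirely blank"):
            trim(_record(np.full(30, 5.0)), 0)

    @settings(max_examples=40, deadline=None)
    @given(
        data=st.lists(st.integers(0, 500), min_size=5, max_size=80),
        start=st.integers(0, 4),
    )
    def test_trim_is_a_pure_slice(self, data, start):
        """Concatenating removed prefix, output and removed suffix
        reconstructs the input; retained values are never altered."""
        ch1 = np.asarray(data, dtype=float)
        rec = _record(ch1)
        try:
            out = trim(rec, start)
        except ValueError:
            return
        s, e = out.trim_span
        assert s == start
        recon = np.concatenate([ch1[:s], out.channels[0], ch1[e:]])
        assert np.array_equal(recon, ch1)


class TestLocalPeaks:
    def test_plateau_counts_once_at_first_scan(self):
        v = [0, 5, 9, 9, 9, 5, 0]
        assert local_peaks(v, 1).tolist() == [2]

    def test_threshold_filters(self):
        v = _triangle(100, 30, 40) + _triangle(100, 70, 400)
        assert local_peaks(v, 50).tolist() == [70]


def test_default_pattern_loads():
    pattern = PeakPattern.default_25plex()
    assert pattern.entries[0].channel == 1
    assert len(pattern.entries) >= 2
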