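"""Resampling, filtering, normalization, windowing and training-window QC."""

import dataclasses

import numpy as np
import pytest

from bcgbeat import (EventSeries, SignalRecording, bandpass, iqr_normalize,
                     qc_filter_training, resample_cubic, segment_windows)
from bcgbeat.types import SignalWindow

from conftest import make_quiet_recording


def sine_recording(freq, fs=1000.0, duration=10.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalRecording(amp * np.sin(2 * np.pi * freq * t)[:, None], fs=fs)


class TestResampleCubic:
    def test_sinusoid_against_closed_form(self):
        rec = sine_recording(5.0, fs=1000.0, duration=10.0)
        out = resample_cubic(rec, 64.0)
        expected = np.sin(2 * np.pi * 5.0 * out.times)
        assert np.max(np.abs(out.samples[:, 0] - expected)) < 1e-3

    def test_identity_rate(self):
        rec = sine_recording(5.0, fs=64.0, duration=4.0)
        out = resample_cubic(rec, 64.0)
        assert np.array_equal(out.samples, rec.samples)

    def test_sample_count(self):
        rec = sine_recording(2.0, fs=1000.0, duration=10.0)
        out = resample_cubic(rec, 64.0)
        assert abs(out.n_samples - 640) <= 1

    def test_rejects_upsampling(self):
        with pytest.raises(ValueError):
            resample_cubic(sine_recording(2.0, fs=64.0), 128.0)


class TestBandpass:
    def test_respiration_attenuated(self):
        rec = sine_recording(0.3, fs=64.0, duration=60.0)
        out = bandpass(rec, 4.0, 25.0)
        mid = slice(640, -640)  # avoid filter edge transients
        ratio = np.sqrt(np.mean(out.samples[mid] ** 2) / np.mean(rec.samples[mid] ** 2))
        assert 20 * np.log10(ratio) <= -20

    def test_passband_flat(self):
        rec = sine_recording(10.0, fs=64.0, duration=60.0)
        out = bandpass(rec, 4.0, 25.0)
        mid = slice(640, -640)
        ratio = np.sqrt(np.mean(out.samples[mid] ** 2) / np.mean(rec.samples[mid] ** 2))
        assert abs(20 * np.log10(ratio)) <= 1.0

    def test_dc_rejected(self):
        rec = SignalRecording(np.full((1280, 2), 3.7), fs=64.0)
        out = bandpass(rec, 4.0, 25.0)
        assert np.max(np.abs(out.samples)) < 1e-6

    def test_rejects_cut_above_nyquist(self):
        with pytest.raises(ValueError):
            bandpass(sine_recording(1, fs=64.0), 4.0, 32.0)

    def test_zero_phase_keeps_peak_times(self):
        """The IJK peak must not be displaced by filtering (events are targets)."""
        rec, _, j, _ = make_quiet_recording(duration=30.0)
        out = bandpass(rec, 4.0, 25.0)
        for p in j.times[2:-2]:
            i0, i1 = int((p - 0.15) * 64), int((p + 0.15) * 64) + 1
            before = i0 + np.argmax(rec.samples[i0:i1, 2])
            after = i0 + np.argmax(out.samples[i0:i1, 2])
            assert abs(after - before) <= 1


class TestIqrNormalize:
    def test_hand_computed_example(self):
        win = SignalWindow(np.array([1, 2, 3, 4, 5.0])[:, None], fs=1.0)
        out = iqr_normalize(win)
        assert np.allclose(out.samples[:, 0], [-1, -0.5, 0, 0.5, 1])

    def test_median_zero_iqr_one(self):
        rng = np.random.default_rng(0)
        win = SignalWindow(rng.normal(2.0, 3.0, size=(4096, 3)), fs=64.0)
        out = iqr_normalize(win)
        assert np.allclose(np.median(out.samples, axis=0), 0, atol=1e-12)
        q75, q25 = np.percentile(out.samples, [75, 25], axis=0)
        assert np.allclose(q75 - q25, 1, atol=1e-12)

    def test_robust_to_single_outlier(self):
        """One extreme sample barely moves IQR scaling, unlike z-scoring."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=4096)
        x_out = x.copy()
        x_out[100] = 1000.0
        a = iqr_normalize(SignalWindow(x[:, None], fs=64.0)).samples[:, 0]
        b = iqr_normalize(SignalWindow(x_out[:, None], fs=64.0)).samples[:, 0]
        keep = np.ones(4096, bool)
        keep[100] = False
        rel = np.abs(b[keep] - a[keep]) / (np.abs(a[keep]) + 1e-3)
        assert np.median(rel) < 0.2
        z_plain = (x - x.mean()) / x.std()
        z_out = (x_out - x_out.mean()) / x_out.std()
        assert np.std(z_out[keep]) < 0.5 * np.std(z_plain[keep])  # z-score collapses

    def test_flat_channel_flagged(self):
        win = SignalWindow(np.zeros((64, 2)), fs=64.0)
        with pytest.warns(UserWarning):
            out = iqr_normalize(win)
        assert "zero_iqr" in out.flags
        assert np.all(np.isfinite(out.samples))


class TestSegmentWindows:
    def test_nonoverlapping_count(self):
        rec = SignalRecording(np.zeros((640 * 64, 1)), fs=64.0)
        wins, _ = segment_windows(rec, None, 64.0, 64.0)
        assert len(wins) == 10

    def test_stride_count_matches_enumeration(self):
        rec = SignalRecording(np.zeros((640 * 64, 1)), fs=64.0)
        wins, _ = segment_windows(rec, None, 64.0, 32.0)
        # brute-force enumeration of valid starts
        starts = [s for s in np.arange(0, 640, 32.0) if s + 64 <= 640]
        assert len(wins) == len(starts) == 19

    def test_events_made_relative(self):
        rec = SignalRecording(np.zeros((128 * 64, 1)), fs=64.0)
        ev = EventSeries([70.0])
        wins, wevs = segment_windows(rec, ev, 64.0, 64.0)
        assert len(wevs[1]) == 1
        assert wevs[1].times[0] == pytest.approx(6.0)
        assert wins[1].abs_start == pytest.approx(64.0)

    def test_lossless_tiling(self):
        rng = np.random.default_rng(2)
        rec = SignalRecording(rng.normal(size=(200 * 64, 2)), fs=64.0)
        wins, _ = segment_windows(rec, None, 64.0, 64.0)
        cat = np.concatenate([w.samples for w in wins])
        assert np.array_equal(cat, rec.samples[:len(cat)])

    def test_short_recording_empty(self):
        rec = SignalRecording(np.zeros((100, 1)), fs=64.0)
        wins, _ = segment_windows(rec, None, 64.0, 64.0)
        assert wins == []


class TestQcFilter:
    @staticmethod
    def _window_with_events(offset=0.0):
        """64-s window whose detector events equal references shifted by offset."""
        ev = EventSeries(np.arange(1.0, 63.0, 1.0))
        win = SignalWindow(np.zeros((4096, 3)), fs=64.0)
        det = EventSeries(ev.times + offset)
        return win, ev, det

    def test_aligned_window_kept(self):
        win, ev, det = self._window_with_events(0.0)
        kept, kept_ev, discarded = qc_filter_training([win], [ev], lambda w: det)
        assert len(kept) == 1 and not discarded
        assert abs(kept[0].qc_delay_s) < 0.02

    def test_shifted_window_discarded(self):
        win, ev, det = self._window_with_events(0.5)
        kept, _, discarded = qc_filter_training([win], [ev], lambda w: det)
        assert not kept and len(discarded) == 1
        assert "delay" in discarded[0][1]

    def test_threshold_boundary(self):
        win, ev, det = self._window_with_events(0.12)
        kept, _, discarded = qc_filter_training([win], [ev], lambda w: det)
        assert not kept

    def test_insufficient_events(self):
        win = SignalWindow(np.zeros((4096, 3)), fs=64.0)
        ev = EventSeries([5.0])
        kept, _, discarded = qc_filter_training([win], [ev], lambda w: ev)
        assert discarded[0][1] == "insufficient events"

    def test_artifact_window_discarded(self):
        """Spurious detections in a movement burst break the lock and fail QC."""
        win, ev, _ = self._window_with_events(0.0)
        rng = np.random.default_rng(0)
        spurious = EventSeries(np.sort(rng.uniform(0, 64, size=60)))
        kept, _, discarded = qc_filter_training([win], [ev], lambda w: spurious)
        assert not kept
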