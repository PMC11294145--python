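"""Signal conditioning and windowing ahead of model training.

Pipeline order on a raw recording: cubic-spline resampling to the 64 Hz
working rate (when acquired faster), 4-25 Hz zero-phase bandpass, 64-s
windowing, per-window interquartile-range normalization, and
synchronization-based quality control of training windows.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .types import EventSeries, SignalRecording, SignalWindow

__all__ = [
    "resample_cubic",
    "bandpass",
    "iqr_normalize",
    "segment_windows",
    "qc_filter_training",
]

WORKING_FS = 64.0
WINDOW_S = 64.0
BANDPASS_LO = 4.0
BANDPASS_HI = 25.0
QC_THRESHOLD_S = 0.1
QC_SEARCH_S = 2.0


def resample_cubic(rec: SignalRecording, target_fs: float) -> SignalRecording:
    """Cubic-spline interpolation of each channel onto a ``target_fs`` grid.

    Downsampling (or the identity rate) only; the target grid starts at the
    recording's ``t0`` and spans the same interval.
    """
    if target_fs > rec.fs:
        raise ValueError("resample_cubic only downsamples; target_fs exceeds rec.fs")
    if target_fs == rec.fs:
        return rec.copy_with(samples=rec.samples.copy())
    t_old = rec.times
    n_new = int(np.floor((rec.n_samples - 1) / rec.fs * target_fs)) + 1
    t_new = rec.t0 + np.arange(n_new) / target_fs
    out = np.empty((n_new, rec.n_channels))
    for c in range(rec.n_channels):
        out[:, c] = CubicSpline(t_old, rec.samples[:, c])(t_new)
    return SignalRecording(out, fs=target_fs, t0=rec.t0, channel_names=rec.channel_names)


def _butter_sos(fs: float, lo: float, hi: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz must be below Nyquist {nyq} Hz")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(rec, lo: float = BANDPASS_LO, hi: float = BANDPASS_HI, order: int = 4):
    """Zero-phase Butterworth bandpass per channel (forward-backward).

    Zero phase matters here: event times are the learning target, so the
    filter must not displace the IJK complex.
    """
    sos = _butter_sos(rec.fs, lo, hi, order)
    out = sps.sosfiltfilt(sos, rec.samples, axis=0)
    return rec.copy_with(samples=out)


def iqr_normalize(window):
    """Center on the median and scale by the interquartile range, per channel.

    More robust to movement artifacts than z-scoring: a handful of extreme
    samples barely moves the quartiles.  A flat channel (zero IQR) is scaled
    by 1 instead and the window is flagged.
    """
    x = window.samples
    med = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = q75 - q25
    flags = tuple(window.flags) if isinstance(window, SignalWindow) else ()
    if np.any(iqr == 0):
        warnings.warn("zero IQR in at least one channel; falling back to scale 1")
        flags = flags + ("zero_iqr",)
        iqr = np.where(iqr == 0, 1.0, iqr)
    out = (x - med) / iqr
    if isinstance(window, SignalWindow):
        return window.copy_with(samples=out, flags=flags)
    return window.copy_with(samples=out)


def segment_windows(
    rec: SignalRecording,
    r_peaks: EventSeries | None = None,
    window_s: float = WINDOW_S,
    stride_s: float | None = None,
    subject_id: str = "",
    night_id: str = "",
) -> tuple[list[SignalWindow], list[EventSeries]]:
    """Tile the recording into fixed-length windows with the given stride.

    Default stride equals the window length (non-overlapping tiling).  Each
    window carries the reference events that fall inside it, re-expressed
    relative to the window start; ``abs_start`` preserves the recording-clock
    position.  A recording shorter than one window yields an empty list.
    """
    if stride_s is None:
        stride_s = window_s
    n_win = int(round(window_s * rec.fs))
    if abs(window_s * rec.fs - n_win) > 1e-9:
        raise ValueError("window_s * fs must be integral")
    n_stride = int(round(stride_s * rec.fs))
    if n_stride < 1:
        raise ValueError("stride too small")
    windows, events = [], []
    for i0 in range(0, rec.n_samples - n_win + 1, n_stride):
        t_start = rec.t0 + i0 / rec.fs
        win = SignalWindow(
            samples=rec.samples[i0:i0 + n_win].copy(),
            fs=rec.fs, t0=0.0, channel_names=rec.channel_names,
            subject_id=subject_id, night_id=night_id, abs_start=t_start,
        )
        windows.append(win)
        if r_peaks is not None:
            events.append(r_peaks.crop(t_start, t_start + window_s, relative=True))
        else:
            events.append(EventSeries(np.empty(0)))
    return windows, events


def qc_filter_training(
    windows: list[SignalWindow],
    window_events: list[EventSeries],
    preliminary_j_detector,
    threshold_s: float = QC_THRESHOLD_S,
    search_s: float = QC_SEARCH_S,
    grid_step_s: float | None = None,
):
    """Discard training windows whose reference/detector delay is >= 0.1 s.

    For each window the preliminary J-peaks from the classical detector are
    compared with the (already globally aligned) reference events via
    event-based time-delay estimation over +/- ``search_s``.  A residual
    delay at or above ``threshold_s`` marks the window as unusable for
    training: either the signal is too corrupted for the detector or the
    alignment is locally wrong.  Validation sets must never pass through this
    filter (all windows are evaluated).

    Returns ``(kept, kept_events, discarded)`` where ``discarded`` is a list
    of ``(window, reason)`` pairs.
    """
    from .sync import estimate_time_delay  # local import avoids a cycle

    kept, kept_events, discarded = [], [], []
    for win, ev in zip(windows, window_events):
        if len(ev) < 2:
            discarded.append((win, "insufficient events"))
            continue
        detected = preliminary_j_detector(win)
        if len(detected) < 2:
            discarded.append((win, "insufficient detections"))
            continue
        step = grid_step_s if grid_step_s is not None else 1.0 / win.fs
        try:
            est = estimate_time_delay(ev, detected, search_range_s=search_s,
                                      grid_step_s=step)
        except ValueError:
            discarded.append((win, "delay estimation failed"))
            continue
        win = win.copy_with(qc_delay_s=est.delay_s)
        if abs(est.delay_s) >= threshold_s:
            discarded.append((win, f"delay {est.delay_s:.3f} s"))
        else:
            kept.append(win)
            kept_events.append(ev)
    return kept, kept_events, discarded
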