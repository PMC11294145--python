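"""Core containers for ballistocardiogram (BCG) signals and heartbeat events.

A BCG recording is a multichannel acceleration time series ``X`` of shape
``(n, k)`` sampled equidistantly at ``fs`` Hz.  Heartbeat events (reference
R-peaks from an ECG, or detected J-peaks from the BCG itself) are ordered
timestamps in seconds on the recording clock.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalRecording",
    "SignalWindow",
    "EventSeries",
]


def _as_2d(samples) -> np.ndarray:
    a = np.asarray(samples, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"samples must be 1-D or 2-D, got shape {a.shape}")
    return a


@dataclass
class SignalRecording:
    """Equidistantly sampled multichannel signal.

    Parameters
    ----------
    samples : (n, k) array
        One column per channel.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds; sample ``i`` sits at
        ``t0 + i / fs``.
    channel_names : tuple of str
        One name per channel, e.g. ``("ax", "ay", "az")``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: tuple = ()

    def __post_init__(self):
        self.samples = _as_2d(self.samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (n / fs)."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.n_samples / self.fs

    def copy_with(self, **kw) -> "SignalRecording":
        return dataclasses.replace(self, **kw)


@dataclass
class SignalWindow(SignalRecording):
    """A fixed-length slice of a recording, the unit the models consume.

    ``t0`` is the window's start on its own clock (0 after slicing); the
    absolute position in the parent recording is kept in ``abs_start`` so
    detections can be mapped back to the recording clock.
    """

    subject_id: str = ""
    night_id: str = ""
    abs_start: float = 0.0
    qc_delay_s: float | None = None
    flags: tuple = ()

    def copy_with(self, **kw) -> "SignalWindow":
        return dataclasses.replace(self, **kw)


@dataclass
class EventSeries:
    """Strictly increasing event timestamps in seconds.

    ``label`` distinguishes reference R-peaks (``"R"``), ground-truth J-peaks
    (``"J"``) and detector output (``"detected"``).
    """

    times: np.ndarray
    label: str = "R"

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def shift(self, dt: float) -> "EventSeries":
        return EventSeries(self.times + dt, label=self.label)

    def crop(self, t_start: float, t_end: float, relative: bool = False) -> "EventSeries":
        """Events in ``[t_start, t_end)``, optionally re-expressed from ``t_start``."""
        m = (self.times >= t_start) & (self.times < t_end)
        t = self.times[m]
        if relative:
            t = t - t_start
        return EventSeries(t, label=self.label)

    def ibis(self) -> np.ndarray:
        """Interbeat intervals (successive differences) in seconds."""
        return np.diff(self.times)
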