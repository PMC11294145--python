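"""Classical signal-processing J-peak detector (Pan-Tompkins-style baseline).

The chain — bandpass, pointwise cube, low-pass, second-order derivative,
absolute value, low-pass — turns the raw BCG into an envelope whose maxima
coincide with J-peaks, followed by maximum-seeking peak detection with a
physiological minimum spacing and an adaptive height threshold.  Besides
serving as the comparison method, this detector supplies the preliminary
J-peaks needed to align reference R-peaks with the BCG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import EventSeries

__all__ = ["DspParams", "detect_jpeaks_dsp"]


@dataclass(frozen=True)
class DspParams:
    """Tunable constants of the baseline chain.

    The bandpass edges follow the recommended 1.5-22.5 Hz BCG system
    bandwidth.  The two low-pass cutoffs and the adaptive threshold rule are
    package defaults, fixed once on synthetic data: the envelope low-pass at
    10 Hz keeps the cubed J-lobe sharp, the final 5 Hz smooths the rectified
    curvature into one bump per beat.
    """

    bandpass_lo: float = 1.5     # Hz
    bandpass_hi: float = 22.5    # Hz
    lowpass1: float = 10.0       # Hz, after cubing
    lowpass2: float = 5.0        # Hz, after rectification
    min_spacing_s: float = 0.31  # refractory spacing between detections
    height_factor: float = 0.3   # fraction of the block-wise 95th percentile
    percentile_block_s: float = 8.0
    channel: str = "dominant"    # "dominant" variance channel or "norm"


def _lowpass(x: np.ndarray, fs: float, cut: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, cut, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _blockwise_percentile(x: np.ndarray, fs: float, block_s: float, q: float) -> np.ndarray:
    """Per-block percentile expanded back to sample resolution."""
    n_block = max(1, int(round(block_s * fs)))
    n = x.size
    out = np.empty(n)
    for i0 in range(0, n, n_block):
        seg = x[i0:i0 + n_block]
        out[i0:i0 + n_block] = np.percentile(seg, q)
    return out


def detect_jpeaks_dsp(win, params: DspParams = DspParams()) -> EventSeries:
    """Run the full baseline chain on a window or recording.

    Works on the RAW (unfiltered) signal: the chain applies its own 1.5-22.5
    Hz bandpass.  Channel selection defaults to the highest-variance axis;
    ``channel="norm"`` combines the three axes by Euclidean norm.  Returns
    peak times in seconds on the input's clock (``t0 + index / fs``).
    """
    fs = win.fs
    x2d = win.samples
    if params.channel == "norm":
        x = np.linalg.norm(x2d, axis=1)
    else:
        x = x2d[:, int(np.argmax(np.var(x2d, axis=0)))]
    if not np.any(x):
        return EventSeries(np.empty(0), label="detected")

    sos = sps.butter(4, [params.bandpass_lo, params.bandpass_hi],
                     btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    y = y ** 3                       # odd power: sharpens peaks, keeps polarity
    y = _lowpass(y, fs, params.lowpass1)
    y = np.gradient(np.gradient(y))  # second-order derivative
    y = np.abs(y)
    y = _lowpass(y, fs, params.lowpass2)

    height = params.height_factor * _blockwise_percentile(
        y, fs, params.percentile_block_s, 95.0)
    distance = max(1, int(round(params.min_spacing_s * fs)))
    peaks, _ = sps.find_peaks(y, distance=distance)
    peaks = peaks[y[peaks] >= height[peaks]]
    t0 = getattr(win, "t0", 0.0)
    return EventSeries(t0 + peaks / fs, label="detected")
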