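"""Event-based time-delay estimation and non-linear alignment.

Reference R-peaks (electrical) and BCG J-peaks (mechanical) are offset by the
slowly drifting RJ-interval, and acquisition clocks may drift.  Both effects
are handled on the EVENT level: the synchronicity of two event series is
scored by the mean distance from each event to its nearest counterpart
("nearest advocate"), the delay is the shift minimizing that score, and
non-linear drift is corrected by estimating the delay per time segment and
interpolating piecewise-linearly between segment centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import EventSeries

__all__ = [
    "DelayEstimate",
    "nearest_event_distance",
    "estimate_time_delay",
    "nonlinear_align",
]

#: distances beyond this cap are clipped when SCORING a candidate shift, so a
#: few missed/spurious beats cannot dominate the search; reported metrics are
#: never capped.
SCORE_CAP_S = 0.25


@dataclass(frozen=True)
class DelayEstimate:
    """Result of a grid search over candidate shifts of the moving series."""

    delay_s: float
    score_ms: float          # mean capped nearest-event distance at the optimum
    search_range_s: float
    grid_step_s: float


def _nearest_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each event in ``a`` to its nearest event in ``b``."""
    idx = np.searchsorted(b, a)
    left = np.where(idx > 0, a - b[np.maximum(idx - 1, 0)], np.inf)
    right = np.where(idx < b.size, b[np.minimum(idx, b.size - 1)] - a, np.inf)
    return np.minimum(np.abs(left), np.abs(right))


def nearest_event_distance(a: EventSeries, b: EventSeries, symmetric: bool = True,
                           cap_s: float | None = None) -> float:
    """Mean nearest-event distance in milliseconds.

    One-directional: mean over events of ``a`` of the distance to the nearest
    event of ``b``.  Symmetric: average of the two directions, which
    penalizes missed beats and false detections alike.
    """
    if len(a) == 0 or len(b) == 0:
        side = "first" if len(a) == 0 else "second"
        raise ValueError(f"nearest_event_distance undefined: {side} series is empty")
    d_ab = _nearest_dists(a.times, b.times)
    if cap_s is not None:
        d_ab = np.minimum(d_ab, cap_s)
    if not symmetric:
        return float(np.mean(d_ab)) * 1e3
    d_ba = _nearest_dists(b.times, a.times)
    if cap_s is not None:
        d_ba = np.minimum(d_ba, cap_s)
    return float((np.mean(d_ab) + np.mean(d_ba)) / 2.0) * 1e3


def estimate_time_delay(
    a: EventSeries,
    b: EventSeries,
    search_range_s: float = 2.0,
    grid_step_s: float = 1.0 / 64.0,
    cap_s: float | None = SCORE_CAP_S,
    refine: bool = True,
) -> DelayEstimate:
    """Shift ``a`` over a grid and keep the shift best aligning it to ``b``.

    The score of a candidate shift ``d`` is the symmetric capped
    nearest-event distance of ``(a + d, b)``; an exhaustive grid over
    ``[-search_range_s, +search_range_s]`` is evaluated and the minimizer
    optionally refined by a parabolic fit through its grid neighbours.
    Deterministic; ties resolve to the smallest shift.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot estimate a delay from an empty event series")
    lo_overlap = max(a.times[0] - search_range_s, b.times[0])
    hi_overlap = min(a.times[-1] + search_range_s, b.times[-1])
    if lo_overlap > hi_overlap:
        raise ValueError("event series do not overlap within the search range")
    shifts = np.arange(-search_range_s, search_range_s + grid_step_s / 2, grid_step_s)
    scores = np.empty(shifts.size)
    for i, d in enumerate(shifts):
        scores[i] = nearest_event_distance(a.shift(d), b, symmetric=True, cap_s=cap_s)
    i_min = int(np.argmin(scores))
    delay = float(shifts[i_min])
    if refine and 0 < i_min < shifts.size - 1:
        y0, y1, y2 = scores[i_min - 1], scores[i_min], scores[i_min + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            offset = 0.5 * (y0 - y2) / denom
            delay += float(np.clip(offset, -1.0, 1.0)) * grid_step_s
    return DelayEstimate(delay, float(scores[i_min]), search_range_s, grid_step_s)


def nonlinear_align(
    moving: EventSeries,
    reference: EventSeries,
    segment_s: float = 300.0,
    search_range_s: float = 2.0,
    grid_step_s: float = 1.0 / 64.0,
    min_events: int = 5,
):
    """Correct a slowly varying delay between two event series.

    The timeline is split into segments of ``segment_s``; a delay is
    estimated per segment (segments with fewer than ``min_events`` moving
    events inherit interpolated values from their neighbours), delays are
    interpolated piecewise-linearly between segment centers, and the
    time-varying correction is added to ``moving``.  Monotonicity of the
    corrected series is enforced.

    Returns ``(aligned, (segment_centers, segment_delays))``.
    """
    t_lo = min(moving.times[0], reference.times[0])
    t_hi = max(moving.times[-1], reference.times[-1])
    n_seg = max(1, int(np.ceil((t_hi - t_lo) / segment_s)))
    if n_seg < 2 and (t_hi - t_lo) > segment_s:
        n_seg = 2
    centers = t_lo + (np.arange(n_seg) + 0.5) * (t_hi - t_lo) / n_seg
    delays = np.full(n_seg, np.nan)
    for s in range(n_seg):
        seg_lo = t_lo + s * (t_hi - t_lo) / n_seg
        seg_hi = t_lo + (s + 1) * (t_hi - t_lo) / n_seg
        m_seg = moving.crop(seg_lo, seg_hi)
        r_seg = reference.crop(seg_lo - search_range_s, seg_hi + search_range_s)
        if len(m_seg) < min_events or len(r_seg) < min_events:
            continue
        try:
            delays[s] = estimate_time_delay(m_seg, r_seg, search_range_s,
                                            grid_step_s).delay_s
        except ValueError:
            continue
    if np.all(np.isnan(delays)):
        raise ValueError("no segment had enough events to estimate a delay")
    valid = ~np.isnan(delays)
    delays = np.interp(centers, centers[valid], delays[valid])
    corr = np.interp(moving.times, centers, delays)
    aligned_t = moving.times + corr
    # a pathological delay profile could reorder events; nudge minimally
    aligned_t = np.maximum.accumulate(aligned_t)
    dup = np.diff(aligned_t) <= 0
    if np.any(dup):
        eps = 1e-9
        for i in np.flatnonzero(dup):
            aligned_t[i + 1] = aligned_t[i] + eps
    return EventSeries(aligned_t, label=moving.label), (centers, delays)
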