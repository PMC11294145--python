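import numpy as np
import pytest

from bcgbeat import (EventSeries, KernelSpec, SubjectParams, derive_jpeaks,
                     simulate_heartbeats, synthesize_bcg)
from bcgbeat.encoding import kernel_value


@pytest.fixture
def quiet_params():
    """A sleeper with no stochastic nuisance terms (pure beat train)."""
    return SubjectParams(mean_ibi=1.0, ibi_sd=0.0, rsa_depth=0.0,
                         resp_amp=0.0, noise_sd=0.0, movement_rate=0.0)


@pytest.fixture
def default_params():
    return SubjectParams()


def make_quiet_recording(duration=64.0, mean_ibi=1.0, seed=0, fs=64.0, **kw):
    """Noise-free BCG with known J-peaks, for oracle-style comparisons."""
    params = SubjectParams(mean_ibi=mean_ibi, ibi_sd=0.0, rsa_depth=0.0,
                           resp_amp=0.0, noise_sd=0.0, movement_rate=0.0, **kw)
    r = simulate_heartbeats(params, duration, seed=seed)
    j = derive_jpeaks(r, params)
    rec = synthesize_bcg(j, params, fs=fs, duration=duration, seed=seed)
    return rec, r, j, params


def brute_force_surrogate(events: EventSeries, n: int, fs: float, t0: float,
                          spec: KernelSpec) -> np.ndarray:
    """Independent per-sample/per-event double loop used as the encoding oracle."""
    t = t0 + np.arange(n) / fs
    y = np.zeros(n)
    if spec.shape == "distance_time":
        for i in range(n):
            if len(events) == 0:
                y[i] = spec.clip_s
            else:
                y[i] = min(spec.clip_s, min(abs(t[i] - p) for p in events.times))
        return y
    for i in range(n):
        for p in events.times:
            y[i] += float(kernel_value(spec, t[i] - p))
    return y


def random_event_series(rng, lo=0.0, hi=10.0, n_min=0, n_max=12) -> EventSeries:
    n = int(rng.integers(n_min, n_max + 1))
    times = np.sort(rng.uniform(lo, hi, size=n))
    times = times[np.concatenate(([True], np.diff(times) > 1e-6))] if n else times
    return EventSeries(times)
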