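"""Synthetic sleeper: paired 3-axis BCG recordings and reference heartbeats.

The generator emulates the statistical structure of night-long mattress-IMU
recordings with simultaneous ECG ground truth:

* a heartbeat train with mean interbeat interval around 0.92 s, slow
  respiratory sinus arrhythmia and Gaussian beat-to-beat jitter;
* J-peaks lagging each R-peak by a slowly drifting RJ-interval inside the
  physiological 180-240 ms band;
* a per-subject IJK-complex waveform (Gabor-like damped oscillation whose
  global maximum defines the J-peak) mixed onto three channels with one
  dominant axis;
* respiration, broadband sensor noise, sparse movement-artifact bursts, and
  an optional linear clock drift between the event clock and the signal
  clock.

Only heartbeat TIMES and a plausible BCG morphology are emulated — no real
IMU transfer function, bed mechanics or ECG waveform.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EventSeries, SignalRecording

__all__ = [
    "IjkTemplate",
    "SubjectParams",
    "SimConfig",
    "Night",
    "simulate_heartbeats",
    "derive_jpeaks",
    "synthesize_bcg",
    "draw_subject_params",
    "make_dataset",
]

# physiological clip for interbeat intervals (180 bpm .. 30 bpm)
IBI_CLIP = (0.33, 2.0)
RJ_HARD_RANGE = (0.15, 0.30)


@dataclass(frozen=True)
class IjkTemplate:
    """Damped-oscillation IJK-complex: ``exp(-u^2/(2 decay^2)) cos(2 pi f u)``.

    The cosine carrier puts the global maximum (the J-peak) exactly at offset
    0, with negative side lobes playing the role of the I and K waves.
    ``weights`` mixes the waveform onto the three channels; the default makes
    one axis dominant, mimicking the chest-aligned IMU axis.
    """

    freq: float = 5.0        # Hz, carrier of the damped oscillation
    decay: float = 0.15      # s, Gaussian envelope scale
    weights: tuple = (0.2, 0.3, 1.0)

    def __call__(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return np.exp(-0.5 * (u / self.decay) ** 2) * np.cos(2 * np.pi * self.freq * u)

    @property
    def half_support(self) -> float:
        """Offset beyond which the envelope is negligible (< 4e-4 of peak)."""
        return 4.0 * self.decay


@dataclass
class SubjectParams:
    """Generative parameters of one synthetic sleeper."""

    subject_id: str = "s00"
    mean_ibi: float = 0.92        # s
    ibi_sd: float = 0.03          # s, beat-to-beat Gaussian jitter
    rsa_freq: float = 0.25        # Hz, respiratory sinus arrhythmia
    rsa_depth: float = 0.02       # s, RSA modulation of the IBI
    rj_base: float = 0.21         # s, mean RJ-interval
    rj_drift_amp: float = 0.025   # s, slow sinusoidal RJ drift
    rj_drift_period: float = 600.0  # s
    ijk_template: IjkTemplate = field(default_factory=IjkTemplate)
    resp_freq: float = 0.25       # Hz
    resp_amp: float = 0.5         # signal units
    noise_sd: float = 0.35        # signal units, broadband sensor noise
    movement_rate: float = 6.0    # artifact bursts per hour
    clock_drift_ppm: float = 0.0  # signal clock vs. event clock

    def __post_init__(self):
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if not (0.18 <= self.rj_base <= 0.24):
            raise ValueError("rj_base must lie in the physiological 0.18-0.24 s band")
        lo, hi = self.rj_base - self.rj_drift_amp, self.rj_base + self.rj_drift_amp
        if lo < RJ_HARD_RANGE[0] or hi > RJ_HARD_RANGE[1]:
            raise ValueError("rj_base +/- rj_drift_amp must stay within [0.15, 0.30] s")
        if self.ibi_sd >= self.mean_ibi / 3:
            raise ValueError("ibi_sd must be < mean_ibi / 3")


def simulate_heartbeats(params: SubjectParams, duration: float, seed: int = 0) -> EventSeries:
    """Draw an R-peak train by cumulative summation of modelled IBIs.

    ``IBI_i = mean_ibi + rsa_depth * sin(2 pi rsa_freq t_i) + eps_i`` with
    ``eps_i ~ N(0, ibi_sd)``, clipped to 0.33-2.0 s.  The first beat falls at
    one IBI after time zero; beats are emitted while they are < ``duration``.
    """
    if duration <= 2 * params.mean_ibi:
        raise ValueError("duration must exceed two mean IBIs")
    rng = np.random.default_rng(seed)
    # upper bound on the number of beats given the IBI clip
    n_max = int(duration / IBI_CLIP[0]) + 2
    eps = rng.normal(0.0, params.ibi_sd, size=n_max) if params.ibi_sd > 0 else np.zeros(n_max)
    times = []
    t = 0.0
    for i in range(n_max):
        ibi = params.mean_ibi + params.rsa_depth * np.sin(2 * np.pi * params.rsa_freq * t) + eps[i]
        t = t + float(np.clip(ibi, *IBI_CLIP))
        if t >= duration:
            break
        times.append(t)
    return EventSeries(np.asarray(times), label="R")


def derive_jpeaks(r_peaks: EventSeries, params: SubjectParams) -> EventSeries:
    """J-peaks as R-peaks delayed by the slowly drifting RJ-interval.

    ``J_i = R_i + rj_base + rj_drift_amp * sin(2 pi R_i / rj_drift_period)``.
    The drift is far slower than a beat, so the output stays strictly
    increasing.
    """
    if len(r_peaks) == 0:
        raise ValueError("r_peaks must be nonempty")
    r = r_peaks.times
    rj = params.rj_base + params.rj_drift_amp * np.sin(2 * np.pi * r / params.rj_drift_period)
    return EventSeries(r + rj, label="J")


def _add_movement_bursts(x: np.ndarray, fs: float, rate_per_h: float,
                         noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-arriving 2-10 s bursts of 10x noise amplitude on all channels."""
    n = x.shape[0]
    duration = n / fs
    n_bursts = rng.poisson(rate_per_h * duration / 3600.0)
    burst_sd = 10.0 * noise_sd if noise_sd > 0 else 1.0
    for _ in range(n_bursts):
        start = rng.uniform(0.0, duration)
        length = rng.uniform(2.0, 10.0)
        i0 = int(start * fs)
        i1 = min(n, int((start + length) * fs))
        if i1 > i0:
            x[i0:i1] += rng.normal(0.0, burst_sd, size=(i1 - i0, x.shape[1]))
    return x


def synthesize_bcg(
    j_peaks: EventSeries,
    params: SubjectParams,
    fs: float = 64.0,
    duration: float | None = None,
    seed: int = 0,
) -> SignalRecording:
    """Render a 3-channel BCG with the IJK template at each J-peak.

    Each channel is ``w_c * sum_i template(t - J_i)`` plus a respiration
    sinusoid (channel-specific phase), white sensor noise, and sparse
    movement bursts.  A nonzero ``clock_drift_ppm`` stretches the signal time
    axis relative to the event clock: an event at ``p`` appears in the signal
    at ``p * (1 + ppm * 1e-6)``.
    """
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz (the working rate)")
    if duration is None:
        duration = float(j_peaks.times[-1] + 2.0) if len(j_peaks) else 10.0
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tpl = params.ijk_template
    w = np.asarray(tpl.weights, dtype=float)
    k = w.size

    beat = np.zeros(n)
    drift = 1.0 + params.clock_drift_ppm * 1e-6
    half = tpl.half_support
    for p in j_peaks.times:
        p_sig = p * drift
        i0 = max(0, int(np.ceil((p_sig - half) * fs)))
        i1 = min(n, int(np.floor((p_sig + half) * fs)) + 1)
        if i1 > i0:
            beat[i0:i1] += tpl(t[i0:i1] - p_sig)

    x = beat[:, None] * w[None, :]
    if params.resp_amp > 0:
        phases = 2 * np.pi * np.arange(k) / k
        x = x + params.resp_amp * np.sin(2 * np.pi * params.resp_freq * t[:, None] + phases[None, :])
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=(n, k))
    if params.movement_rate > 0:
        x = _add_movement_bursts(x, fs, params.movement_rate, params.noise_sd, rng)
    return SignalRecording(x, fs=fs, t0=0.0, channel_names=("ax", "ay", "az")[:k])


def draw_subject_params(subject_id: str, rng: np.random.Generator,
                        noise_scale: float = 1.0) -> SubjectParams:
    """Draw one sleeper's parameters from realistic inter-subject ranges."""
    rj_amp = rng.uniform(0.01, 0.025)
    rj_base = rng.uniform(0.18 + rj_amp, 0.24 - rj_amp)
    resp_freq = rng.uniform(0.18, 0.30)
    minor = rng.uniform(0.15, 0.35, size=2)
    return SubjectParams(
        subject_id=subject_id,
        mean_ibi=rng.uniform(0.82, 1.02),
        ibi_sd=rng.uniform(0.02, 0.05),
        rsa_freq=resp_freq,
        rsa_depth=rng.uniform(0.01, 0.03),
        rj_base=rj_base,
        rj_drift_amp=rj_amp,
        rj_drift_period=rng.uniform(300.0, 900.0),
        ijk_template=IjkTemplate(
            freq=rng.uniform(4.5, 5.5),
            decay=rng.uniform(0.12, 0.18),
            weights=(float(minor[0]), float(minor[1]), 1.0),
        ),
        resp_freq=resp_freq,
        resp_amp=rng.uniform(0.3, 0.7),
        noise_sd=rng.uniform(0.8, 1.2) * 0.35 * noise_scale,
        movement_rate=6.0,
    )


@dataclass
class SimConfig:
    """Dataset-level generation settings."""

    n_subjects: int = 4
    nights_per_subject: int = 1
    night_duration: float = 1200.0  # s
    fs: float = 64.0
    seed: int = 0
    clock_drift_ppm: float = 0.0
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.nights_per_subject < 1:
            raise ValueError("nights_per_subject must be >= 1")


@dataclass
class Night:
    """One generated night: recording + reference R-peaks + provenance."""

    recording: SignalRecording
    r_peaks: EventSeries
    j_peaks: EventSeries
    subject_id: str
    night_id: str
    params: SubjectParams


def make_dataset(config: SimConfig, out_dir: str | Path | None = None,
                 overwrite: bool = False, fmt: str = "csv") -> list[Night]:
    """Generate the full synthetic dataset, optionally writing it to disk.

    Subject parameters and per-night noise are drawn from independent child
    seeds of ``config.seed``, so the whole dataset is reproducible (and its
    files byte-identical) for a fixed config.
    """
    root = np.random.SeedSequence(config.seed)
    subj_seqs = root.spawn(config.n_subjects)
    nights: list[Night] = []
    for si, sseq in enumerate(subj_seqs):
        subject_id = f"s{si:02d}"
        srng = np.random.default_rng(sseq)
        params = draw_subject_params(subject_id, srng, noise_scale=config.noise_scale)
        params = dataclasses.replace(params, clock_drift_ppm=config.clock_drift_ppm)
        for ni in range(config.nights_per_subject):
            beat_seed, sig_seed = srng.integers(0, 2**31 - 1, size=2)
            r = simulate_heartbeats(params, config.night_duration, seed=int(beat_seed))
            j = derive_jpeaks(r, params)
            rec = synthesize_bcg(j, params, fs=config.fs,
                                 duration=config.night_duration, seed=int(sig_seed))
            nights.append(Night(rec, r, j, subject_id, f"n{ni:02d}", params))
    if out_dir is not None:
        write_dataset(nights, out_dir, overwrite=overwrite, fmt=fmt)
    return nights


def write_events_csv(events: EventSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": events.times, "label": events.label})
    df.to_csv(path, index=False, float_format="%.6f")


def read_events_csv(path: str | Path) -> EventSeries:
    df = pd.read_csv(path)
    label = str(df["label"].iloc[0]) if len(df) else "R"
    return EventSeries(df["time_s"].to_numpy(dtype=float), label=label)


def write_recording(rec: SignalRecording, path: str | Path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        path = path.with_suffix(".csv")
        df = pd.DataFrame({"time_s": rec.times})
        for i, name in enumerate(rec.channel_names):
            df[name] = rec.samples[:, i]
        df.to_csv(path, index=False, float_format="%.6f")
    elif fmt == "npz":
        path = path.with_suffix(".npz")
        np.savez_compressed(path, samples=rec.samples, fs=rec.fs, t0=rec.t0,
                            channel_names=np.array(rec.channel_names))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path) -> SignalRecording:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        fs = 1.0 / float(np.median(np.diff(t)))
        chans = [c for c in df.columns if c != "time_s"]
        return SignalRecording(df[chans].to_numpy(dtype=float), fs=round(fs, 6),
                               t0=float(t[0]), channel_names=tuple(chans))
    if path.suffix == ".npz":
        z = np.load(path, allow_pickle=False)
        return SignalRecording(z["samples"], fs=float(z["fs"]), t0=float(z["t0"]),
                               channel_names=tuple(str(c) for c in z["channel_names"]))
    raise ValueError(f"unsupported recording file {path}")


def write_dataset(nights: list[Night], out_dir: str | Path,
                  overwrite: bool = False, fmt: str = "csv") -> Path:
    """Write recordings, event files and a manifest; refuse to clobber."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{out_dir} already holds a dataset; pass overwrite=True")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for night in nights:
        stem = f"{night.subject_id}_{night.night_id}"
        rec_path = write_recording(night.recording, out_dir / f"{stem}_bcg", fmt=fmt)
        ev_path = out_dir / f"{stem}_rpeaks.csv"
        write_events_csv(night.r_peaks, ev_path)
        rows.append({
            "subject_id": night.subject_id,
            "night_id": night.night_id,
            "recording_path": rec_path.name,
            "events_path": ev_path.name,
            "fs": night.recording.fs,
            "duration_s": night.recording.duration,
        })
    pd.DataFrame(rows).to_csv(manifest_path, index=False, float_format="%.6f")
    return manifest_path


def load_dataset(out_dir: str | Path) -> list[tuple[SignalRecording, EventSeries, str, str]]:
    """Read back (recording, r_peaks, subject_id, night_id) tuples from a manifest."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        rec = read_recording(out_dir / row["recording_path"])
        ev = read_events_csv(out_dir / row["events_path"])
        out.append((rec, ev, str(row["subject_id"]), str(row["night_id"])))
    return out
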