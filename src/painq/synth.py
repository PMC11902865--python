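"""Synthetic multi-subject ECG with ground-truth R peaks and pain labels.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed at RR
intervals drawn from a class-dependent heart-rate-variability process:
the RR series is the mean interval modulated by a respiratory-band
sinusoid (~0.25 Hz), a low-frequency sinusoid (~0.1 Hz) and white jitter,
scaled so the RR standard deviation matches the profile's SDNN. Higher
pain maps to a higher mean heart rate and lower SDNN, mirroring the
sympathetic/parasympathetic shift that HRV-based nociception indices
quantify. Baseline wander, powerline and white noise are added per
profile. Ground truth records the exact R-bump centres, so downstream
QRS detection can be scored without any manual annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import h5py
import numpy as np

PAIN_CLASSES = ("low", "medium", "high")

#: per-class (base_heart_rate bpm, hrv_sdnn s) defaults: higher pain ->
#: faster, less variable heart rate (monotone, separable).
CLASS_DEFAULTS = {
    "low": (65.0, 0.060),
    "medium": (80.0, 0.040),
    "high": (95.0, 0.022),
}

#: beat template: (amplitude mV, offset from R in s, Gaussian width s)
BEAT_TEMPLATE = (
    (0.12, -0.200, 0.030),   # P
    (-0.13, -0.040, 0.012),  # Q
    (1.00, 0.000, 0.014),    # R
    (-0.25, 0.040, 0.013),   # S
    (0.35, 0.300, 0.070),    # T
)

#: variance split of hrv_sdnn^2 across the three RR modulation sources
_RESP_FRAC, _LF_FRAC, _WHITE_FRAC = 0.4, 0.4, 0.2
_RESP_HZ, _LF_HZ = 0.25, 0.10

RR_MIN_S, RR_MAX_S = 0.27, 2.0
LABEL_INTERVAL_S = 300.0  # one expert pain score per 5-minute interval


@dataclass(frozen=True)
class NoiseAmplitudes:
    """Per-source noise amplitudes in mV."""

    baseline_wander: float = 0.10
    powerline: float = 0.02
    white: float = 0.03

    def __post_init__(self) -> None:
        for name in ("baseline_wander", "powerline", "white"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise amplitude {name} must be >= 0")


@dataclass(frozen=True)
class SubjectProfile:
    """Static description of one simulated subject."""

    subject_id: str
    base_heart_rate: float = 75.0
    hrv_sdnn: float = 0.04
    pain_class: str = "low"
    noise: NoiseAmplitudes = field(default_factory=NoiseAmplitudes)
    powerline_hz: float = 60.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.base_heart_rate <= 220.0:
            raise ValueError(
                f"base_heart_rate {self.base_heart_rate} outside [30, 220] bpm"
            )
        if self.hrv_sdnn < 0:
            raise ValueError("hrv_sdnn must be >= 0")
        if self.pain_class not in PAIN_CLASSES:
            raise ValueError(f"pain_class must be one of {PAIN_CLASSES}")


@dataclass
class ECGRecord:
    """A single-channel ECG trace with ground truth."""

    samples: np.ndarray          # mV
    fs: int                      # Hz
    subject_id: str
    r_peak_truth: np.ndarray     # sample indices, strictly increasing
    pain_scores: list            # one class label per 5-min interval

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


def _rr_series(profile: SubjectProfile, duration: float,
               rng: np.random.Generator) -> np.ndarray:
    """Beat times (s of each R centre) spanning the record."""
    mean_rr = 60.0 / profile.base_heart_rate
    sdnn = profile.hrv_sdnn
    # sinusoid of amplitude A sampled at spread phases has std A/sqrt(2)
    a_resp = np.sqrt(2.0 * _RESP_FRAC) * sdnn
    a_lf = np.sqrt(2.0 * _LF_FRAC) * sdnn
    s_white = np.sqrt(_WHITE_FRAC) * sdnn
    ph_resp = rng.uniform(0, 2 * np.pi)
    ph_lf = rng.uniform(0, 2 * np.pi)

    times = []
    t = 0.3 * mean_rr  # first R a fraction of a beat into the record
    while t < duration + RR_MAX_S:
        times.append(t)
        rr = (mean_rr
              + a_resp * np.sin(2 * np.pi * _RESP_HZ * t + ph_resp)
              + a_lf * np.sin(2 * np.pi * _LF_HZ * t + ph_lf)
              + (s_white * rng.standard_normal() if s_white > 0 else 0.0))
        t += float(np.clip(rr, RR_MIN_S, RR_MAX_S))
    return np.asarray(times)


def _render_beats(n_samples: int, fs: int, beat_times: np.ndarray) -> np.ndarray:
    """Sum the PQRST Gaussian template at every beat time."""
    x = np.zeros(n_samples)
    half = int(0.6 * fs)  # template support around R, samples
    for t_r in beat_times:
        c = t_r * fs
        lo = max(0, int(c) - half)
        hi = min(n_samples, int(c) + half + 1)
        if lo >= hi:
            continue
        tt = (np.arange(lo, hi) - c) / fs
        for amp, off, width in BEAT_TEMPLATE:
            x[lo:hi] += amp * np.exp(-0.5 * ((tt - off) / width) ** 2)
    return x


def generate_record(profile: SubjectProfile, duration: float,
                    seed: int) -> ECGRecord:
    """Generate one subject's ECG trace.

    Parameters
    ----------
    profile : SubjectProfile
    duration : float
        Record length in seconds, >= 10.
    seed : int
        Full determinism: same profile + seed gives bit-identical output.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 10:
        raise ValueError("duration must be >= 10 s (one analysis window)")
    fs = 512
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    beat_times = _rr_series(profile, duration, rng)
    x = _render_beats(n, fs, beat_times)

    t = np.arange(n) / fs
    na = profile.noise
    if na.baseline_wander > 0:
        x += na.baseline_wander * (
            0.7 * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi))
            + 0.3 * np.sin(2 * np.pi * 0.30 * t + rng.uniform(0, 2 * np.pi)))
    if na.powerline > 0:
        x += na.powerline * np.sin(
            2 * np.pi * profile.powerline_hz * t + rng.uniform(0, 2 * np.pi))
    if na.white > 0:
        x += na.white * rng.standard_normal(n)

    peaks = np.round(beat_times * fs).astype(np.int64)
    peaks = peaks[(peaks >= 0) & (peaks < n)]

    n_intervals = max(1, int(np.ceil(duration / LABEL_INTERVAL_S)))
    labels = [profile.pain_class] * n_intervals
    return ECGRecord(samples=x, fs=fs, subject_id=profile.subject_id,
                     r_peak_truth=peaks, pain_scores=labels)


def _largest_remainder(n: int, fractions) -> list:
    """Integer counts summing to n, proportional to fractions."""
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_dataset(n_subjects: int, duration: float,
                     class_mix=(1 / 3, 1 / 3, 1 / 3), seed: int = 0,
                     noise: NoiseAmplitudes | None = None,
                     powerline_hz: float = 60.0) -> list:
    """Generate a cohort of labelled subjects, one pain class each."""
    if n_subjects < 3:
        raise ValueError("need >= 3 subjects (one per class minimum)")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix must sum to 1")
    rng = np.random.default_rng(seed)
    counts = _largest_remainder(n_subjects, class_mix)
    records = []
    idx = 0
    for cls, cnt in zip(PAIN_CLASSES, counts):
        hr0, sdnn0 = CLASS_DEFAULTS[cls]
        for _ in range(cnt):
            profile = SubjectProfile(
                subject_id=f"S{idx:03d}",
                base_heart_rate=float(hr0 + rng.uniform(-4.0, 4.0)),
                hrv_sdnn=float(sdnn0 * rng.uniform(0.9, 1.1)),
                pain_class=cls,
                noise=noise if noise is not None else NoiseAmplitudes(),
                powerline_hz=powerline_hz,
            )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            records.append(generate_record(profile, duration, sub_seed))
            idx += 1
    return records


# ---------------------------------------------------------------------------
# persistence

def save_records_hdf5(records, path) -> None:
    with h5py.File(path, "w") as f:
        for rec in records:
            g = f.create_group(rec.subject_id)
            g.create_dataset("samples", data=rec.samples)
            g.create_dataset("r_peak_truth", data=rec.r_peak_truth)
            g.attrs["fs"] = rec.fs
            g.attrs["pain_scores"] = [s.encode() for s in rec.pain_scores]


def load_records_hdf5(path) -> list:
    records = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            records.append(ECGRecord(
                samples=np.asarray(g["samples"]),
                fs=int(g.attrs["fs"]),
                subject_id=sid,
                r_peak_truth=np.asarray(g["r_peak_truth"], dtype=np.int64),
                pain_scores=[s.decode() if isinstance(s, bytes) else str(s)
                             for s in g.attrs["pain_scores"]],
            ))
    return records


def save_record_csv(record: ECGRecord, path) -> None:
    """Small plain-text export (one sample per row) for fixtures."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["# subject_id", record.subject_id])
        w.writerow(["# fs", record.fs])
        w.writerow(["# pain_scores", ";".join(record.pain_scores)])
        w.writerow(["# r_peak_truth", ";".join(map(str, record.r_peak_truth))])
        w.writerow(["sample_mv"])
        for v in record.samples:
            w.writerow([f"{v:.6f}"])


def with_samples(record: ECGRecord, samples: np.ndarray) -> ECGRecord:
    """Copy of a record with the signal replaced (metadata preserved)."""
    return ECGRecord(samples=samples, fs=record.fs,
                     subject_id=record.subject_id,
                     r_peak_truth=record.r_peak_truth,
                     pain_scores=list(record.pain_scores))
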