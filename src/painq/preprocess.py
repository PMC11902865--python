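"""Classical ECG preprocessing: bandpass filtering, normalization,
fixed-window segmentation and wavelet-coefficient QRS detection.

The QRS detector follows the classic wavelet recipe: compute CWT
magnitudes in a band tuned to QRS energy (10-25 Hz), threshold them at a
multiple of a robust scale statistic (the median), pick local maxima
above the threshold, then refine temporally by enforcing a refractory
period and the physiological RR range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cwt import MorseParams, cwt_coefficients, scale_for_frequency
from .synth import ECGRecord, LABEL_INTERVAL_S, with_samples

#: QRS energy band (Hz) used for detection scales
QRS_BAND_HZ = (10.0, 25.0)
QRS_N_SCALES = 8

RR_MIN_S, RR_MAX_S = 0.27, 2.0


class DegenerateSignalError(ValueError):
    """Raised when an operation receives a constant/empty signal."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design; defaults give the 0.5-40 Hz passband."""

    low_cut: float = 0.5
    high_cut: float = 40.0
    order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= fs / 2:
            raise ValueError(
                f"high_cut {self.high_cut} Hz violates Nyquist for fs={fs}")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class ECGSegment:
    """A fixed-length analysis window carrying exactly one pain label."""

    samples: np.ndarray
    fs: int
    subject_id: str
    label: str
    source_offset: int  # sample index in the parent record

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")


def bandpass_filter(record: ECGRecord,
                    spec: FilterSpec = FilterSpec()) -> ECGRecord:
    """Zero-phase Butterworth bandpass; same length and sampling rate."""
    spec.validate(record.fs)
    if len(record.samples) <= 3 * spec.order:
        raise ValueError("record too short for the requested filter order")
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                     btype="bandpass", fs=record.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, record.samples)
    return with_samples(record, filtered)


def normalize(segment: ECGSegment, method: str = "zscore") -> ECGSegment:
    """Amplitude normalization: zscore (mean 0, std 1) or minmax ([0, 1])."""
    x = np.asarray(segment.samples, dtype=float)
    if method == "zscore":
        std = x.std()
        if std < 1e-12:
            raise DegenerateSignalError("constant signal cannot be z-scored")
        y = (x - x.mean()) / std
    elif method == "minmax":
        lo, hi = x.min(), x.max()
        y = np.zeros_like(x) if hi - lo < 1e-300 else (x - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ECGSegment(samples=y, fs=segment.fs, subject_id=segment.subject_id,
                      label=segment.label, source_offset=segment.source_offset)


def segment_record(record: ECGRecord, window: float = 10.0) -> list:
    """Non-overlapping windows; incomplete tail dropped.

    Each segment inherits the pain label of the 5-minute interval its
    start falls in (all windows of an interval share one expert score).
    """
    win = int(round(window * record.fs))
    n = len(record.samples)
    if n < win:
        raise ValueError("record shorter than one window")
    segments = []
    for k in range(n // win):
        off = k * win
        interval = int((off / record.fs) // LABEL_INTERVAL_S)
        interval = min(interval, len(record.pain_scores) - 1)
        segments.append(ECGSegment(
            samples=record.samples[off:off + win].copy(),
            fs=record.fs, subject_id=record.subject_id,
            label=record.pain_scores[interval], source_offset=off))
    return segments


def qrs_envelope(record: ECGRecord,
                 params: MorseParams = MorseParams()) -> np.ndarray:
    """Summed CWT magnitude over the QRS-tuned scale band."""
    freqs = np.geomspace(QRS_BAND_HZ[0], QRS_BAND_HZ[1], QRS_N_SCALES)
    scales = scale_for_frequency(freqs, record.fs, params)
    coeffs = cwt_coefficients(record.samples, scales, params)
    return np.abs(coeffs).sum(axis=0)


def detect_qrs(record: ECGRecord, threshold_factor: float = 3.0,
               refractory: float = 0.2) -> np.ndarray:
    """R-peak sample indices via wavelet magnitude thresholding.

    Threshold = threshold_factor x median(envelope); local maxima above
    it are kept, then refined: minimum spacing of `refractory` seconds,
    and any remaining pair closer than the physiological RR minimum
    keeps only the stronger peak.
    """
    if len(record.samples) < record.fs // 2:
        raise ValueError("record too short for QRS detection")
    env = qrs_envelope(record)
    thr = threshold_factor * float(np.median(env))
    if thr <= 0:
        thr = 1e-12
    peaks, _ = sps.find_peaks(env, height=thr,
                              distance=max(1, int(refractory * record.fs)))
    # temporal refinement: enforce the minimum plausible RR interval
    min_rr = int(RR_MIN_S * record.fs)
    kept: list = []
    for p in peaks:
        if kept and p - kept[-1] < min_rr:
            if env[p] > env[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    return np.asarray(kept, dtype=np.int64)


def match_peaks(detected: np.ndarray, truth: np.ndarray, fs: int,
                tolerance_s: float = 0.05) -> tuple:
    """Greedy one-to-one matching; returns (recall, precision).

    A detected peak matches an unclaimed truth peak within the tolerance.
    """
    tol = tolerance_s * fs
    truth = np.asarray(truth)
    used = np.zeros(len(truth), dtype=bool)
    tp = 0
    for d in np.asarray(detected):
        if len(truth) == 0:
            break
        j = int(np.argmin(np.where(used, np.inf, np.abs(truth - d))))
        if not used[j] and abs(truth[j] - d) <= tol:
            used[j] = True
            tp += 1
    recall = tp / len(truth) if len(truth) else 1.0
    precision = tp / len(detected) if len(detected) else 1.0
    return recall, precision


def save_peaks_csv(peaks: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(peaks, dtype=np.int64)[:, None],
               fmt="%d", header="r_peak_sample", comments="")
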