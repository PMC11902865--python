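"""Continuous wavelet transform with a generalized Morse wavelet.

The analytic Morse wavelet is defined directly in the frequency domain,

    psi_hat(w) = H(w) * (w / w0)**beta * exp(-(w / w0)**gamma),

with H the unit step, so it has no negative-frequency content and the
transform magnitude is an envelope. The CWT uses the L2 convention

    W_x(a, b) = (1 / sqrt(a)) * integral x(t) psi*((t - b) / a) dt,

evaluated in the Fourier domain as ifft(X(w) * sqrt(a) * psi_hat(a w)).
The reference frequency w0 defaults to (gamma/beta)**(1/gamma), which
places the undilated wavelet's peak response at exactly 1 rad/sample, so
scale a responds maximally to fs / (2 pi a) Hz.

Scalograms are 640 x 640 magnitude images: 640 log-spaced scales whose
centre frequencies span the analysis passband (0.5-40 Hz by default) and
a time axis reduced to 640 columns by block-averaging (factor 8 for a
10-s segment at 512 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BETA = 3.0
DEFAULT_GAMMA = 60.0
SCALOGRAM_SIZE = 640
DEFAULT_F_MIN_HZ = 0.5
DEFAULT_F_MAX_HZ = 40.0


@dataclass(frozen=True)
class MorseParams:
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    omega0: float | None = None  # None -> peak-normalized (gamma/beta)**(1/gamma)

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if self.omega0 is not None and self.omega0 <= 0:
            raise ValueError("omega0 must be positive")

    @property
    def omega_ref(self) -> float:
        if self.omega0 is not None:
            return self.omega0
        return (self.gamma / self.beta) ** (1.0 / self.gamma)

    @property
    def peak_omega(self) -> float:
        """Frequency (rad/sample) of maximal psi_hat: w0*(beta/gamma)**(1/gamma)."""
        return self.omega_ref * (self.beta / self.gamma) ** (1.0 / self.gamma)


@dataclass(frozen=True)
class ScaleGrid:
    """Dilations (strictly increasing) and translations in samples."""

    scales: np.ndarray
    translations: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or len(self.translations) == 0:
            raise ValueError("scale and translation grids must be non-empty")
        if np.any(np.diff(self.scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(np.asarray(self.scales) <= 0):
            raise ValueError("scales must be positive")


@dataclass
class Scalogram:
    magnitude: np.ndarray   # (n_scales, n_times), non-negative
    scale_axis: np.ndarray  # dilations, increasing
    time_axis: np.ndarray   # seconds
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.magnitude)) or np.any(self.magnitude < 0):
            raise ValueError("scalogram magnitudes must be finite and >= 0")


def morse_fourier(omega, params: MorseParams = MorseParams()):
    """Frequency-domain Morse wavelet amplitude; total on the reals.

    Vectorized; returns 0 for omega <= 0 (analytic wavelet).
    """
    omega = np.asarray(omega, dtype=float)
    scalar = omega.ndim == 0
    omega = np.atleast_1d(omega)
    out = np.zeros_like(omega)
    pos = omega > 0
    with np.errstate(over="ignore", under="ignore"):
        r = omega[pos] / params.omega_ref
        logr = np.log(r)
        decay = np.exp(np.minimum(params.gamma * logr, 700.0))
        out[pos] = np.exp(params.beta * logr - decay)
    return float(out[0]) if scalar else out


def scale_for_frequency(f_hz, fs: float,
                        params: MorseParams = MorseParams()):
    """Dilation whose peak response sits at f_hz for sampling rate fs."""
    f_hz = np.asarray(f_hz, dtype=float)
    if np.any(f_hz <= 0) or np.any(f_hz >= fs / 2):
        raise ValueError("frequency must lie in (0, fs/2)")
    return fs * params.peak_omega / (2.0 * np.pi * f_hz)


def frequency_for_scale(scales, fs: float,
                        params: MorseParams = MorseParams()):
    scales = np.asarray(scales, dtype=float)
    return fs * params.peak_omega / (2.0 * np.pi * scales)


def default_scale_grid(n_samples: int, fs: float,
                       n_scales: int = SCALOGRAM_SIZE,
                       f_min: float = DEFAULT_F_MIN_HZ,
                       f_max: float = DEFAULT_F_MAX_HZ,
                       params: MorseParams = MorseParams()) -> ScaleGrid:
    """Log-spaced scales covering [f_min, f_max] Hz; every-sample shifts."""
    freqs = np.geomspace(f_max, f_min, n_scales)  # descending f -> ascending a
    scales = scale_for_frequency(freqs, fs, params)
    return ScaleGrid(scales=scales, translations=np.arange(n_samples))


def cwt_coefficients(x: np.ndarray, scales: np.ndarray,
                     params: MorseParams = MorseParams()) -> np.ndarray:
    """Complex CWT coefficients, shape (n_scales, len(x)).

    Frequency-domain evaluation: multiply the signal spectrum by the
    dilated wavelet (conjugation is a no-op: psi_hat is real) with the
    sqrt(a) factor of the L2 convention, then inverse transform.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("signal must have at least 2 samples")
    scales = np.asarray(scales, dtype=float)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample
    X = np.fft.fft(x)
    filt = morse_fourier(scales[:, None] * omega[None, :], params)
    return np.fft.ifft(X[None, :] * np.sqrt(scales)[:, None] * filt, axis=1)


def _block_reduce_time(mag: np.ndarray, n_out: int) -> np.ndarray:
    """Average consecutive time columns down to n_out (tail truncated)."""
    n = mag.shape[1]
    if n < n_out:
        raise ValueError(f"cannot reduce {n} time points to {n_out}")
    factor = n // n_out
    mag = mag[:, : factor * n_out]
    return mag.reshape(mag.shape[0], n_out, factor).mean(axis=2)


def cwt_transform(segment, grid: ScaleGrid | None = None,
                  params: MorseParams = MorseParams(),
                  n_out: int = SCALOGRAM_SIZE) -> Scalogram:
    """Scalogram of an ECG segment (640 x 640 at defaults).

    Accepts an ECGSegment (anything with .samples/.fs and optionally
    .subject_id) or a bare array with fs=512 assumed.
    """
    if hasattr(segment, "samples"):
        x, fs = np.asarray(segment.samples, dtype=float), segment.fs
        sid = getattr(segment, "subject_id", "")
    else:
        x, fs, sid = np.asarray(segment, dtype=float), 512, ""
    if grid is None:
        grid = default_scale_grid(len(x), fs, n_scales=n_out, params=params)
    nyq_scale = scale_for_frequency(fs / 2 * (1 - 1e-9), fs, params)
    if np.any(np.asarray(grid.scales) < nyq_scale):
        raise ValueError("scale grid maps above the Nyquist frequency")
    coeffs = cwt_coefficients(x, grid.scales, params)
    mag = np.abs(coeffs)
    mag = _block_reduce_time(mag, n_out)
    factor = len(x) // n_out
    time_axis = (np.arange(n_out) + 0.5) * factor / fs
    return Scalogram(magnitude=mag, scale_axis=np.asarray(grid.scales),
                     time_axis=time_axis, source_id=str(sid))


def scalogram_to_image(s: Scalogram) -> np.ndarray:
    """Min-max scale magnitudes to [0, 1]; constant input maps to zeros."""
    m = s.magnitude
    lo, hi = float(m.min()), float(m.max())
    if hi - lo < 1e-300:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def save_image_png(image: np.ndarray, path) -> None:
    """Write a [0,1] image as 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.clip(image * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_scalogram_hdf5(s: Scalogram, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("magnitude", data=s.magnitude)
        f.create_dataset("scale_axis", data=s.scale_axis)
        f.create_dataset("time_axis", data=s.time_axis)
        f.attrs["source_id"] = s.source_id
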