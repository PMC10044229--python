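"""Spectro-temporal primitives: spectrograms, average spectra, envelopes,
merging/resampling.

Power spectra are densities (amplitude²/Hz) with the window normalized so
that integrating the peak of a full-scale sine recovers its RMS power
independently of the FFT size; this is what downstream calibration relies
on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .audio import AudioSegment, read_wav

__all__ = [
    "Spectrogram",
    "AverageSpectrum",
    "spectrogram",
    "average_spectrum",
    "envelope",
    "merge_and_resample",
]


@dataclass
class Spectrogram:
    """Short-time power-density matrix, ``power[time, frequency]``."""

    power: np.ndarray
    times: np.ndarray  # frame centers, s from recording start
    freqs: np.ndarray  # Hz
    rate: float
    window: str
    fft_size: int
    overlap: float

    @property
    def time_step(self) -> float:
        return self.fft_size * (1.0 - self.overlap) / self.rate

    @property
    def freq_step(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def frame_power(self) -> np.ndarray:
        """Total power per frame (integral of the density over frequency)."""
        return np.trapezoid(self.power, self.freqs, axis=1)

    def mean_power_spectrum(self) -> np.ndarray:
        return self.power.mean(axis=0)

    def export_csv(self, path: str | Path) -> None:
        """Plain-matrix export: first row frequencies, first column times."""
        out = np.zeros((self.power.shape[0] + 1, self.power.shape[1] + 1))
        out[0, 1:] = self.freqs
        out[1:, 0] = self.times
        out[1:, 1:] = self.power
        np.savetxt(path, out, delimiter=",")


@dataclass
class AverageSpectrum:
    """Time-averaged power density over a segment, zeroed outside ``band``."""

    freqs: np.ndarray
    power: np.ndarray  # density, amplitude²/Hz
    band: tuple[float, float]

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs/power shape mismatch")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power, self.freqs))

    @property
    def is_silent(self) -> bool:
        return self.total_power <= 0.0


def spectrogram(segment: AudioSegment, fft_size: int = 1024,
                overlap: float = 0.75, window: str = "hamming",
                nfft: int | None = None) -> Spectrogram:
    """Magnitude-squared short-time transform (power density).

    Raises ``ValueError`` if the segment is shorter than one analysis frame.
    """
    x = segment.samples
    if len(x) < fft_size:
        raise ValueError(f"segment of {len(x)} samples shorter than one "
                         f"{fft_size}-point frame")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    noverlap = int(round(overlap * fft_size))
    f, t, sxx = signal.spectrogram(
        x, fs=segment.rate, window=signal.get_window(window, fft_size),
        nperseg=fft_size, noverlap=noverlap, nfft=nfft,
        detrend=False, scaling="density", mode="psd")
    return Spectrogram(power=sxx.T, times=segment.start_time + t, freqs=f,
                       rate=segment.rate, window=window, fft_size=fft_size,
                       overlap=overlap)


def average_spectrum(segment: AudioSegment,
                     band: tuple[float, float] | None = None,
                     fft_size: int = 1024, overlap: float = 0.75,
                     window: str = "hamming",
                     nfft: int | None = None) -> AverageSpectrum:
    """Time-averaged power spectral profile of a segment, band-restricted.

    Frequency parameters of calls are measured on this average energy
    spectrum.  ``fft_size`` is shrunk to the segment length for short
    segments.  ``band=None`` keeps the full ``[0, rate/2]`` range.
    """
    nyq = segment.rate / 2.0
    if band is None:
        band = (0.0, nyq)
    lo, hi = band
    if hi <= lo:
        raise ValueError(f"inverted band {band}")
    if hi > nyq + 1e-9:
        raise ValueError(f"band {band} exceeds Nyquist {nyq} Hz")
    nper = min(fft_size, len(segment))
    # zero-pad half a frame on both ends so overlapping frames cover the
    # segment edges uniformly: transient calls are not underweighted at
    # their onset/offset
    pad = np.zeros(nper // 2)
    x = np.concatenate([pad, segment.samples, pad])
    f, _, sxx = signal.spectrogram(
        x, fs=segment.rate,
        window=signal.get_window(window, nper), nperseg=nper,
        noverlap=int(round(overlap * nper)),
        nfft=max(nfft or 0, nper), detrend=False, scaling="density",
        mode="psd")
    p = sxx.mean(axis=1)
    p[(f < lo) | (f > hi)] = 0.0
    return AverageSpectrum(freqs=f, power=p, band=(lo, hi))


def envelope(segment: AudioSegment, smoothing: float = 0.01) -> np.ndarray:
    """Amplitude envelope by rectification + zero-phase low-pass.

    ``smoothing`` (s) sets the low-pass cutoff at ``1 / (2 * smoothing)``
    Hz (default 50 Hz), mirroring how pulse counts are read off an
    oscillogram.  Result is non-negative and the same length as the input.
    """
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    if smoothing >= segment.duration:
        raise ValueError(f"smoothing {smoothing}s >= segment duration "
                         f"{segment.duration}s")
    cutoff = 1.0 / (2.0 * smoothing)
    cutoff = min(cutoff, 0.45 * segment.rate)
    sos = signal.butter(4, cutoff, fs=segment.rate, output="sos")
    env = signal.sosfiltfilt(sos, np.abs(segment.samples))
    # rectified mean is amplitude * 2/pi for a sine; rescale to amplitude
    return np.maximum(env, 0.0) * (np.pi / 2.0)


def merge_and_resample(files: list[str | Path],
                       target_rate: float = 11025.0) -> AudioSegment:
    """Concatenate WAV files in order and resample to ``target_rate``.

    Anti-aliased polyphase resampling; a single file already at the target
    rate passes through bit-identically.  Upconversion triggers a warning
    (not an error).
    """
    if not files:
        raise ValueError("no input files")
    parts = [read_wav(f) for f in files]
    rates = {p.rate for p in parts}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates {sorted(rates)}; resample "
                         "inputs individually first")
    src_rate = parts[0].rate
    samples = np.concatenate([p.samples for p in parts]) if len(parts) > 1 \
        else parts[0].samples
    if target_rate == src_rate:
        return AudioSegment(samples, src_rate)
    if target_rate > src_rate:
        warnings.warn(f"upconverting {src_rate} Hz -> {target_rate} Hz adds "
                      "no information", stacklevel=2)
    from fractions import Fraction
    frac = Fraction(int(round(target_rate)), int(round(src_rate)))
    out = signal.resample_poly(samples, frac.numerator, frac.denominator)
    return AudioSegment(out, float(target_rate))
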