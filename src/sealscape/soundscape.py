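"""Calibrated long-term soundscape metrics.

Provides hydrophone calibration to pressure units, long-term spectrogram
averages (LTSA), per-frequency PSD percentile curves, and broadband /
octave-band level time series.  Levels are in dB re 1 µPa (or dB re full
scale for uncalibrated input, flagged by the segment units).

PSD estimation uses averaged windowed periodograms (1 s Hann windows, 50%
overlap, 1 Hz bins); octave bands are base-2, spanning ``[fc/√2, fc·√2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .audio import AudioSegment

__all__ = [
    "HydrophoneCal",
    "LTSA",
    "PSDPercentiles",
    "calibrate",
    "ltsa",
    "psd_percentiles",
    "band_levels",
    "octave_band",
    "BROADBAND",
    "OCTAVE_CENTERS",
]

#: broadband integration range, Hz
BROADBAND = (20.0, 5500.0)
#: nominal octave-band centers, Hz
OCTAVE_CENTERS = (125.0, 500.0, 2000.0)

_TINY = 1e-30


@dataclass(frozen=True)
class HydrophoneCal:
    """Hydrophone transfer: sensitivity (dB re V/µPa), gain (dB), ADC
    full-scale voltage."""

    sensitivity_db: float = -168.5
    gain_db: float = 0.0
    adc_full_scale: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.sensitivity_db, self.gain_db, self.adc_full_scale):
            if not np.isfinite(v):
                raise ValueError("calibration values must be finite")
        if self.adc_full_scale <= 0:
            raise ValueError("adc_full_scale must be > 0")

    @property
    def fullscale_to_upa(self) -> float:
        """Linear factor from full-scale fraction to µPa."""
        return self.adc_full_scale * 10.0 ** (
            -(self.sensitivity_db + self.gain_db) / 20.0)


def calibrate(segment: AudioSegment, cal: HydrophoneCal) -> AudioSegment:
    """Convert a full-scale recording to a pressure series in µPa."""
    if cal is None:
        raise ValueError("missing calibration")
    if segment.units == "uPa":
        return segment
    return replace(segment, samples=segment.samples * cal.fullscale_to_upa,
                   units="uPa", calibration=cal)


def _ref_label(segment: AudioSegment) -> str:
    return "dB re 1 uPa" if segment.units == "uPa" else "dB re full scale"


def _psd_frames(segment: AudioSegment, window_s: float, overlap: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame power densities: (freqs, frame_times, psd[time, freq])."""
    nper = int(round(window_s * segment.rate))
    if nper > len(segment):
        raise ValueError(f"analysis window {window_s}s exceeds recording "
                         f"({segment.duration:.2f}s)")
    f, t, sxx = signal.spectrogram(
        segment.samples, fs=segment.rate,
        window=signal.get_window("hann", nper), nperseg=nper,
        noverlap=int(round(overlap * nper)), detrend=False,
        scaling="density", mode="psd")
    return f, segment.start_time + t, sxx.T


@dataclass
class LTSA:
    """Long-term spectrogram average: power-averaged dB matrix."""

    times: np.ndarray          # bin starts, s
    freqs: np.ndarray          # bin centers, Hz
    levels_db: np.ndarray      # time bins x frequency bins
    reference: str

    @property
    def linear(self) -> np.ndarray:
        return 10.0 ** (self.levels_db / 10.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels_db, index=self.times,
                            columns=self.freqs)


def ltsa(segment: AudioSegment, time_bin: float = 5.0, freq_bin: float = 5.0,
         window_s: float = 1.0, overlap: float = 0.5) -> LTSA:
    """Average spectrogram power into a coarse time × frequency grid (dB)."""
    if time_bin > segment.duration:
        raise ValueError(f"time bin {time_bin}s exceeds recording span "
                         f"{segment.duration:.2f}s")
    f, t, psd = _psd_frames(segment, window_s, overlap)
    if freq_bin > f[-1]:
        raise ValueError(f"frequency bin {freq_bin} Hz exceeds bandwidth")
    t_edges = np.arange(segment.start_time, segment.end_time + 1e-9, time_bin)
    if t_edges[-1] < segment.end_time - 1e-9:
        t_edges = np.append(t_edges, segment.end_time)
    f_edges = np.arange(0.0, f[-1] + freq_bin, freq_bin)
    ti = np.clip(np.digitize(t, t_edges) - 1, 0, len(t_edges) - 2)
    fi = np.clip(np.digitize(f, f_edges) - 1, 0, len(f_edges) - 2)
    out = np.zeros((len(t_edges) - 1, len(f_edges) - 1))
    cnt = np.zeros_like(out)
    np.add.at(out, (ti[:, None], fi[None, :]), psd)
    np.add.at(cnt, (ti[:, None], fi[None, :]), 1.0)
    mean = out / np.maximum(cnt, 1.0)
    return LTSA(times=t_edges[:-1],
                freqs=0.5 * (f_edges[:-1] + f_edges[1:]),
                levels_db=10.0 * np.log10(mean + _TINY),
                reference=_ref_label(segment))


@dataclass
class PSDPercentiles:
    """Per-frequency percentiles of windowed spectral density estimates."""

    freqs: np.ndarray
    percentiles: tuple[int, ...]
    levels_db: dict[int, np.ndarray]   # percentile -> curve
    reference: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({f"P{p}": self.levels_db[p]
                             for p in self.percentiles}, index=self.freqs)


def psd_percentiles(segment: AudioSegment,
                    percentiles: tuple[int, ...] = (10, 25, 50, 75, 90),
                    window_s: float = 1.0, overlap: float = 0.5
                    ) -> PSDPercentiles:
    """Percentile curves of per-window PSD estimates (dB re 1 µPa²/Hz).

    Requires at least 10 analysis windows.
    """
    f, _, psd = _psd_frames(segment, window_s, overlap)
    if psd.shape[0] < 10:
        raise ValueError(f"only {psd.shape[0]} analysis windows; need >= 10")
    pcts = tuple(sorted(percentiles))
    curves = {p: 10.0 * np.log10(np.percentile(psd, p, axis=0) + _TINY)
              for p in pcts}
    ref = ("dB re 1 uPa^2/Hz" if segment.units == "uPa"
           else "dB re full scale^2/Hz")
    return PSDPercentiles(freqs=f, percentiles=pcts, levels_db=curves,
                          reference=ref)


def octave_band(center: float) -> tuple[float, float]:
    """Base-2 octave band ``[fc/√2, fc·√2]``."""
    return (center / np.sqrt(2.0), center * np.sqrt(2.0))


def band_levels(segment: AudioSegment,
                bands: dict[str, tuple[float, float]] | None = None,
                time_bin: float = 60.0, window_s: float = 1.0,
                overlap: float = 0.5) -> pd.DataFrame:
    """RMS level per time bin integrated over each band (dB re 1 µPa).

    Default bands: broadband 20 Hz–5.5 kHz plus octave bands centered at
    125/500/2000 Hz.  Band edges must lie below the Nyquist frequency.
    """
    if bands is None:
        bands = {"BB": BROADBAND}
        bands.update({f"OL{int(c)}": octave_band(c) for c in OCTAVE_CENTERS})
    nyq = segment.rate / 2.0
    for name, (lo, hi) in bands.items():
        if hi > nyq + 1e-9:
            raise ValueError(f"band {name} {lo, hi} exceeds Nyquist {nyq}")
        if hi <= lo:
            raise ValueError(f"inverted band {name}")
    f, t, psd = _psd_frames(segment, window_s, overlap)
    df = float(f[1] - f[0])
    t_edges = np.arange(segment.start_time, segment.end_time - window_s / 2,
                        time_bin)
    ti = np.clip(np.digitize(t, t_edges) - 1, 0, len(t_edges) - 1)
    out = {"time": t_edges}
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f < hi)
        band_power = psd[:, sel].sum(axis=1) * df
        binned = np.zeros(len(t_edges))
        cnt = np.zeros(len(t_edges))
        np.add.at(binned, ti, band_power)
        np.add.at(cnt, ti, 1.0)
        out[name] = 10.0 * np.log10(binned / np.maximum(cnt, 1.0) + _TINY)
    result = pd.DataFrame(out)
    result.attrs["reference"] = _ref_label(segment)
    return result
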