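"""Independent brute-force oracles used to cross-check the library paths.

These deliberately avoid the package's own DSP routines: plain periodograms,
moving-average envelopes, direct cumulative sums, and per-second occupancy
grids.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram


def fft_peak(x: np.ndarray, rate: float,
             band: tuple[float, float] | None = None) -> float:
    """Dominant frequency by plain periodogram argmax."""
    f, p = periodogram(x, fs=rate, detrend=False)
    if band is not None:
        p = np.where((f >= band[0]) & (f <= band[1]), p, 0.0)
    return float(f[np.argmax(p)])


def band_power_fraction(x: np.ndarray, rate: float,
                        band: tuple[float, float]) -> float:
    """Fraction of total power inside ``band`` (Parseval route)."""
    f, p = periodogram(x, fs=rate, detrend=False)
    total = p.sum()
    return float(p[(f >= band[0]) & (f <= band[1])].sum() / total)


def moving_average_envelope(x: np.ndarray, rate: float,
                            window_s: float = 0.01) -> np.ndarray:
    n = max(int(round(window_s * rate)), 1)
    kernel = np.ones(n) / n
    return np.convolve(np.abs(x), kernel, mode="same")


def envelope_fft_peak(x: np.ndarray, rate: float,
                      search: tuple[float, float] = (1.0, 45.0)) -> float:
    """Modulation rate via moving-average envelope + FFT argmax."""
    env = moving_average_envelope(x, rate)
    env = env - env.mean()
    nfft = 8 * env.size
    f = np.fft.rfftfreq(nfft, 1.0 / rate)
    p = np.abs(np.fft.rfft(env, n=nfft)) ** 2
    p[(f < search[0]) | (f > search[1])] = 0.0
    return float(f[np.argmax(p)])


def count_pulses(x: np.ndarray, rate: float,
                 threshold: float = 0.25) -> int:
    """Count pulses as contiguous runs of envelope above a threshold."""
    env = moving_average_envelope(x, rate, window_s=0.005)
    above = env > threshold * env.max()
    edges = np.diff(above.astype(int))
    return int(np.sum(edges == 1) + (1 if above[0] else 0))


def cumsum_quartiles(freqs: np.ndarray, power: np.ndarray,
                     band: tuple[float, float]
                     ) -> tuple[float, float, float]:
    """Quartile frequencies by direct cumulative summation over bins."""
    p = np.where((freqs >= band[0]) & (freqs <= band[1]), power, 0.0)
    cum = np.cumsum(p) / p.sum()
    return tuple(float(freqs[np.searchsorted(cum, q)])
                 for q in (0.25, 0.50, 0.75))


def occupancy_hours(intervals: list[tuple[float, float]],
                    day_s: int = 86400) -> float:
    """Union length (hours) of integer-second intervals via a 1 s grid."""
    grid = np.zeros(day_s, dtype=bool)
    for s, e in intervals:
        grid[int(s):int(e)] = True
    return float(grid.sum() / 3600.0)


def occupancy_per_hour(intervals: list[tuple[float, float]]) -> np.ndarray:
    """Per-clock-hour union occupancy (hours) via a 1 s grid."""
    grid = np.zeros(86400, dtype=bool)
    for s, e in intervals:
        grid[int(s):int(e)] = True
    return grid.reshape(24, 3600).sum(axis=1) / 3600.0
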