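"""Per-category acoustic measurements on labeled call segments.

Implements the measured variables — duration (``dur``), fundamental
frequency (``f0``), frequency excursion (``excF``), spectral peak
(``Fmax``), energy quartiles (``Q25``/``Q50``/``Q75``) and pulse rate
(``PR``) — with call-type-specific band limits, and the category dispatch
that fills a :class:`FeatureVector`.

The fundamental is estimated automatically (the variable was originally a
manual cursor reading): a harmonic-comb score over the average spectrum
seeds a frame-by-frame fundamental track, and f0 is reported as the
midrange of that track (the midrange of a symmetric modulation arch equals
the contour mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioSegment
from .dsp import AverageSpectrum, average_spectrum, envelope
from .repertoire import CallType, VARIABLES, get_call_type

__all__ = [
    "SilentSegmentError",
    "UndefinedF0Error",
    "TrackTooShortError",
    "NotMeasurableError",
    "CallSegment",
    "FeatureVector",
    "measure_duration",
    "estimate_f0",
    "track_fundamental",
    "excursion_frequency",
    "peak_and_quartiles",
    "pulse_rate",
    "extract_features",
]


class SilentSegmentError(ValueError):
    """Segment has no energy to measure."""


class UndefinedF0Error(ValueError):
    """No harmonic structure exceeding the noise floor."""


class TrackTooShortError(ValueError):
    """Fundamental trackable over fewer than 3 frames."""


class NotMeasurableError(ValueError):
    """Call type or quality excludes this segment from measurement."""


@dataclass
class CallSegment:
    """A labeled call interval within a recording; unit of measurement."""

    audio: AudioSegment
    start: float
    end: float
    call_type: CallType
    quality: str = "good"  # "good" | "degraded"

    def __post_init__(self) -> None:
        if isinstance(self.call_type, str):
            self.call_type = get_call_type(self.call_type)
        if self.end <= self.start:
            raise ValueError(f"end {self.end} <= start {self.start}")

    def clip(self) -> AudioSegment:
        return self.audio.slice(self.start, self.end)


@dataclass
class FeatureVector:
    """Measured variables of one call; fields are None where unavailable."""

    dur: float | None = None
    f0: float | None = None
    excF: float | None = None
    Fmax: float | None = None
    Q25: float | None = None
    Q50: float | None = None
    Q75: float | None = None
    PR: float | None = None

    def __post_init__(self) -> None:
        if self.dur is not None and self.dur <= 0:
            raise ValueError("dur must be > 0")
        if self.PR is not None and self.PR <= 0:
            raise ValueError("PR must be > 0")
        qs = [q for q in (self.Q25, self.Q50, self.Q75) if q is not None]
        if len(qs) == 3 and not qs[0] <= qs[1] <= qs[2]:
            raise ValueError(f"quartiles out of order: {qs}")

    def masked(self, mask: tuple[str, ...]) -> dict[str, float | None]:
        """Report dict with variables outside ``mask`` blanked."""
        return {v: getattr(self, v) if v in mask else None
                for v in VARIABLES}

    def as_dict(self) -> dict[str, float | None]:
        return {v: getattr(self, v) for v in VARIABLES}


# ---------------------------------------------------------------------------
# temporal measurements
# ---------------------------------------------------------------------------

def measure_duration(segment: AudioSegment, threshold_db: float = -20.0,
                     smoothing: float = 0.01) -> float:
    """Duration between first and last envelope crossings of the threshold.

    The threshold is relative to the envelope peak (default -20 dB),
    mirroring a reading off the oscillogram.
    """
    env = envelope(segment, smoothing=smoothing)
    peak = env.max()
    if peak <= 0 or not np.any(np.abs(segment.samples) > 0):
        raise SilentSegmentError("all-silent segment")
    thresh = peak * 10.0 ** (threshold_db / 20.0)
    above = np.flatnonzero(env >= thresh)
    return float((above[-1] - above[0] + 1) / segment.rate)


def pulse_rate(segment: AudioSegment, mode: str = "discrete",
               smoothing: float = 0.01,
               am_search: tuple[float, float] = (1.0, 45.0)) -> float:
    """Pulses per second of a pulsative call.

    ``discrete``: ``(n_peaks - 1) / (t_last - t_first)`` from envelope peak
    detection.  ``am``: frequency of the envelope-spectrum peak within
    ``am_search``.
    """
    env = envelope(segment, smoothing=smoothing)
    if env.max() <= 0:
        raise SilentSegmentError("all-silent segment")
    if mode == "discrete":
        distance = max(int(0.03 * segment.rate), 1)
        peaks, _ = signal.find_peaks(env, height=0.25 * env.max(),
                                     distance=distance,
                                     prominence=0.15 * env.max())
        if len(peaks) < 2:
            raise NotMeasurableError(
                f"found {len(peaks)} pulse(s); need at least 2")
        span = (peaks[-1] - peaks[0]) / segment.rate
        return float((len(peaks) - 1) / span)
    if mode == "am":
        x = env - env.mean()
        nfft = max(8 * x.size, 4096)
        spec = np.abs(np.fft.rfft(x * np.hanning(x.size), n=nfft)) ** 2
        freqs = np.fft.rfftfreq(nfft, 1.0 / segment.rate)
        mask = (freqs >= am_search[0]) & (freqs <= am_search[1])
        if not mask.any() or spec[mask].max() <= 0:
            raise NotMeasurableError("no modulation energy in search range")
        idx = np.flatnonzero(mask)[np.argmax(spec[mask])]
        pr = _parabolic_peak(freqs, spec, idx)
        if pr * segment.duration < 2.0:
            raise NotMeasurableError(
                f"fewer than 2 modulation cycles at {pr:.2f} Hz")
        return float(pr)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# spectral measurements
# ---------------------------------------------------------------------------

def _parabolic_peak(freqs: np.ndarray, power: np.ndarray, idx: int) -> float:
    """Refine a discrete argmax by fitting a parabola to its neighbours."""
    if idx <= 0 or idx >= power.size - 1:
        return float(freqs[idx])
    a, b, c = power[idx - 1], power[idx], power[idx + 1]
    denom = a - 2 * b + c
    if denom == 0 or not np.isfinite(denom):
        return float(freqs[idx])
    shift = 0.5 * (a - c) / denom
    shift = np.clip(shift, -1.0, 1.0)
    return float(freqs[idx] + shift * (freqs[1] - freqs[0]))


def peak_and_quartiles(avg_spectrum: AverageSpectrum,
                       band: tuple[float, float] | None = None
                       ) -> tuple[float, float, float, float]:
    """``(Fmax, Q25, Q50, Q75)`` of an average spectrum.

    Fmax is the in-band argmax of the power density; Qk is the lowest
    frequency bin at which the cumulative in-band power reaches k% of the
    total in-band power.
    """
    band = band or avg_spectrum.band
    f = avg_spectrum.freqs
    mask = (f >= band[0]) & (f <= band[1])
    p = np.where(mask, avg_spectrum.power, 0.0)
    total = p.sum()
    if total <= 0:
        raise SilentSegmentError(f"zero in-band energy in {band}")
    fmax = float(f[np.argmax(p)])
    cum = np.cumsum(p) / total
    q25, q50, q75 = (float(f[np.searchsorted(cum, q)])
                     for q in (0.25, 0.50, 0.75))
    return fmax, q25, q50, q75


def _comb_estimate(spec: AverageSpectrum, search: tuple[float, float],
                   n_harmonics: int, resolution: float,
                   min_peak_ratio: float) -> float:
    """Fundamental maximizing a log-domain harmonic-comb score.

    The score averages ``log1p(P(k f) / floor)`` over the comb teeth inside
    the band (a harmonic-product-spectrum variant): hit counts dominate, so
    sub- and super-harmonics of the true fundamental lose against it.
    """
    f, p = spec.freqs, spec.power
    in_band = p[(f >= spec.band[0]) & (f <= spec.band[1])]
    if in_band.size == 0 or in_band.max() <= 0:
        raise SilentSegmentError("no in-band energy")
    floor = max(float(np.median(in_band)), in_band.max() * 1e-12)
    # noise gate: a tonal/harmonic structure shows a spectral peak far
    # above the median in-band density; broadband noise does not
    if in_band.max() < min_peak_ratio * floor:
        raise UndefinedF0Error(
            f"in-band peak {in_band.max():.3g} below {min_peak_ratio} x "
            f"median density {floor:.3g}: no harmonic structure")
    candidates = np.arange(search[0], search[1] + resolution, resolution)
    if candidates.size == 0:
        raise ValueError(f"empty search range {search}")
    k = np.arange(1, n_harmonics + 1)
    teeth = candidates[:, None] * k[None, :]          # candidates x teeth
    # 1/k weighting: a candidate scoring only through high-order teeth
    # (a deep sub-harmonic of a wide modulated band) cannot beat the true
    # fundamental, whose first tooth carries full weight
    weights = (teeth <= spec.band[1]).astype(float) / k[None, :]
    logp = np.log1p(np.interp(teeth, f, p, right=0.0) / floor)
    scores = (logp * weights).sum(axis=1) / np.maximum(weights.sum(axis=1),
                                                       1e-9)
    # a candidate must itself carry energy: rejects sub-harmonics that only
    # score through their higher teeth
    fundamental_power = np.interp(candidates, f, p)
    scores[fundamental_power < 2.0 * floor] = -np.inf
    if not np.isfinite(scores).any():
        raise UndefinedF0Error("no candidate fundamental above the noise "
                               "floor")
    # sub-harmonics of a sparse stack tie with the true fundamental on the
    # comb score; among near-ties prefer the candidate carrying the most
    # power itself
    smax = scores.max()
    tied = np.flatnonzero(scores >= 0.95 * smax)
    best = int(tied[np.argmax(fundamental_power[tied])])
    # parabolic refinement on the comb score surface
    return _parabolic_peak(candidates, scores, best)


def track_fundamental(segment: AudioSegment, init_search: tuple[float, float],
                      fft_size: int | None = None, overlap: float = 0.75,
                      max_jump: float = 0.30) -> tuple[np.ndarray, np.ndarray]:
    """Frame-by-frame track of the lowest visible frequency band.

    The first frame picks the spectral peak inside ``init_search``;
    subsequent frames are constrained to ``±max_jump`` relative to the
    previous frame (contour continuity).  Frames more than 25 dB below the
    strongest frame are dropped.  Returns ``(times, freqs)``.
    """
    if fft_size is None:
        # window short enough to resolve the modulation in time: at most
        # an eighth of the call, within [256, 1024] points
        fft_size = int(2 ** np.clip(np.floor(np.log2(len(segment) / 8)),
                                    8, 10))
    fft_size = min(fft_size, len(segment))
    hop = max(int(round(fft_size * (1 - overlap))), 1)
    f, t, sxx = signal.spectrogram(
        segment.samples, fs=segment.rate,
        window=signal.get_window("hamming", fft_size), nperseg=fft_size,
        noverlap=fft_size - hop, nfft=4 * fft_size, detrend=False,
        scaling="density", mode="psd")
    frame_energy = sxx.sum(axis=0)
    keep = frame_energy >= frame_energy.max() * 10 ** (-25 / 10)
    times, freqs = [], []
    prev = None
    for j in range(sxx.shape[1]):
        if not keep[j]:
            continue
        if prev is None:
            lo, hi = init_search
        else:
            lo, hi = prev * (1 - max_jump), prev * (1 + max_jump)
        mask = (f >= lo) & (f <= hi)
        if not mask.any():
            continue
        col = np.where(mask, sxx[:, j], 0.0)
        top = col.max()
        if top <= 0:
            continue
        # the track follows the first visible (lowest) band, not the
        # strongest one: take the lowest prominent in-window peak
        peaks, _ = signal.find_peaks(col, height=0.05 * top,
                                     prominence=0.05 * top)
        idx = int(peaks[0]) if peaks.size else int(np.argmax(col))
        freq = _parabolic_peak(f, sxx[:, j], idx)
        prev = freq
        times.append(t[j])
        freqs.append(freq)
    return np.asarray(times), np.asarray(freqs)


def estimate_f0(segment: AudioSegment, band: tuple[float, float],
                search: tuple[float, float], n_harmonics: int = 6,
                resolution: float = 0.5, min_peak_ratio: float = 4.0) -> float:
    """Fundamental frequency of a harmonic call.

    A harmonic-comb score over the average spectrum locates the stack; the
    estimate is then refined to the midrange of the fundamental track,
    which is insensitive to frequency modulation within the call.  Raises
    :class:`UndefinedF0Error` when no comb beats the noise floor.
    """
    nper = min(4096, len(segment))
    spec = average_spectrum(segment, band=band, fft_size=nper,
                            nfft=4 * nper)
    coarse = _comb_estimate(spec, search, n_harmonics, resolution,
                            min_peak_ratio)
    times, track = track_fundamental(
        segment, (max(coarse * 0.45, band[0]), coarse * 1.7))
    if track.size >= 5:
        smooth = signal.medfilt(track, 3)
        return float((smooth.max() + smooth.min()) / 2.0)
    return float(coarse)


def excursion_frequency(segment: AudioSegment,
                        f0_track: np.ndarray | None = None,
                        search: tuple[float, float] | None = None) -> float:
    """Frequency excursion: max - min of the fundamental track.

    Either pass a precomputed ``f0_track`` or a ``search`` range from which
    the track is computed.  Requires at least 3 tracked frames.
    """
    if f0_track is None:
        if search is None:
            raise ValueError("need either f0_track or search")
        _, f0_track = track_fundamental(segment, search)
    f0_track = np.asarray(f0_track, dtype=float)
    if f0_track.size < 3:
        raise TrackTooShortError(
            f"track has {f0_track.size} frames; need at least 3")
    if f0_track.size >= 5:
        f0_track = signal.medfilt(f0_track, 3)
    return float(f0_track.max() - f0_track.min())


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def extract_features(segment: CallSegment, fft_size: int = 4096
                     ) -> FeatureVector:
    """Measure the per-category variable set of a good-quality call.

    harmonic -> dur, f0, excF (when trackable), Fmax and quartiles;
    noisy -> dur, Fmax, quartiles; pulsative -> dur, PR plus Fmax/quartiles
    where defined for the type.  Degraded/overlapped segments and
    non-measurable types are refused.
    """
    ct = segment.call_type
    if not ct.measurable:
        raise NotMeasurableError(f"call type {ct.name!r} is too faint to "
                                 "be measured")
    if segment.quality != "good":
        raise NotMeasurableError(f"quality {segment.quality!r}: only "
                                 "good-quality calls are measured")
    clip = segment.clip()
    band = ct.analysis_band
    fv = FeatureVector(dur=measure_duration(clip))

    if ct.category == "harmonic":
        fv.f0 = estimate_f0(clip, band, ct.f0_search)
        try:
            _, track = track_fundamental(
                clip, (max(fv.f0 * 0.45, band[0]), fv.f0 * 1.7))
            fv.excF = excursion_frequency(clip, f0_track=track)
        except TrackTooShortError:
            fv.excF = None
        nper = min(fft_size, len(clip))
        spec = average_spectrum(clip, band=band, fft_size=nper)
        fv.Fmax, fv.Q25, fv.Q50, fv.Q75 = peak_and_quartiles(spec)
    elif ct.category == "noisy":
        nper = min(fft_size, len(clip))
        spec = average_spectrum(clip, band=band, fft_size=nper)
        fv.Fmax, fv.Q25, fv.Q50, fv.Q75 = peak_and_quartiles(spec)
    else:  # pulsative
        fv.PR = pulse_rate(clip, mode=ct.pulse_mode)
        if "Fmax" in ct.stats:
            nper = min(fft_size, len(clip))
            spec = average_spectrum(clip, band=band, fft_size=nper)
            fmax, q25, q50, q75 = peak_and_quartiles(spec)
            fv.Fmax = fmax
            if "Q25" in ct.stats:
                fv.Q25, fv.Q50, fv.Q75 = q25, q50, q75
    return fv
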