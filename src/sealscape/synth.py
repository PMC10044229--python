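"""Synthetic call and soundscape generation.

Generates waveforms whose measurable structure (durations, fundamental
contours, spectral energy quartiles, pulse rates) matches the per-type
statistics in :mod:`sealscape.repertoire`, together with ground-truth
records, label tracks, and directly sampled feature tables.  Everything is
deterministic for a fixed seed.

Synthesis conventions (not field facts):

* harmonic amplitude roll-off is -6 dB/harmonic by default, with the
  harmonic nearest the sampled spectral peak boosted so it dominates the
  average spectrum;
* the fundamental contour is one smooth sine cycle spanning the sampled
  excursion, so the contour mean equals the sampled fundamental and both
  contour extremes lie inside the call;
* noisy calls are random-phase noise with a deterministic spectral envelope
  (four equal-energy segments pinned to the quartile targets plus a narrow
  peak at the Fmax target);
* calls are tapered with 5 ms raised-cosine edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfftfreq
from scipy import signal, stats

from .audio import AudioSegment
from .labels import LabelEvent
from .repertoire import CALL_TYPES, CallType, VARIABLES, get_call_type

__all__ = [
    "SynthesisError",
    "SynthesisSpec",
    "SoundscapeMix",
    "GroundTruth",
    "synth_harmonic_call",
    "synth_noisy_call",
    "synth_pulsative_call",
    "synth_call",
    "synth_soundscape",
    "sample_feature_table",
    "truncated_normal",
]

DEFAULT_RATE = 22050.0
EDGE_TAPER = 0.005  # s, raised-cosine fade at call edges
PULSE_DUR = 0.010   # s, discrete pulse unit length


class SynthesisError(ValueError):
    """Unsatisfiable synthesis request (Nyquist violation, empty band, ...)."""


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=512)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter whose truncated-normal mean equals ``mean``."""
    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean
    from scipy.optimize import brentq
    return brentq(gap, mean - 6 * sd, mean + 6 * sd, xtol=1e-9 * max(1.0, sd))


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     lo: float | None = None, hi: float | None = None,
                     size: int | None = None) -> np.ndarray | float:
    """Truncated-normal samples whose *expected value equals* ``mean``.

    Bounds default to ``mean ± 3 sd`` (with ``lo`` floored at the given
    value).  When truncation is asymmetric, the underlying location is
    shifted so the truncated mean still matches the requested mean; this
    keeps large-sample feature-table means on target.
    """
    lo_eff = mean - 3.0 * sd if lo is None else max(lo, mean - 3.0 * sd)
    hi_eff = mean + 3.0 * sd if hi is None else min(hi, mean + 3.0 * sd)
    if sd == 0:
        if not lo_eff <= mean <= hi_eff:
            raise SynthesisError(f"mean {mean} outside bounds "
                                 f"[{lo_eff}, {hi_eff}]")
        return np.full(size, float(mean)) if size is not None else float(mean)
    if not lo_eff < hi_eff:
        raise SynthesisError(f"empty truncation interval [{lo_eff}, {hi_eff}]")
    if not lo_eff < mean < hi_eff:
        raise SynthesisError(f"target mean {mean} not attainable in "
                             f"[{lo_eff}, {hi_eff}]")
    mu = _matched_loc(round(mean, 9), round(sd, 9),
                      round(lo_eff, 9), round(hi_eff, 9))
    a, b = (lo_eff - mu) / sd, (hi_eff - mu) / sd
    out = stats.truncnorm.rvs(a, b, loc=mu, scale=sd,
                              size=size or 1, random_state=rng)
    return out if size is not None else float(out[0])


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SynthesisSpec:
    """Per-call-type generative parameters.

    Means/SDs mirror the repertoire statistics; a zero SD pins a parameter
    at its mean.  ``spectral_band`` gives flat-band shaping for noisy calls
    without quartile targets.
    """

    call_type: str
    category: str
    dur_mean: float
    dur_sd: float = 0.0
    f0_mean: float | None = None
    f0_sd: float = 0.0
    excF_mean: float = 0.0
    excF_sd: float = 0.0
    n_harmonics: int = 1
    fmax_mean: float | None = None
    fmax_sd: float = 0.0
    quartiles_mean: tuple[float, float, float] | None = None
    quartiles_sd: tuple[float, float, float] | None = None
    spectral_band: tuple[float, float] | None = None
    pr_mean: float | None = None
    pr_sd: float = 0.0
    pulse_mode: str = "discrete"
    amplitude: float = 0.3
    min_duration: float = 0.05
    analysis_band: tuple[float, float] = (20.0, 1000.0)
    rolloff_db: float = 6.0

    def __post_init__(self) -> None:
        if self.category not in ("harmonic", "noisy", "pulsative"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.dur_mean <= 0 or self.dur_sd < 0:
            raise ValueError("dur_mean must be > 0, dur_sd >= 0")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be > 0")
        if self.category == "harmonic":
            if self.f0_mean is None or self.f0_mean <= 0:
                raise ValueError("harmonic spec needs f0_mean > 0")
            if self.n_harmonics < 1:
                raise ValueError("n_harmonics must be >= 1")
        if self.category == "pulsative":
            if self.pr_mean is None or self.pr_mean <= 0:
                raise SynthesisError("pulsative spec needs pr_mean > 0")
            if self.pulse_mode not in ("discrete", "am"):
                raise ValueError(f"bad pulse_mode {self.pulse_mode!r}")
        if not 0 < self.amplitude <= 1.0:
            raise ValueError("amplitude must be in (0, 1]")

    @classmethod
    def from_call_type(cls, call_type: str | CallType,
                       **overrides) -> "SynthesisSpec":
        """Build a spec from the registry statistics of a call type."""
        ct = (call_type if isinstance(call_type, CallType)
              else get_call_type(call_type))
        if not ct.measurable:
            # faint type: synthesize as a quiet low-pitched harmonic call
            kw = dict(call_type=ct.name, category="harmonic", dur_mean=0.5,
                      dur_sd=0.2, f0_mean=90.0, f0_sd=25.0, excF_mean=20.0,
                      n_harmonics=3, amplitude=0.01,
                      analysis_band=ct.analysis_band)
        else:
            kw = dict(call_type=ct.name, category=ct.category,
                      analysis_band=ct.analysis_band)
            kw["dur_mean"], kw["dur_sd"] = ct.stats["dur"]
            if "f0" in ct.stats:
                kw["f0_mean"], kw["f0_sd"] = ct.stats["f0"]
            if "excF" in ct.stats:
                kw["excF_mean"], kw["excF_sd"] = ct.stats["excF"]
            if "Fmax" in ct.stats:
                kw["fmax_mean"], kw["fmax_sd"] = ct.stats["Fmax"]
            if "Q25" in ct.stats:
                kw["quartiles_mean"] = tuple(ct.stats[q][0]
                                             for q in ("Q25", "Q50", "Q75"))
                kw["quartiles_sd"] = tuple(ct.stats[q][1]
                                           for q in ("Q25", "Q50", "Q75"))
            if "PR" in ct.stats:
                kw["pr_mean"], kw["pr_sd"] = ct.stats["PR"]
            kw["n_harmonics"] = ct.n_harmonics
            kw["pulse_mode"] = ct.pulse_mode
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Realized parameters of one synthesized call."""

    call_type: str
    category: str
    dur: float
    f0: float | None = None
    excF: float | None = None
    Fmax: float | None = None
    Q25: float | None = None
    Q50: float | None = None
    Q75: float | None = None
    PR: float | None = None

    def as_dict(self) -> dict:
        return {"call_type": self.call_type, "category": self.category,
                **{v: getattr(self, v if v != "dur" else "dur")
                   for v in VARIABLES}}


# ---------------------------------------------------------------------------
# waveform building blocks
# ---------------------------------------------------------------------------

def _taper(x: np.ndarray, rate: float, edge: float = EDGE_TAPER) -> np.ndarray:
    n_edge = min(int(round(edge * rate)), x.size // 2)
    if n_edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        x[:n_edge] *= ramp
        x[-n_edge:] *= ramp[::-1]
    return x


def _random_phase_noise(n: int, rate: float, density: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Noise with a deterministic magnitude spectrum and random phases."""
    mag = np.sqrt(np.maximum(density, 0.0))
    phases = rng.uniform(0.0, 2.0 * np.pi, mag.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    x = irfft(mag * np.exp(1j * phases), n=n)
    return x


def _shape_density(freqs: np.ndarray,
                   quartiles: tuple[float, float, float] | None,
                   fmax: float | None,
                   band: tuple[float, float]) -> np.ndarray:
    """Spectral envelope: equal-energy quartile segments + Fmax peak."""
    lo, hi = band
    if hi <= lo:
        raise SynthesisError(f"empty spectral band {band}")
    density = np.zeros_like(freqs)
    if quartiles is not None:
        q25, q50, q75 = quartiles
        if not 0 < q25 <= q50 <= q75:
            raise SynthesisError(f"bad quartile targets {quartiles}")
        e0 = max(lo, q25 - max(q50 - q25, 10.0))
        e4 = min(hi, q75 + max(q75 - q50, 10.0))
        edges = [min(e0, q25 - 5.0), q25, q50, q75, max(e4, q75 + 5.0)]
        for a, b in zip(edges[:-1], edges[1:]):
            seg = (freqs >= a) & (freqs < b)
            if seg.any():
                density[seg] = 0.25 / (b - a)
    else:
        seg = (freqs >= lo) & (freqs <= hi)
        if not seg.any():
            raise SynthesisError(f"band {band} contains no FFT bins")
        density[seg] = 1.0 / (hi - lo)
    if fmax is not None:
        sigma = 8.0 if quartiles is not None else max(0.02 * fmax, 20.0)
        base = density.max() if density.max() > 0 else 1.0 / (hi - lo)
        bump = 1.6 * base * np.exp(-0.5 * ((freqs - fmax) / sigma) ** 2)
        density = density + bump
    density[(freqs < lo) | (freqs > hi)] = 0.0
    return density


def _spectrum_quartiles(x: np.ndarray, rate: float,
                        band: tuple[float, float]) -> tuple[float, float, float]:
    """Realized energy quartiles by direct cumulative summation."""
    f, p = signal.periodogram(x, fs=rate, detrend=False)
    mask = (f >= band[0]) & (f <= band[1])
    p = np.where(mask, p, 0.0)
    total = p.sum()
    if total <= 0:
        raise SynthesisError("zero in-band energy")
    cum = np.cumsum(p) / total
    return tuple(float(f[np.searchsorted(cum, q)])
                 for q in (0.25, 0.50, 0.75))


def _spectrum_peak(x: np.ndarray, rate: float,
                   band: tuple[float, float]) -> float:
    """Realized in-band spectral peak of the synthesized waveform."""
    f, p = signal.periodogram(x, fs=rate, detrend=False)
    p = np.where((f >= band[0]) & (f <= band[1]), p, 0.0)
    if p.max() <= 0:
        raise SynthesisError("zero in-band energy")
    return float(f[np.argmax(p)])


# ---------------------------------------------------------------------------
# per-category synthesis
# ---------------------------------------------------------------------------

def synth_harmonic_call(spec: SynthesisSpec, seed: int,
                        rate: float = DEFAULT_RATE
                        ) -> tuple[AudioSegment, GroundTruth]:
    """Sum of harmonics of a slowly modulated fundamental.

    The contour is a raised-cosine arch spanning the sampled excursion, so
    its time mean equals the sampled fundamental.  The harmonic nearest the
    sampled Fmax target is boosted to dominate the average spectrum.
    """
    if spec.category != "harmonic":
        raise ValueError(f"spec category {spec.category!r} != 'harmonic'")
    rng = np.random.default_rng(seed)
    dur = truncated_normal(rng, spec.dur_mean, spec.dur_sd,
                           lo=spec.min_duration)
    f0 = truncated_normal(rng, spec.f0_mean, spec.f0_sd, lo=26.0,
                          hi=spec.analysis_band[1] * 0.96)
    excF = truncated_normal(rng, spec.excF_mean, spec.excF_sd, lo=0.0) \
        if spec.excF_mean > 0 else 0.0
    # keep the contour bottom above 20 Hz
    excF = min(excF, 1.5 * (f0 - 22.0)) if excF > 0 else 0.0
    nyq = rate / 2.0
    f_top = (f0 + excF / 2.0) * spec.n_harmonics
    if f_top >= nyq:
        raise SynthesisError(
            f"harmonic {spec.n_harmonics} at {f_top:.0f} Hz exceeds the "
            f"Nyquist frequency {nyq:.0f} Hz")

    if spec.fmax_mean is not None:
        fmax_target = truncated_normal(rng, spec.fmax_mean, spec.fmax_sd,
                                       lo=spec.analysis_band[0] + 10.0,
                                       hi=spec.analysis_band[1])
        k_star = int(np.clip(round(fmax_target / f0), 1, spec.n_harmonics))
    else:
        k_star = 1

    n = max(int(round(dur * rate)), 16)
    t = np.arange(n) / rate
    # one full sine cycle: both contour extremes lie in the call interior
    # (an arch pins the minimum to the tapered call edges, where windowed
    # spectral averages underweight it), and the contour mean equals f0
    contour = f0 + 0.5 * excF * np.sin(2.0 * np.pi * t / dur)
    phase = 2.0 * np.pi * np.cumsum(contour) / rate
    phase0 = rng.uniform(0, 2 * np.pi, spec.n_harmonics)

    amps = 10.0 ** (-spec.rolloff_db * np.arange(spec.n_harmonics) / 20.0)
    if spec.n_harmonics > 1:
        # boost so the chosen harmonic dominates the *density*, which for a
        # modulated fundamental falls off faster than the amplitudes
        spread = np.maximum(np.arange(1, spec.n_harmonics + 1) * max(excF, 1.0),
                            1.0)
        dens = amps ** 2 / spread
        amps[k_star - 1] = math.sqrt(2.0 * dens.max() * spread[k_star - 1])
    x = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        x += amps[k - 1] * np.sin(k * phase + phase0[k - 1])
    x *= spec.amplitude / np.max(np.abs(x))
    x = _taper(x, rate)

    gt = GroundTruth(spec.call_type, "harmonic", dur=n / rate, f0=f0,
                     excF=excF,
                     Fmax=_spectrum_peak(x, rate, spec.analysis_band))
    if spec.quartiles_mean is not None or spec.n_harmonics > 1:
        gt.Q25, gt.Q50, gt.Q75 = _spectrum_quartiles(x, rate,
                                                     spec.analysis_band)
    return AudioSegment(x, rate), gt


def synth_noisy_call(spec: SynthesisSpec, seed: int,
                     rate: float = DEFAULT_RATE
                     ) -> tuple[AudioSegment, GroundTruth]:
    """Band-shaped noise burst approaching the quartile/Fmax targets."""
    if spec.category != "noisy":
        raise ValueError(f"spec category {spec.category!r} != 'noisy'")
    rng = np.random.default_rng(seed)
    dur = truncated_normal(rng, spec.dur_mean, spec.dur_sd,
                           lo=spec.min_duration)
    band = spec.spectral_band or spec.analysis_band
    if band[1] > rate / 2.0:
        raise SynthesisError(f"band {band} exceeds Nyquist {rate / 2} Hz")
    quartiles = None
    if spec.quartiles_mean is not None:
        qs = [truncated_normal(rng, m, s, lo=band[0] + 10.0, hi=band[1])
              for m, s in zip(spec.quartiles_mean, spec.quartiles_sd)]
        quartiles = tuple(sorted(qs))
    fmax = None
    if spec.fmax_mean is not None:
        fmax = truncated_normal(rng, spec.fmax_mean, spec.fmax_sd,
                                lo=band[0] + 15.0, hi=band[1] - 15.0)
    n = max(int(round(dur * rate)), 32)
    freqs = rfftfreq(n, 1.0 / rate)
    density = _shape_density(freqs, quartiles, fmax, band)
    x = _random_phase_noise(n, rate, density, rng)
    x *= spec.amplitude / np.max(np.abs(x))
    x = _taper(x, rate)
    q25, q50, q75 = _spectrum_quartiles(x, rate, spec.analysis_band)
    gt = GroundTruth(spec.call_type, "noisy", dur=n / rate,
                     Fmax=_spectrum_peak(x, rate, spec.analysis_band)
                     if fmax is not None else None,
                     Q25=q25, Q50=q50, Q75=q75)
    return AudioSegment(x, rate), gt


def synth_pulsative_call(spec: SynthesisSpec, seed: int,
                         rate: float = DEFAULT_RATE
                         ) -> tuple[AudioSegment, GroundTruth]:
    """Discrete broadband pulse train or AM-modulated noise.

    ``discrete`` mode places identical band-shaped clicks at exactly
    ``1/PR`` spacing (realized duration spans first to last click);
    ``am`` mode multiplies a shaped-noise carrier by a full-depth
    raised-cosine envelope at the pulse rate.
    """
    if spec.category != "pulsative":
        raise ValueError(f"spec category {spec.category!r} != 'pulsative'")
    rng = np.random.default_rng(seed)
    pr = truncated_normal(rng, spec.pr_mean, spec.pr_sd,
                          lo=max(0.2, spec.pr_mean - 3 * spec.pr_sd))
    if pr <= 0:
        raise SynthesisError("pulse rate must be > 0")
    dur = truncated_normal(rng, spec.dur_mean, spec.dur_sd,
                           lo=max(spec.min_duration, 2.2 / pr))
    band = spec.spectral_band or spec.analysis_band
    fmax = None
    if spec.fmax_mean is not None:
        fmax = truncated_normal(rng, spec.fmax_mean, spec.fmax_sd,
                                lo=band[0] + 15.0, hi=band[1] - 15.0)

    if spec.pulse_mode == "discrete":
        n_pulses = int(math.floor(pr * dur)) + 1
        if n_pulses < 2:
            raise SynthesisError(
                f"fewer than 2 pulses representable (PR={pr:.3g}/s over "
                f"{dur:.3g} s)")
        kn = max(int(round(PULSE_DUR * rate)), 8)
        kfreqs = rfftfreq(kn, 1.0 / rate)
        kband = (max(band[0], 100.0), band[1])
        density = _shape_density(kfreqs, None, fmax, kband)
        kernel = _random_phase_noise(kn, rate, density, rng)
        kernel *= signal.windows.hann(kn)
        span = (n_pulses - 1) / pr
        n = int(round(span * rate)) + kn
        x = np.zeros(n)
        for i in range(n_pulses):
            i0 = int(round(i / pr * rate))
            x[i0:i0 + kn] += kernel
        realized_dur = span + kn / rate
        pr_realized = pr
    else:  # am
        if pr * dur < 2.0:
            raise SynthesisError(
                f"fewer than 2 modulation cycles (PR={pr:.3g} Hz over "
                f"{dur:.3g} s)")
        n = max(int(round(dur * rate)), 32)
        freqs = rfftfreq(n, 1.0 / rate)
        quartiles = None
        if spec.quartiles_mean is not None:
            qs = [truncated_normal(rng, m, s, lo=band[0] + 10.0, hi=band[1])
                  for m, s in zip(spec.quartiles_mean, spec.quartiles_sd)]
            quartiles = tuple(sorted(qs))
        density = _shape_density(freqs, quartiles, fmax, band)
        carrier = _random_phase_noise(n, rate, density, rng)
        t = np.arange(n) / rate
        x = carrier * 0.5 * (1.0 - np.cos(2.0 * np.pi * pr * t))
        realized_dur = n / rate
        pr_realized = pr

    x *= spec.amplitude / np.max(np.abs(x))
    x = _taper(x, rate)
    gt = GroundTruth(spec.call_type, "pulsative", dur=realized_dur,
                     Fmax=_spectrum_peak(x, rate, spec.analysis_band)
                     if fmax is not None else None,
                     PR=pr_realized)
    if spec.pulse_mode == "am" and spec.quartiles_mean is not None:
        gt.Q25, gt.Q50, gt.Q75 = _spectrum_quartiles(x, rate,
                                                     spec.analysis_band)
    return AudioSegment(x, rate), gt


_SYNTHESIZERS = {
    "harmonic": synth_harmonic_call,
    "noisy": synth_noisy_call,
    "pulsative": synth_pulsative_call,
}


def synth_call(spec: SynthesisSpec, seed: int, rate: float = DEFAULT_RATE
               ) -> tuple[AudioSegment, GroundTruth]:
    """Dispatch to the category-specific synthesizer."""
    return _SYNTHESIZERS[spec.category](spec, seed, rate)


# ---------------------------------------------------------------------------
# soundscape mixing
# ---------------------------------------------------------------------------

@dataclass
class SoundscapeMix:
    """Background components of a synthetic soundscape.

    Component gains are linear RMS amplitudes on the full-scale axis
    (0 disables a component).  ``boat_events`` restricts boat noise to the
    given ``(start, end)`` intervals; ``None`` means continuous.
    """

    shrimp_band: tuple[float, float] = (1500.0, 5500.0)
    shrimp_snap_rate: float = 60.0
    shrimp_gain: float = 0.0
    boat_band: tuple[float, float] = (20.0, 200.0)
    boat_tonal_lines: tuple[float, ...] = ()
    boat_gain: float = 0.0
    boat_events: list[tuple[float, float]] | None = None
    flow_cutoff: float = 30.0
    flow_gain: float = 0.0

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        for name, band in (("shrimp", self.shrimp_band),
                           ("boat", self.boat_band)):
            if not 0 < band[0] < band[1] < nyq:
                raise SynthesisError(f"{name} band {band} outside (0, {nyq})")
        if not 0 < self.flow_cutoff < nyq:
            raise SynthesisError(f"flow cutoff {self.flow_cutoff} outside "
                                 f"(0, {nyq})")
        for g in (self.shrimp_gain, self.boat_gain, self.flow_gain):
            if not np.isfinite(g) or g < 0:
                raise SynthesisError(f"bad component gain {g}")


def _set_rms(x: np.ndarray, target: float) -> np.ndarray:
    rms = float(np.sqrt(np.mean(x ** 2)))
    return x * (target / rms) if rms > 0 else x


def synth_soundscape(mix: SoundscapeMix,
                     calls: list[tuple[float, SynthesisSpec]],
                     duration: float, seed: int,
                     rate: float = DEFAULT_RATE, call_gain: float = 1.0
                     ) -> tuple[AudioSegment, list[LabelEvent],
                                list[GroundTruth]]:
    """Additively mix background components and placed calls.

    Returns the mixed segment, a label track (one row per inserted call and
    per boat-noise interval) and the per-call ground truth.  Calls whose
    waveform would extend past ``duration`` are truncated at the file end;
    start times outside ``[0, duration)`` raise.
    """
    if duration < 0:
        raise SynthesisError("negative duration")
    mix.validate(rate)
    n = int(round(duration * rate))
    out = np.zeros(max(n, 1))
    rng = np.random.default_rng(seed)
    events: list[LabelEvent] = []

    if mix.shrimp_gain > 0 and n > 0:
        n_snaps = rng.poisson(mix.shrimp_snap_rate * duration)
        impulses = np.zeros(n)
        if n_snaps > 0:
            idx = rng.integers(0, n, n_snaps)
            np.add.at(impulses, idx, rng.lognormal(0.0, 0.5, n_snaps))
        taps = signal.firwin(513, mix.shrimp_band, fs=rate, pass_zero=False)
        shrimp = signal.fftconvolve(impulses, taps, mode="same")
        out += _set_rms(shrimp, mix.shrimp_gain)

    if mix.boat_gain > 0 and n > 0:
        freqs = rfftfreq(n, 1.0 / rate)
        density = np.zeros_like(freqs)
        bmask = (freqs >= mix.boat_band[0]) & (freqs <= mix.boat_band[1])
        density[bmask] = 1.0
        boat = _random_phase_noise(n, rate, density, rng)
        t = np.arange(n) / rate
        for line in mix.boat_tonal_lines:
            boat += 0.7 * np.std(boat) * np.sin(2 * np.pi * line * t
                                                + rng.uniform(0, 2 * np.pi))
        boat = _set_rms(boat, mix.boat_gain)
        intervals = mix.boat_events or [(0.0, duration)]
        gate = np.zeros(n)
        for start, end in intervals:
            i0, i1 = int(round(start * rate)), int(round(end * rate))
            gate[max(i0, 0):min(i1, n)] = 1.0
            events.append(LabelEvent(max(start, 0.0), min(end, duration),
                                     "boat"))
        out += boat * gate

    if mix.flow_gain > 0 and n > 0:
        freqs = rfftfreq(n, 1.0 / rate)
        density = np.where((freqs > 0) & (freqs < mix.flow_cutoff), 1.0, 0.0)
        out += _set_rms(_random_phase_noise(n, rate, density, rng),
                        mix.flow_gain)

    truths: list[GroundTruth] = []
    seeds = np.random.SeedSequence(seed).spawn(len(calls))
    for (start, spec), sub in zip(calls, seeds):
        if not 0.0 <= start < duration:
            raise SynthesisError(f"call placement {start} s outside "
                                 f"[0, {duration})")
        seg, gt = synth_call(spec, int(sub.generate_state(1)[0]), rate)
        wav = seg.samples * call_gain
        i0 = int(round(start * rate))
        avail = min(wav.size, n - i0)
        out[i0:i0 + avail] += wav[:avail]
        end = start + avail / rate
        events.append(LabelEvent(start, end, spec.call_type))
        truths.append(gt)

    events.sort(key=lambda e: (e.start, e.end, e.label))
    return AudioSegment(out, rate), events, truths


# ---------------------------------------------------------------------------
# direct feature-table sampling
# ---------------------------------------------------------------------------

def sample_feature_table(category: str | None = None,
                         n_per_type: dict[str, int] | None = None,
                         seed: int = 0,
                         override_stats: dict[str, dict[str, tuple[float, float]]]
                         | None = None) -> pd.DataFrame:
    """Sample a labeled feature table from the per-type statistics.

    Variables are drawn independently (truncated normal, mean-matched) per
    type; the column set follows the category availability masks, with NaN
    for unavailable variables.  Single-band harmonic types get quartiles
    tied to their sampled fundamental so the harmonic RF variable set is
    complete.  Sample sizes default to the registry values;
    ``override_stats`` maps type name -> {variable -> (mean, sd)} to
    replace registry statistics (an SD of 0 pins a variable, making all
    rows of a type identical in it).
    """
    rng = np.random.default_rng(seed)
    if n_per_type is None:
        names = [t.name for t in CALL_TYPES.values()
                 if t.measurable and (category is None
                                      or t.category == category)]
        n_per_type = {name: CALL_TYPES[name].n for name in names}
    rows = []
    for name, n in n_per_type.items():
        ct = get_call_type(name)
        if not ct.measurable:
            raise ValueError(f"call type {name!r} is not measurable")
        if n < 1:
            raise ValueError(f"n_per_type[{name!r}] must be >= 1")
        cols: dict[str, np.ndarray] = {}
        for var in VARIABLES:
            st = (override_stats or {}).get(name, {}).get(var,
                                                           ct.stat(var))
            if st is None:
                cols[var] = np.full(n, np.nan)
            else:
                mean, sd = st
                if var == "dur":
                    lo = (2.2 / ct.stats["PR"][0]
                          if ct.category == "pulsative" else 0.05)
                else:
                    lo = 1e-3
                cols[var] = np.asarray(truncated_normal(
                    rng, mean, sd, lo=lo, size=n))
        if ct.category == "harmonic" and ct.single_band:
            # energy concentrated at the fundamental: quartiles hug f0
            f0 = cols["f0"]
            q50 = f0 * rng.normal(1.0, 0.01, n)
            q25 = q50 * (1.0 - np.abs(rng.normal(0.02, 0.01, n)))
            q75 = q50 * (1.0 + np.abs(rng.normal(0.02, 0.01, n)))
            cols["Q25"], cols["Q50"], cols["Q75"] = q25, q50, q75
        for i in range(n):
            rows.append({"call_id": f"{name}_{i:04d}", "type": name,
                         "category": ct.category,
                         **{v: cols[v][i] for v in VARIABLES}})
    return pd.DataFrame(rows)
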