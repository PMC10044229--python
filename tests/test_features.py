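import numpy as np
import pytest

from sealscape.audio import AudioSegment
from sealscape.dsp import AverageSpectrum, average_spectrum
from sealscape.features import (CallSegment, NotMeasurableError,
                                SilentSegmentError, TrackTooShortError,
                                UndefinedF0Error, estimate_f0,
                                excursion_frequency, extract_features,
                                measure_duration, peak_and_quartiles,
                                pulse_rate, track_fundamental)
from sealscape.repertoire import CALL_TYPES
from sealscape.synth import SynthesisSpec, synth_call, synth_pulsative_call

from .oracles import count_pulses, cumsum_quartiles

RATE = 22050.0


def pinned_spec(name, **overrides):
    """Registry spec with all SDs zeroed (parameters pinned at means)."""
    spec = SynthesisSpec.from_call_type(name)
    for field in ("dur_sd", "f0_sd", "excF_sd", "fmax_sd", "pr_sd"):
        setattr(spec, field, 0.0)
    if spec.quartiles_sd is not None:
        spec.quartiles_sd = (0.0, 0.0, 0.0)
    for key, val in overrides.items():
        setattr(spec, key, val)
    return spec


class TestMeasureDuration:
    def test_rectangular_burst(self):
        x = np.zeros(int(RATE))
        x[int(0.25 * RATE):int(0.75 * RATE)] = np.sin(
            2 * np.pi * 300 * np.arange(int(0.5 * RATE)) / RATE)
        dur = measure_duration(AudioSegment(x, RATE))
        assert dur == pytest.approx(0.5, abs=0.02)  # one smoothing constant

    def test_clap_series_within_5pct(self):
        seg, gt = synth_call(pinned_spec("clap"), seed=0)
        assert measure_duration(seg) == pytest.approx(gt.dur, rel=0.05)

    def test_silence_rejected(self):
        with pytest.raises(SilentSegmentError):
            measure_duration(AudioSegment(np.zeros(int(RATE)), RATE))


class TestEstimateF0:
    def test_bark_stack_within_3pct(self):
        seg, gt = synth_call(pinned_spec("bark"), seed=1)
        est = estimate_f0(seg, (20, 1000), CALL_TYPES["bark"].f0_search)
        assert est == pytest.approx(137.0, rel=0.03)

    def test_scream_single_tone(self):
        seg, gt = synth_call(pinned_spec("scream"), seed=2)
        est = estimate_f0(seg, (20, 2000), (500, 2000))
        assert est == pytest.approx(1207.0, rel=0.03)

    def test_white_noise_undefined(self, rng):
        seg = AudioSegment(rng.standard_normal(int(RATE)), RATE)
        with pytest.raises(UndefinedF0Error):
            estimate_f0(seg, (20, 1000), (40, 400))


class TestExcursionFrequency:
    def test_unmodulated_tone_zero(self):
        t = np.arange(int(RATE)) / RATE
        seg = AudioSegment(np.sin(2 * np.pi * 200 * t), RATE)
        excF = excursion_frequency(seg, search=(100, 300))
        assert excF < 8.0  # frame resolution

    def test_synthesized_span_recovered(self):
        seg, gt = synth_call(pinned_spec("bark"), seed=3)
        excF = excursion_frequency(seg, search=(80, 220))
        assert excF == pytest.approx(45.0, abs=11.0)  # within frame resolution

    def test_linear_chirp_span(self):
        t = np.arange(int(2 * RATE)) / RATE
        phase = 2 * np.pi * (100 * t + 0.5 * 40 * t ** 2)  # 100 -> 180 Hz
        seg = AudioSegment(np.sin(phase), RATE)
        excF = excursion_frequency(seg, search=(60, 250))
        assert excF == pytest.approx(80.0, abs=12.0)

    def test_short_track_rejected(self):
        with pytest.raises(TrackTooShortError):
            excursion_frequency(AudioSegment(np.zeros(10), RATE),
                                f0_track=np.array([100.0, 101.0]))


class TestPeakAndQuartiles:
    def test_flat_spectrum_uniform(self):
        freqs = np.arange(0.0, 1001.0)
        spec = AverageSpectrum(freqs, np.ones_like(freqs), (0.0, 1000.0))
        fmax, q25, q50, q75 = peak_and_quartiles(spec)
        assert (q25, q50, q75) == (250.0, 500.0, 750.0)

    def test_single_bin_degenerate(self):
        freqs = np.arange(0.0, 1001.0)
        power = np.zeros_like(freqs)
        power[300] = 5.0
        spec = AverageSpectrum(freqs, power, (0.0, 1000.0))
        assert peak_and_quartiles(spec) == (300.0, 300.0, 300.0, 300.0)

    def test_matches_cumsum_oracle_bin_exact(self):
        seg, _ = synth_call(SynthesisSpec.from_call_type("hiccup"), seed=4)
        spec = average_spectrum(seg, band=(20, 1000),
                                fft_size=min(4096, len(seg)))
        _, q25, q50, q75 = peak_and_quartiles(spec)
        oracle = cumsum_quartiles(spec.freqs, spec.power, (20, 1000))
        assert (q25, q50, q75) == oracle

    def test_zero_energy_rejected(self):
        freqs = np.arange(0.0, 1001.0)
        spec = AverageSpectrum(freqs, np.zeros_like(freqs), (0.0, 1000.0))
        with pytest.raises(SilentSegmentError):
            peak_and_quartiles(spec)


class TestPulseRate:
    def test_clap_discrete_within_5pct(self):
        seg, gt = synth_call(pinned_spec("clap"), seed=5)
        assert pulse_rate(seg, mode="discrete") == pytest.approx(1.70,
                                                                 rel=0.05)

    def test_rumble_am_within_5pct(self):
        seg, gt = synth_call(pinned_spec("rumble"), seed=6)
        assert pulse_rate(seg, mode="am") == pytest.approx(16.31, rel=0.05)

    def test_single_impulse_rejected(self):
        x = np.zeros(int(RATE))
        x[5000:5100] = 1.0
        with pytest.raises(NotMeasurableError):
            pulse_rate(AudioSegment(x, RATE), mode="discrete")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            pulse_rate(AudioSegment(np.ones(1000), RATE), mode="wavelet")


class TestExtractFeatures:
    def test_bark_mask(self):
        seg, _ = synth_call(pinned_spec("bark"), seed=7)
        fv = extract_features(CallSegment(seg, 0, seg.duration, "bark"))
        for var in ("dur", "f0", "excF", "Fmax", "Q25", "Q50", "Q75"):
            assert getattr(fv, var) is not None, var
        assert fv.PR is None

    def test_clap_mask(self):
        seg, _ = synth_call(pinned_spec("clap"), seed=8)
        fv = extract_features(CallSegment(seg, 0, seg.duration, "clap"))
        assert fv.dur is not None and fv.PR is not None
        assert fv.Fmax is None and fv.Q50 is None and fv.f0 is None

    def test_degraded_quality_refused(self):
        seg, _ = synth_call(pinned_spec("bark"), seed=9)
        with pytest.raises(NotMeasurableError, match="quality"):
            extract_features(CallSegment(seg, 0, seg.duration, "bark",
                                         quality="degraded"))

    def test_moan_refused(self):
        seg, _ = synth_call(SynthesisSpec.from_call_type("moan"), seed=10)
        with pytest.raises(NotMeasurableError, match="faint"):
            extract_features(CallSegment(seg, 0, seg.duration, "moan"))


class TestProperties:
    @pytest.mark.parametrize("seed", range(12))
    def test_quartile_ordering_random_calls(self, seed, rng):
        name = ["bark", "growl", "hiccup", "squeak", "rumble", "wom"][seed % 6]
        seg, _ = synth_call(SynthesisSpec.from_call_type(name), seed=seed)
        fv = extract_features(CallSegment(seg, 0, seg.duration, name))
        if fv.Q25 is not None:
            assert fv.Q25 <= fv.Q50 <= fv.Q75

    def test_quartiles_equal_cumsum_oracle_100_instances(self, rng):
        for i in range(100):
            name = ("hiccup", "squeak", "growl")[i % 3]
            seg, _ = synth_call(SynthesisSpec.from_call_type(name),
                                seed=1000 + i)
            nper = min(4096, len(seg))
            band = CALL_TYPES[name].analysis_band
            spec = average_spectrum(seg, band=band, fft_size=nper)
            _, q25, q50, q75 = peak_and_quartiles(spec)
            assert (q25, q50, q75) == cumsum_quartiles(spec.freqs,
                                                       spec.power, band)

    def test_pulse_rate_vs_manual_count_100_instances(self):
        mismatches = 0
        for i in range(100):
            spec = SynthesisSpec(call_type="x", category="pulsative",
                                 dur_mean=2.0, dur_sd=0.5,
                                 pr_mean=5.0, pr_sd=1.5)
            seg, gt = synth_pulsative_call(spec, seed=2000 + i)
            n_manual = count_pulses(seg.samples, seg.rate)
            pr = pulse_rate(seg, mode="discrete")
            expected = (n_manual - 1) / ((n_manual - 1) / gt.PR)
            if abs(pr - gt.PR) > 0.05 * gt.PR:
                mismatches += 1
        assert mismatches == 0
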