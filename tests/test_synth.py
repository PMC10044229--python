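import numpy as np
import pytest

from sealscape.repertoire import CALL_TYPES
from sealscape.synth import (SoundscapeMix, SynthesisError, SynthesisSpec,
                             sample_feature_table, synth_call,
                             synth_harmonic_call, synth_noisy_call,
                             synth_pulsative_call, synth_soundscape,
                             truncated_normal)

from .oracles import (band_power_fraction, count_pulses, cumsum_quartiles,
                      envelope_fft_peak, fft_peak)


class TestHarmonic:
    def test_bark_harmonic_stack(self):
        spec = SynthesisSpec(call_type="x", category="harmonic",
                             dur_mean=0.418, f0_mean=137.0, excF_mean=45.0,
                             n_harmonics=3)
        seg, gt = synth_harmonic_call(spec, seed=0)
        assert gt.f0 == pytest.approx(137.0)
        assert gt.excF == pytest.approx(45.0)
        from scipy.signal import periodogram
        f, p = periodogram(seg.samples, fs=seg.rate, detrend=False)
        ref = p[(f >= 500) & (f <= 560)].sum()  # gap between harmonics
        for k, target in enumerate((137.0, 274.0, 411.0), start=1):
            lo, hi = target - 30, target + 30
            band = p[(f >= lo) & (f <= hi)].sum()
            assert band > 20 * ref, f"harmonic {k} missing"

    def test_pure_tone_when_unmodulated(self):
        spec = SynthesisSpec(call_type="x", category="harmonic",
                             dur_mean=0.5, f0_mean=200.0, excF_mean=0.0,
                             n_harmonics=1)
        seg, gt = synth_harmonic_call(spec, seed=1)
        assert gt.excF == 0.0
        assert abs(fft_peak(seg.samples, seg.rate) - 200.0) < 3.0

    def test_single_band_peak_oracle(self):
        spec = SynthesisSpec(call_type="x", category="harmonic",
                             dur_mean=0.408, f0_mean=1207.0, excF_mean=0.0,
                             n_harmonics=1, analysis_band=(20.0, 2000.0))
        seg, _ = synth_harmonic_call(spec, seed=2)
        assert abs(fft_peak(seg.samples, seg.rate) - 1207.0) < 5.0

    def test_nyquist_violation_names_harmonic(self):
        spec = SynthesisSpec(call_type="x", category="harmonic",
                             dur_mean=0.3, f0_mean=3000.0, n_harmonics=6,
                             analysis_band=(20.0, 8000.0))
        with pytest.raises(SynthesisError, match="harmonic 6"):
            synth_harmonic_call(spec, seed=0)

    def test_category_guard(self):
        spec = SynthesisSpec(call_type="x", category="noisy", dur_mean=0.2,
                             spectral_band=(100.0, 500.0))
        with pytest.raises(ValueError):
            synth_harmonic_call(spec, seed=0)


class TestNoisy:
    def test_flat_band_median(self):
        spec = SynthesisSpec(call_type="x", category="noisy", dur_mean=1.0,
                             spectral_band=(300.0, 700.0))
        seg, gt = synth_noisy_call(spec, seed=3)
        assert gt.Q50 == pytest.approx(500.0, abs=25.0)

    def test_hiccup_quartile_targets(self):
        spec = SynthesisSpec.from_call_type("hiccup")
        for f in ("dur_sd", "fmax_sd"):
            setattr(spec, f, 0.0)
        spec.quartiles_sd = (0.0, 0.0, 0.0)
        seg, gt = synth_noisy_call(spec, seed=4)
        assert gt.dur == pytest.approx(0.177, abs=0.01)
        for realized, target in zip((gt.Q25, gt.Q50, gt.Q75),
                                    (353.0, 422.0, 567.0)):
            assert realized == pytest.approx(target, rel=0.10)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            SynthesisSpec(call_type="x", category="noisy", dur_mean=0.0)

    def test_empty_band_rejected(self):
        spec = SynthesisSpec(call_type="x", category="noisy", dur_mean=0.2,
                             spectral_band=(500.0, 400.0))
        with pytest.raises(SynthesisError):
            synth_noisy_call(spec, seed=0)

    def test_ground_truth_matches_cumsum_oracle(self):
        from scipy.signal import periodogram
        spec = SynthesisSpec.from_call_type("squeak")
        seg, gt = synth_noisy_call(spec, seed=5)
        f, p = periodogram(seg.samples, fs=seg.rate, detrend=False)
        q = cumsum_quartiles(f, p, (20.0, 1000.0))
        assert (gt.Q25, gt.Q50, gt.Q75) == pytest.approx(q, abs=1.0)


class TestPulsative:
    def test_clap_pulse_count(self):
        spec = SynthesisSpec(call_type="x", category="pulsative",
                             dur_mean=5.103, pr_mean=1.70)
        seg, gt = synth_pulsative_call(spec, seed=6)
        assert gt.PR == pytest.approx(1.70)
        assert count_pulses(seg.samples, seg.rate) in (8, 9)

    def test_am_envelope_oracle(self):
        spec = SynthesisSpec(call_type="x", category="pulsative",
                             dur_mean=1.5, pr_mean=16.31, pulse_mode="am",
                             fmax_mean=205.0,
                             quartiles_mean=(215.0, 347.0, 571.0),
                             quartiles_sd=(0.0, 0.0, 0.0))
        seg, gt = synth_pulsative_call(spec, seed=7)
        assert abs(envelope_fft_peak(seg.samples, seg.rate) - 16.31) < 0.8

    def test_zero_rate_rejected(self):
        with pytest.raises(SynthesisError):
            SynthesisSpec(call_type="x", category="pulsative",
                          dur_mean=1.0, pr_mean=0.0)

    def test_too_few_pulses_rejected(self):
        spec = SynthesisSpec(call_type="x", category="pulsative",
                             dur_mean=2.0, pr_mean=0.3)
        with pytest.raises(SynthesisError):
            synth_pulsative_call(spec, seed=0)


class TestSoundscape:
    def test_silent_when_everything_off(self, tmp_path):
        seg, events, truths = synth_soundscape(SoundscapeMix(), [], 10.0,
                                               seed=0)
        assert np.all(seg.samples == 0.0)
        assert events == [] and truths == []

    def test_call_row_count(self):
        spec = SynthesisSpec.from_call_type("hiccup")
        calls = [(float(i), spec) for i in range(10)]
        _, events, truths = synth_soundscape(SoundscapeMix(), calls, 20.0,
                                             seed=1)
        assert len([e for e in events if e.label == "hiccup"]) == 10
        assert len(truths) == 10

    def test_shrimp_band_power(self):
        mix = SoundscapeMix(shrimp_gain=0.05)
        seg, _, _ = synth_soundscape(mix, [], 20.0, seed=2)
        assert band_power_fraction(seg.samples, seg.rate,
                                   (1500.0, 5500.0)) > 0.95

    def test_placement_beyond_duration_rejected(self):
        spec = SynthesisSpec.from_call_type("hiccup")
        with pytest.raises(SynthesisError, match="placement"):
            synth_soundscape(SoundscapeMix(), [(25.0, spec)], 20.0, seed=0)

    def test_boat_events_labeled(self):
        mix = SoundscapeMix(boat_gain=0.05, boat_events=[(2.0, 5.0),
                                                         (8.0, 9.0)])
        _, events, _ = synth_soundscape(mix, [], 10.0, seed=3)
        boat = [e for e in events if e.label == "boat"]
        assert [(e.start, e.end) for e in boat] == [(2.0, 5.0), (8.0, 9.0)]

    def test_seed_determinism_byte_identical(self, tmp_path):
        from sealscape.audio import write_wav
        mix = SoundscapeMix(shrimp_gain=0.02, boat_gain=0.03, flow_gain=0.01)
        calls = [(1.0, SynthesisSpec.from_call_type("bark"))]
        paths = []
        for name in ("a.wav", "b.wav"):
            seg, _, _ = synth_soundscape(mix, calls, 10.0, seed=99)
            write_wav(tmp_path / name, seg)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestTruncatedNormal:
    def test_mean_matched_despite_floor(self, rng):
        # heavy truncation (knock dur): naive truncation inflates the mean
        samples = truncated_normal(rng, 1.922, 1.828, lo=0.3, size=200_000)
        assert np.all(samples >= 0.3)
        assert np.mean(samples) == pytest.approx(1.922, abs=0.02)

    def test_sd_zero_pins_mean(self, rng):
        assert truncated_normal(rng, 5.0, 0.0) == 5.0

    def test_unattainable_mean_rejected(self, rng):
        with pytest.raises(SynthesisError):
            truncated_normal(rng, 1.0, 0.1, lo=2.0)


class TestSampleFeatureTable:
    def test_harmonic_row_total(self):
        table = sample_feature_table(category="harmonic", seed=0)
        assert len(table) == 739
        assert table["type"].nunique() == 11

    def test_sd_zero_override_identical_rows(self):
        table = sample_feature_table(
            n_per_type={"clap": 5}, seed=1,
            override_stats={"clap": {"dur": (5.103, 0.0), "PR": (1.70, 0.0)}})
        assert table["dur"].nunique() == 1 and table["PR"].nunique() == 1

    def test_same_seed_same_table(self):
        a = sample_feature_table(n_per_type={"clap": 5}, seed=1)
        b = sample_feature_table(n_per_type={"clap": 5}, seed=1)
        assert a.equals(b)

    def test_large_n_means_within_3se(self):
        n = 4000
        table = sample_feature_table(n_per_type={"bark": n, "growl": n},
                                     seed=2)
        from sealscape.repertoire import get_call_type
        for name in ("bark", "growl"):
            ct = get_call_type(name)
            grp = table[table["type"] == name]
            for var, (mean, sd) in ct.stats.items():
                se = sd / np.sqrt(n)
                assert abs(grp[var].mean() - mean) < 3 * se, (name, var)

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError):
            sample_feature_table(n_per_type={"yodel": 3}, seed=0)

    def test_moan_rejected(self):
        with pytest.raises(ValueError, match="not measurable"):
            sample_feature_table(n_per_type={"moan": 3}, seed=0)

    def test_category_masks(self):
        table = sample_feature_table(seed=3)
        noisy = table[table["category"] == "noisy"]
        assert noisy["f0"].isna().all() and noisy["PR"].isna().all()
        clap = table[table["type"] == "clap"]
        assert clap["Fmax"].isna().all()
        assert clap[["dur", "PR"]].notna().all().all()
        harmonic = table[table["category"] == "harmonic"]
        assert harmonic[["dur", "f0", "Fmax", "Q25", "Q50", "Q75"]]\
            .notna().all().all()


class TestRepertoireDefaults:
    @pytest.mark.parametrize("name", [t.name for t in CALL_TYPES.values()
                                      if t.measurable])
    def test_every_type_synthesizes_with_ground_truth_oracles(self, name):
        spec = SynthesisSpec.from_call_type(name)
        seg, gt = synth_call(spec, seed=11)
        assert gt.dur > 0
        if gt.PR is not None and CALL_TYPES[name].pulse_mode == "am":
            assert abs(envelope_fft_peak(seg.samples, seg.rate) - gt.PR) \
                < 0.05 * gt.PR
        if gt.f0 is not None and gt.excF == 0:
            # unmodulated stack: the spectral peak sits on some harmonic
            peak = fft_peak(seg.samples, seg.rate,
                            CALL_TYPES[name].analysis_band)
            ratio = peak / gt.f0
            assert abs(ratio - round(ratio)) < 0.03
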