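# sealscape

Underwater pinniped call-repertoire and soundscape analysis, exercised
end-to-end on synthetic audio with controlled statistical structure.

The package covers a passive-acoustic-monitoring workflow for a repertoire
of 18 call types in three structural categories (harmonic, noisy,
pulsative):

- **`sealscape.synth`** — synthetic call waveforms (harmonic stacks with
  frequency modulation, quartile-shaped noise bursts, pulse trains and
  AM calls), mixed soundscapes (snapping-shrimp crackle 1.5–5.5 kHz, vessel
  noise 20–200 Hz, flow noise < 30 Hz), Audacity-style label tracks,
  per-call ground truth, and directly sampled feature tables.
- **`sealscape.dsp`** — spectrograms (1024-pt FFT, 75 % overlap, Hamming by
  default), average energy spectra, amplitude envelopes, merge/resample.
- **`sealscape.features`** — per-category acoustic measurements on labeled
  call segments: duration, fundamental frequency (harmonic-comb +
  fundamental tracking), frequency excursion, spectral peak, energy
  quartiles, pulse rate; with call-type-specific band limits
  (20 Hz–1 kHz default, 3 kHz for growl/knock, 2 kHz for scream).
- **`sealscape.rf`** — out-of-bag Random-Forest validation of the call-type
  classification (500 trees; 6/5/2 variables and mtry 2/2/1 per category),
  confusion matrices, per-class/overall error, accuracy = 1 − OOB, chance
  rates, Gini importance ranking.
- **`sealscape.soundscape`** — hydrophone calibration (dB re V/µPa → µPa),
  LTSA, PSD percentile curves (dB re 1 µPa²/Hz), broadband
  (20 Hz–5.5 kHz) and octave-band (125/500/2000 Hz) level series.
- **`sealscape.noise_budget`** — hourly/daily noise-presence statistics
  with interval-union semantics and quiet-day flags.
- **`sealscape.cli` / `sealscape.pipeline`** — file-based pipeline stages
  behind a single CLI.

## CLI

```bash
sealscape synth      --config config.yaml --out dataset/
sealscape features   --config config.yaml --dataset dataset/ --out features.csv
sealscape repertoire --config config.yaml --features features.csv --out rf/
sealscape soundscape --config config.yaml --wav dataset/soundscape.wav --out metrics/
sealscape all        --config config.yaml --out run/     # everything
```

The YAML config is strictly validated (unknown keys rejected); every stage
is deterministic for a fixed `seed`, and `synth` writes a manifest with
SHA-256 checksums of all artifacts. Example config:

```yaml
seed: 7
synth:
  n_per_type: {bark: 20, hiccup: 20, clap: 10}
  soundscape_duration: 60.0
rf:
  n_trees: 500
calibration:
  sensitivity_db: -168.5
```

Omit the `calibration` block to get levels in dB re full scale (flagged in
the outputs) instead of dB re 1 µPa.

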