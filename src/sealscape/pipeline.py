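"""File-based pipeline stages behind the CLI.

Stages communicate only through files (WAV, label tracks, CSV) so each is
independently testable and reproducible: a fixed config + seed yields
byte-identical artifacts, recorded in a checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .audio import AudioSegment, read_wav, write_wav
from .config import PipelineConfig
from .features import CallSegment, NotMeasurableError, extract_features
from .labels import LabelEvent, write_label_track
from .repertoire import CALL_TYPES, CATEGORIES, VARIABLES, get_call_type
from .rf import RFConfig, rf_validate
from .soundscape import (HydrophoneCal, band_levels, calibrate, ltsa,
                         psd_percentiles)
from .synth import SoundscapeMix, SynthesisSpec, synth_call, synth_soundscape

log = logging.getLogger("sealscape")

__all__ = ["run_synth", "run_features", "run_repertoire", "run_soundscape"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, config: PipelineConfig,
                    started: float) -> None:
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": config.digest(),
        "version": __version__,
        "python": platform.python_version(),
        "wall_time_s": round(time.time() - started, 3),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def run_synth(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate a call corpus + mixed soundscape dataset directory."""
    started = time.time()
    out = Path(out_dir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_per_type = config.synth.n_per_type
    if n_per_type is None:
        n_per_type = {t.name: t.n for t in CALL_TYPES.values() if t.n > 0}
    index_rows, gt_rows = [], []
    for name, n in n_per_type.items():
        ct = get_call_type(name)
        spec = SynthesisSpec.from_call_type(ct,
                                            amplitude=config.synth.amplitude)
        for i in range(n):
            call_id = f"{name}_{i:04d}"
            seg, gt = synth_call(spec, int(rng.integers(2 ** 63)),
                                 rate=config.sample_rate)
            rel = f"calls/{call_id}.wav"
            write_wav(out / rel, seg)
            degraded = rng.random() < config.synth.degraded_fraction
            index_rows.append({
                "call_id": call_id, "file": rel, "start": 0.0,
                "end": seg.duration, "type": name,
                "quality": "degraded" if degraded else "good"})
            gt_rows.append({"call_id": call_id, **gt.as_dict()})
    pd.DataFrame(index_rows).to_csv(out / "calls.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)

    if config.synth.soundscape_duration > 0:
        mix = SoundscapeMix(shrimp_gain=config.synth.shrimp_gain,
                            shrimp_snap_rate=config.synth.shrimp_snap_rate,
                            boat_gain=config.synth.boat_gain,
                            flow_gain=config.synth.flow_gain)
        seg, events, _ = synth_soundscape(
            mix, [], config.synth.soundscape_duration,
            seed=config.seed, rate=config.sample_rate)
        write_wav(out / "soundscape.wav", seg)
        write_label_track(out / "soundscape_labels.txt", events)

    _write_manifest(out, config, started)
    log.info("synth: %d calls -> %s", len(index_rows), out)
    return out


def run_features(config: PipelineConfig, dataset: str | Path,
                 out_csv: str | Path) -> pd.DataFrame:
    """Extract features for every good-quality measurable call.

    Skipped calls (degraded quality, non-measurable types) are logged with
    reasons; a missing audio file referenced by the index is an error.
    """
    dataset = Path(dataset)
    index = pd.read_csv(dataset / "calls.csv")
    rows, skipped = [], 0
    for rec in index.itertuples():
        wav_path = dataset / rec.file
        if not wav_path.exists():
            raise FileNotFoundError(f"audio file missing: {wav_path}")
        ct = get_call_type(rec.type)
        if not ct.measurable:
            log.info("skip %s: type %s not measurable", rec.call_id, rec.type)
            skipped += 1
            continue
        if rec.quality != "good":
            log.info("skip %s: quality %s", rec.call_id, rec.quality)
            skipped += 1
            continue
        audio = read_wav(wav_path)
        seg = CallSegment(audio, rec.start, rec.end, ct, rec.quality)
        try:
            fv = extract_features(seg)
        except NotMeasurableError as exc:  # defensive; filtered above
            log.info("skip %s: %s", rec.call_id, exc)
            skipped += 1
            continue
        rows.append({"call_id": rec.call_id, "type": rec.type,
                     "category": ct.category, **fv.as_dict()})
    table = pd.DataFrame(rows, columns=["call_id", "type", "category",
                                        *VARIABLES])
    table.to_csv(out_csv, index=False)
    log.info("features: %d measured, %d skipped -> %s",
             len(rows), skipped, out_csv)
    return table


def summary_table(features: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean ± SD table with the per-type variable masks applied."""
    rows = []
    for name, grp in features.groupby("type", sort=False):
        ct = get_call_type(name)
        row = {"type": name, "category": ct.category, "n": len(grp)}
        for var in VARIABLES:
            if var in ct.mask and grp[var].notna().any():
                row[var] = (f"{grp[var].mean():.3f} ± {grp[var].std():.3f}"
                            if var == "dur" or var == "PR" else
                            f"{grp[var].mean():.0f} ± {grp[var].std():.0f}")
            else:
                row[var] = "--"
        rows.append(row)
    return pd.DataFrame(rows)


def run_repertoire(config: PipelineConfig, features: str | Path | pd.DataFrame,
                   out_dir: str | Path) -> dict:
    """Per-category out-of-bag validation; serializes confusion + summary."""
    if not isinstance(features, pd.DataFrame):
        features = pd.read_csv(features)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for category in CATEGORIES:
        sub = features[features["category"] == category]
        if sub["type"].nunique() < 2:
            log.warning("repertoire: category %r has < 2 call types; skipped",
                        category)
            continue
        rfc = RFConfig.for_category(category, seed=config.seed,
                                    n_trees=config.rf.n_trees)
        cols = [c for c in rfc.variables]
        usable = sub.dropna(subset=cols)
        result = rf_validate(usable, rfc)
        result.confusion.to_dataframe().to_csv(
            out / f"confusion_{category}.csv")
        summary[category] = result.summary()
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    summary_table(features).to_csv(out / "feature_summary.csv", index=False)
    return summary


def run_soundscape(config: PipelineConfig, wav: str | Path,
                   out_dir: str | Path) -> None:
    """LTSA, PSD percentile, broadband and octave-level outputs for a WAV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    segment = read_wav(wav)
    calibrated = config.calibration is not None
    if calibrated:
        cal = HydrophoneCal(config.calibration.sensitivity_db,
                            config.calibration.gain_db,
                            config.calibration.adc_full_scale)
        segment = calibrate(segment, cal)
    else:
        log.warning("no calibration block: levels are dB re full scale")

    ss = config.soundscape
    lt = ltsa(segment, time_bin=min(ss.ltsa_time_bin, segment.duration),
              freq_bin=ss.ltsa_freq_bin, window_s=ss.psd_window)
    lt.to_dataframe().to_csv(out / "ltsa.csv")
    psd = psd_percentiles(segment, window_s=ss.psd_window)
    psd.to_dataframe().to_csv(out / "psd_percentiles.csv")
    nyq_ok = {"BB": (20.0, min(5500.0, segment.rate / 2 - 1))}
    from .soundscape import OCTAVE_CENTERS, octave_band
    for c in OCTAVE_CENTERS:
        lo, hi = octave_band(c)
        if hi < segment.rate / 2:
            nyq_ok[f"OL{int(c)}"] = (lo, hi)
    bl = band_levels(segment, bands=nyq_ok,
                     time_bin=min(ss.band_time_bin, segment.duration))
    bl[["time", "BB"]].to_csv(out / "broadband.csv", index=False)
    bl.to_csv(out / "octave_levels.csv", index=False)
    meta = {"calibrated": calibrated,
            "reference": "dB re 1 uPa" if calibrated else "dB re full scale"}
    (out / "soundscape_meta.json").write_text(json.dumps(meta, indent=1))
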