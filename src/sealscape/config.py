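"""Structured pipeline configuration (YAML) with strict validation.

Unknown keys are rejected so typos fail before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpectrogramConfig(_Strict):
    fft_size: int = 1024
    overlap: float = Field(0.75, ge=0.0, lt=1.0)
    window: str = "hamming"


class RFSettings(_Strict):
    n_trees: int = Field(500, ge=1)


class CalibrationConfig(_Strict):
    sensitivity_db: float = -168.5
    gain_db: float = 0.0
    adc_full_scale: float = Field(1.0, gt=0.0)


class SynthSettings(_Strict):
    n_per_type: dict[str, int] | None = None
    amplitude: float = Field(0.3, gt=0.0, le=1.0)
    degraded_fraction: float = Field(0.0, ge=0.0, le=1.0)
    soundscape_duration: float = Field(60.0, ge=0.0)
    shrimp_gain: float = Field(0.02, ge=0.0)
    boat_gain: float = Field(0.05, ge=0.0)
    flow_gain: float = Field(0.01, ge=0.0)
    shrimp_snap_rate: float = Field(60.0, ge=0.0)


class SoundscapeSettings(_Strict):
    ltsa_time_bin: float = Field(5.0, gt=0.0)
    ltsa_freq_bin: float = Field(5.0, gt=0.0)
    psd_window: float = Field(1.0, gt=0.0)
    band_time_bin: float = Field(10.0, gt=0.0)


class PipelineConfig(_Strict):
    seed: int = 0
    sample_rate: float = Field(22050.0, gt=0.0)
    synth: SynthSettings = SynthSettings()
    spectrogram: SpectrogramConfig = SpectrogramConfig()
    rf: RFSettings = RFSettings()
    calibration: CalibrationConfig | None = None
    soundscape: SoundscapeSettings = SoundscapeSettings()

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(raw)
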