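"""Audio containers and WAV I/O.

WAV files are written as mono float32 (or PCM-16 on request) via
:mod:`scipy.io.wavfile`; samples are dimensionless full-scale fractions in
``[-1, 1]`` unless a segment has been calibrated to pressure units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
from scipy.io import wavfile

if TYPE_CHECKING:  # pragma: no cover
    from .soundscape import HydrophoneCal

__all__ = ["AudioSegment", "read_wav", "write_wav"]


@dataclass
class AudioSegment:
    """A single-channel signal with a sample rate and a time offset.

    ``start_time`` is the offset (s) of the first sample within the parent
    recording; all segment times are half-open ``[start, end)`` intervals in
    seconds from recording start.  ``units`` is ``"fullscale"`` for raw
    recordings and ``"uPa"`` after calibration.
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    units: str = "fullscale"
    calibration: "HydrophoneCal | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSegment is single-channel; got "
                             f"{self.samples.ndim}-d samples")
        if self.samples.size < 1:
            raise ValueError("empty segment")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    def slice(self, start: float, end: float) -> "AudioSegment":
        """Extract ``[start, end)`` (seconds from recording start)."""
        if end <= start:
            raise ValueError(f"empty slice [{start}, {end})")
        i0 = max(0, int(round((start - self.start_time) * self.rate)))
        i1 = min(len(self), int(round((end - self.start_time) * self.rate)))
        if i1 <= i0:
            raise ValueError(f"slice [{start}, {end}) outside segment")
        return replace(self, samples=self.samples[i0:i1],
                       start_time=self.start_time + i0 / self.rate)


def read_wav(path: str | Path) -> AudioSegment:
    """Read a mono WAV file, normalizing integer PCM to ``[-1, 1]``."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(np.float64) / scale
    return AudioSegment(np.asarray(data, dtype=np.float64), float(rate))


def write_wav(path: str | Path, segment: AudioSegment, *,
              dtype: str = "float32") -> None:
    """Write a segment as mono WAV (``float32`` default, or ``int16``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dtype == "float32":
        wavfile.write(str(path), int(round(segment.rate)),
                      segment.samples.astype(np.float32))
    elif dtype == "int16":
        clipped = np.clip(segment.samples, -1.0, 1.0 - 1.0 / 32768)
        wavfile.write(str(path), int(round(segment.rate)),
                      np.round(clipped * 32768).astype(np.int16))
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
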