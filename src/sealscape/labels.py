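"""Label-track I/O (Audacity three-column dialect).

A label track is plain text, one event per line::

    start_s<TAB>end_s<TAB>label

Floats are written with ``repr`` so a write/parse round trip reproduces
intervals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["LabelEvent", "read_label_track", "write_label_track"]


@dataclass(frozen=True)
class LabelEvent:
    """A labeled half-open interval ``[start, end)`` in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start: {self}")
        if "\t" in self.label or "\n" in self.label:
            raise ValueError("label may not contain tabs or newlines")

    @property
    def duration(self) -> float:
        return self.end - self.start


def write_label_track(path: str | Path, events: list[LabelEvent]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{e.start!r}\t{e.end!r}\t{e.label}" for e in events]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_label_track(path: str | Path) -> list[LabelEvent]:
    events = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated "
                             f"fields, got {len(parts)}")
        events.append(LabelEvent(float(parts[0]), float(parts[1]), parts[2]))
    return events
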