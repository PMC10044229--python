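"""Call-type registry for the underwater monk-seal repertoire.

Eighteen call types grouped in three structural categories:

* ``harmonic`` — a fundamental frequency with a stack of harmonics
  (12 types, one of which, the moan, is too faint to be measured),
* ``noisy`` — broadband calls without harmonic structure (3 types),
* ``pulsative`` — trains of discrete broadband units or fast
  amplitude-modulated calls (3 types).

Each measurable type carries the per-variable mean/SD statistics used both
as synthesis targets (:mod:`sealscape.synth`) and as sampling parameters for
feature tables, its spectral analysis band, and the mask of variables that
are reported for it.  Variables are named ``dur`` (s), ``f0`` (Hz), ``excF``
(Hz), ``Fmax`` (Hz), ``Q25``/``Q50``/``Q75`` (Hz) and ``PR`` (pulses/s).

The module also bundles the reference out-of-bag confusion matrices of the
aural–visual classification validation, used by examples and acceptance
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CallType",
    "CALL_TYPES",
    "CATEGORIES",
    "VARIABLES",
    "RF_VARIABLES",
    "RF_MTRY",
    "types_in_category",
    "get_call_type",
    "REFERENCE_CONFUSIONS",
]

#: canonical variable order used throughout feature tables
VARIABLES = ("dur", "f0", "excF", "Fmax", "Q25", "Q50", "Q75", "PR")

CATEGORIES = ("harmonic", "noisy", "pulsative")

#: per-category variable sets used for random-forest validation
#: (only variables measurable for every type of the category)
RF_VARIABLES = {
    "harmonic": ("dur", "f0", "Fmax", "Q25", "Q50", "Q75"),
    "noisy": ("dur", "Fmax", "Q25", "Q50", "Q75"),
    "pulsative": ("dur", "PR"),
}

#: number of variables drawn at each split, per category
RF_MTRY = {"harmonic": 2, "noisy": 2, "pulsative": 1}

DEFAULT_BAND = (20.0, 1000.0)


@dataclass(frozen=True)
class CallType:
    """A call type: category, analysis band and generative statistics.

    ``stats`` maps variable name -> (mean, sd).  Variables absent from
    ``stats`` are not defined for the type.  ``mask`` lists the variables
    reported for the type in summary tables (single-band harmonic types
    compute quartiles internally but do not report them).
    """

    name: str
    category: str
    n: int
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    analysis_band: tuple[float, float] = DEFAULT_BAND
    mask: tuple[str, ...] = ()
    measurable: bool = True
    single_band: bool = False
    n_harmonics: int = 1
    pulse_mode: str = "discrete"  # pulsative only: "discrete" | "am"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        lo, hi = self.analysis_band
        if not 0 < lo < hi:
            raise ValueError(f"bad analysis band {self.analysis_band}")
        for var, (mean, sd) in self.stats.items():
            if var not in VARIABLES:
                raise ValueError(f"unknown variable {var!r}")
            if mean <= 0 or sd < 0:
                raise ValueError(f"{self.name}.{var}: mean must be > 0, sd >= 0")

    def stat(self, var: str) -> tuple[float, float] | None:
        return self.stats.get(var)

    @property
    def f0_search(self) -> tuple[float, float]:
        """Search range for the fundamental, derived from the f0 statistics."""
        mean, sd = self.stats.get("f0", (150.0, 100.0))
        lo = max(25.0, mean - 3.0 * sd) - 10.0
        hi = min(mean + 3.0 * sd + 10.0, self.analysis_band[1] - 20.0)
        return (max(20.0, lo), hi)


def _harm(name, n, dur, f0, excF, fmax, q25, q50, q75, *, band=DEFAULT_BAND,
          n_harmonics=4, single_band=False):
    stats = {"dur": dur, "f0": f0, "Fmax": fmax}
    mask = ["dur", "f0", "Fmax"]
    if excF is not None:
        stats["excF"] = excF
        mask.insert(2, "excF")
    if q25 is not None:
        stats.update({"Q25": q25, "Q50": q50, "Q75": q75})
        mask += ["Q25", "Q50", "Q75"]
    return CallType(name, "harmonic", n, stats, band, tuple(mask),
                    n_harmonics=n_harmonics, single_band=single_band)


def _noisy(name, n, dur, fmax, q25, q50, q75, *, band=DEFAULT_BAND):
    stats = {"dur": dur, "Fmax": fmax, "Q25": q25, "Q50": q50, "Q75": q75}
    return CallType(name, "noisy", n, stats, band,
                    ("dur", "Fmax", "Q25", "Q50", "Q75"))


_TYPES = [
    # --- harmonic -------------------------------------------------------
    _harm("bark", 294, (0.418, 0.262), (137, 37), (45, 27), (312, 190),
          (275, 83), (450, 134), (687, 148)),
    _harm("croak", 32, (0.460, 0.147), (96, 40), (43, 29), (282, 146),
          (238, 86), (366, 162), (622, 406)),
    _harm("cry", 24, (1.386, 1.074), (290, 150), (95, 77), (360, 170),
          (272, 106), (433, 118), (699, 129), n_harmonics=3),
    _harm("gloo", 76, (0.350, 0.359), (112, 29), (74, 43), (147, 79),
          (153, 53), (283, 109), (490, 147), n_harmonics=3),
    _harm("gloogloo", 39, (0.555, 0.562), (116, 28), None, (193, 80),
          (171, 37), (288, 61), (503, 119)),
    _harm("groan", 78, (0.500, 0.247), (79, 36), None, (174, 87),
          (178, 58), (287, 82), (507, 289)),
    CallType("moan", "harmonic", 0, measurable=False),
    _harm("scream", 19, (0.408, 0.277), (1207, 444), (150, 111), (1207, 444),
          None, None, None, band=(20.0, 2000.0), n_harmonics=1,
          single_band=True),
    _harm("whine", 47, (0.663, 0.313), (134, 45), (51, 30), (143, 41),
          None, None, None, n_harmonics=1, single_band=True),
    _harm("whoo", 65, (0.207, 0.068), (439, 154), (73, 48), (461, 190),
          None, None, None, n_harmonics=1, single_band=True),
    _harm("wop", 23, (0.229, 0.069), (297, 70), (68, 30), (406, 145),
          (316, 59), (486, 110), (699, 94), n_harmonics=3),
    _harm("wom", 42, (0.303, 0.100), (95, 30), (54, 33), (100, 44),
          (117, 39), (288, 157), (632, 191)),
    # --- noisy ----------------------------------------------------------
    _noisy("growl", 442, (1.136, 0.616), (648, 412), (542, 249), (920, 388),
           (1399, 662), band=(20.0, 3000.0)),
    _noisy("hiccup", 210, (0.177, 0.042), (395, 109), (353, 82), (422, 99),
           (567, 120)),
    _noisy("squeak", 43, (0.155, 0.081), (557, 147), (422, 92), (556, 92),
           (690, 105)),
    # --- pulsative ------------------------------------------------------
    CallType("clap", "pulsative", 13,
             {"dur": (5.103, 1.619), "PR": (1.70, 0.16)},
             DEFAULT_BAND, ("dur", "PR"), pulse_mode="discrete"),
    CallType("knock", "pulsative", 226,
             {"dur": (1.922, 1.828), "Fmax": (699, 441), "PR": (6.81, 1.43)},
             (20.0, 3000.0), ("dur", "Fmax", "PR"), pulse_mode="discrete"),
    CallType("rumble", "pulsative", 23,
             {"dur": (1.062, 0.434), "Fmax": (205, 65), "Q25": (215, 50),
              "Q50": (347, 97), "Q75": (571, 142), "PR": (16.31, 3.5)},
             DEFAULT_BAND, ("dur", "Fmax", "Q25", "Q50", "Q75", "PR"),
             pulse_mode="am"),
]

CALL_TYPES: dict[str, CallType] = {t.name: t for t in _TYPES}

assert sum(t.category == "harmonic" for t in _TYPES) == 12
assert sum(t.category == "noisy" for t in _TYPES) == 3
assert sum(t.category == "pulsative" for t in _TYPES) == 3


def get_call_type(name: str) -> CallType:
    try:
        return CALL_TYPES[name]
    except KeyError:
        raise KeyError(f"unknown call type {name!r}; known types: "
                       f"{sorted(CALL_TYPES)}") from None


def types_in_category(category: str, measurable_only: bool = True) -> list[CallType]:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return [t for t in _TYPES
            if t.category == category and (t.measurable or not measurable_only)]


# ---------------------------------------------------------------------------
# Reference out-of-bag confusion matrices (rows = true class, columns =
# predicted class) from the validation of the aural–visual classification.
# ---------------------------------------------------------------------------

_HARMONIC_LABELS = ("bark", "croak", "cry", "gloo", "gloogloo", "groan",
                    "scream", "whine", "whoo", "wom", "wop")
_HARMONIC_COUNTS = np.array([
    [271, 2, 2, 11, 1, 0, 0, 0, 0, 4, 3],
    [15, 14, 0, 2, 0, 1, 0, 0, 0, 0, 0],
    [9, 0, 12, 0, 0, 1, 0, 0, 0, 0, 2],
    [17, 2, 0, 44, 2, 2, 0, 0, 0, 9, 0],
    [7, 0, 0, 1, 19, 11, 0, 0, 0, 1, 0],
    [9, 0, 0, 0, 8, 61, 0, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 0, 15, 0, 4, 0, 0],
    [0, 0, 0, 0, 0, 0, 0, 46, 1, 0, 0],
    [0, 0, 0, 0, 0, 0, 1, 2, 62, 0, 0],
    [6, 0, 0, 10, 0, 2, 0, 0, 0, 24, 0],
    [4, 0, 1, 0, 0, 0, 0, 0, 0, 0, 18],
])

_NOISY_LABELS = ("growl", "hiccup", "squeak")
_NOISY_COUNTS = np.array([
    [441, 1, 0],
    [0, 199, 11],
    [1, 19, 23],
])

_PULSATIVE_LABELS = ("clap", "knock", "rumble")
_PULSATIVE_COUNTS = np.array([
    [13, 0, 0],
    [0, 222, 2],
    [0, 2, 21],
])

#: category -> (class labels, OOB count matrix)
REFERENCE_CONFUSIONS: dict[str, tuple[tuple[str, ...], np.ndarray]] = {
    "harmonic": (_HARMONIC_LABELS, _HARMONIC_COUNTS),
    "noisy": (_NOISY_LABELS, _NOISY_COUNTS),
    "pulsative": (_PULSATIVE_LABELS, _PULSATIVE_COUNTS),
}
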