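"""Rhythm vocabulary shared across the pipeline.

The detector's target dichotomy is LTA (life-threatening arrhythmia:
ventricular tachycardia, ventricular fibrillation, ventricular flutter,
polymorphic ventricular tachycardia) versus everything else ("Other").
Noise spans carry their own code so the segmenter can mask them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class RhythmCode(str, enum.Enum):
    """Internal rhythm codes."""

    SINUS = "SINUS"
    AFIB_LIKE = "AFIB_LIKE"
    TACHY_OTHER = "TACHY_OTHER"
    VT = "VT"
    VF = "VF"
    VFL = "VFL"
    PVT = "PVT"
    NOISE = "NOISE"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Rhythms treated as life-threatening (the positive class).
LTA_CODES = frozenset({RhythmCode.VT, RhythmCode.VF, RhythmCode.VFL, RhythmCode.PVT})

#: Everything that is a genuine (non-noise) rhythm.
NON_LTA_CODES = frozenset(
    {RhythmCode.SINUS, RhythmCode.AFIB_LIKE, RhythmCode.TACHY_OTHER, RhythmCode.OTHER}
)


def is_lta(code: RhythmCode) -> bool:
    return code in LTA_CODES


#: Default mapping from WFDB aux rhythm strings to internal codes.  The
#: aux strings follow the PhysioNet convention of a '(' prefix.
DEFAULT_AUX_MAP: dict[str, RhythmCode] = {
    "(N": RhythmCode.SINUS,
    "(NSR": RhythmCode.SINUS,
    "(SINUS": RhythmCode.SINUS,
    "(AFIB": RhythmCode.AFIB_LIKE,
    "(AFL": RhythmCode.AFIB_LIKE,
    "(SVTA": RhythmCode.TACHY_OTHER,
    "(T": RhythmCode.TACHY_OTHER,
    "(VT": RhythmCode.VT,
    "(VF": RhythmCode.VF,
    "(VFIB": RhythmCode.VF,
    "(VFL": RhythmCode.VFL,
    "(PVT": RhythmCode.PVT,
    "(NOISE": RhythmCode.NOISE,
}


@dataclass
class LabelCodeMap:
    """Maps dataset rhythm strings (or diagnosis codes) to internal codes.

    ``aux_map`` covers annotation aux strings; ``dx_map`` covers
    whole-recording diagnosis codes (SNOMED-CT style).  Strings absent from
    the map fall back to :attr:`RhythmCode.OTHER` unless ``strict`` is set,
    in which case lookup raises ``KeyError``.
    """

    aux_map: dict[str, RhythmCode] = field(default_factory=lambda: dict(DEFAULT_AUX_MAP))
    dx_map: dict[str, RhythmCode] = field(default_factory=dict)
    strict: bool = False

    def map_aux(self, aux: str) -> RhythmCode:
        aux = aux.strip()
        if aux in self.aux_map:
            return self.aux_map[aux]
        if self.strict:
            raise KeyError(f"unknown rhythm string {aux!r} (strict mode)")
        return RhythmCode.OTHER

    def is_rhythm_dx(self, code: str) -> bool:
        return code.strip() in self.dx_map

    def map_dx(self, code: str) -> RhythmCode:
        return self.dx_map[code.strip()]
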