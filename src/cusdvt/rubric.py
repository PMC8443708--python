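"""Expert image-quality rubric for curating compression-ultrasound sequences.

Ten ordinal criteria scored by an expert reviewer (lower is better), summing
to a total between 10 and 35.  Sequences with a total at or below the cutoff
(default 20) are accepted for analysis; the rubric is entered by a human,
never estimated from pixels.

Criteria and ranges:

========================  =====  =============================================
criterion                 range  1 = best
========================  =====  =============================================
vessel_boundaries         1-5    vessels fully in frame
lm_adherence              1-5    strongly adherent to the landmark layout
vein_contrast             1-3    dark veins, bright tissue
artery_contrast           1-3    dark arteries, bright tissue
vein_sharpness            1-3    clear boundaries, strong dorsal enhancement
artery_sharpness          1-3    clear boundaries, strong dorsal enhancement
gain                      1-3    medium gain range
depth                     1-3    image ends ~1 cm below the lowest vessel
artefacts                 1-3    only minor artefacts
probe_movement            1-4    medium-paced compression, no lateral drift
========================  =====  =============================================
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping

__all__ = ["CRITERION_RANGES", "QualityAssessment", "total_score", "accept", "validate"]

CRITERION_RANGES: dict[str, tuple[int, int]] = {
    "vessel_boundaries": (1, 5),
    "lm_adherence": (1, 5),
    "vein_contrast": (1, 3),
    "artery_contrast": (1, 3),
    "vein_sharpness": (1, 3),
    "artery_sharpness": (1, 3),
    "gain": (1, 3),
    "depth": (1, 3),
    "artefacts": (1, 3),
    "probe_movement": (1, 4),
}

DEFAULT_CUTOFF = 20


class RubricValidationError(ValueError):
    """One or more criterion scores are missing, unknown or out of range."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


@dataclass(frozen=True)
class QualityAssessment:
    vessel_boundaries: int
    lm_adherence: int
    vein_contrast: int
    artery_contrast: int
    vein_sharpness: int
    artery_sharpness: int
    gain: int
    depth: int
    artefacts: int
    probe_movement: int

    def __post_init__(self) -> None:
        problems = []
        for f in fields(self):
            lo, hi = CRITERION_RANGES[f.name]
            v = getattr(self, f.name)
            if not isinstance(v, int) or not lo <= v <= hi:
                problems.append(f"{f.name}={v!r} outside [{lo}, {hi}]")
        if problems:
            raise RubricValidationError(problems)

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def total_score(a: QualityAssessment) -> int:
    """Sum of the ten criterion scores (range 10-35)."""
    return sum(a.as_dict().values())


def accept(a: QualityAssessment, cutoff: int = DEFAULT_CUTOFF) -> bool:
    """True iff the total score is less than or equal to ``cutoff`` (inclusive)."""
    return total_score(a) <= cutoff


def validate(raw: Mapping[str, int]) -> QualityAssessment:
    """Build a :class:`QualityAssessment` from a raw mapping.

    Collects every violation (missing criterion, unknown key, out-of-range
    value) into a single :class:`RubricValidationError` naming the offenders.
    """
    problems = []
    for key in raw:
        if key not in CRITERION_RANGES:
            problems.append(f"unknown criterion {key!r}")
    for key in CRITERION_RANGES:
        if key not in raw:
            problems.append(f"missing criterion {key!r}")
    if problems:
        raise RubricValidationError(problems)
    return QualityAssessment(**{k: raw[k] for k in CRITERION_RANGES})
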