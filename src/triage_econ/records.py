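"""Domain types for per-patient reading records and reference-standard labels.

A *reading record* is one radiologist's ordinal diagnostic-confidence score
(1-5) for the marker lesion of one patient on one modality (chest radiography
or digital tomosynthesis).  The reference standard assigns each patient one
lesion category; the binary ground truth distinguishes non-calcified pulmonary
lesions that warrant CT work-up (positives) from benign, extra-pulmonary or
pseudo-lesions that do not (negatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional


class Modality(str, Enum):
    CXR = "CXR"
    DTS = "DTS"


class LesionCategory(str, Enum):
    PULMONARY_OPACITY = "pulmonary_opacity"
    PRIMARY_LUNG_NEOPLASM = "primary_lung_neoplasm"
    GROUND_GLASS = "ground_glass"
    NONCALCIFIED_SOLID_NODULE = "noncalcified_solid_nodule"
    PULMONARY_SCAR = "pulmonary_scar"
    CALCIFIED_SOLID_NODULE = "calcified_solid_nodule"
    PLEURAL_PLAQUE = "pleural_plaque"
    PSEUDOLESION = "pseudolesion"


#: categories that constitute a CT-deserving, non-calcified pulmonary lesion
POSITIVE_CATEGORIES = frozenset(
    {
        LesionCategory.PULMONARY_OPACITY,
        LesionCategory.PRIMARY_LUNG_NEOPLASM,
        LesionCategory.GROUND_GLASS,
        LesionCategory.NONCALCIFIED_SOLID_NODULE,
    }
)

VALID_SCORES = frozenset({1, 2, 3, 4, 5})


@dataclass(frozen=True)
class ReadingRecord:
    """One reader's confidence score for one patient on one modality."""

    patient_id: str
    modality: Modality
    reader_id: str
    score: int
    interpretation_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score not in VALID_SCORES:
            raise ValueError(
                f"score must be an integer in 1..5, got {self.score!r} "
                f"(patient {self.patient_id}, reader {self.reader_id})"
            )
        if self.interpretation_time_s is not None and self.interpretation_time_s < 0:
            raise ValueError("interpretation_time_s must be nonnegative")


@dataclass(frozen=True)
class TruthLabel:
    """Reference-standard lesion category for one patient."""

    patient_id: str
    category: LesionCategory
    size_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.size_cm is not None and self.size_cm <= 0:
            raise ValueError("size_cm must be positive when given")


@dataclass(frozen=True)
class BinaryTruth:
    """Binary ground truth: positive = non-calcified pulmonary lesion deserving CT."""

    patient_id: str
    positive: bool


def map_truth(label: TruthLabel) -> BinaryTruth:
    """Derive the binary ground truth from a lesion-category label.

    Positives are the non-calcified pulmonary lesions (opacities, primary
    neoplasms, ground-glass lesions, non-calcified solid nodules); calcified
    lesions, scars, pleural plaques and pseudolesions are negatives.
    """
    category = LesionCategory(label.category)
    return BinaryTruth(patient_id=label.patient_id, positive=category in POSITIVE_CATEGORIES)


def truth_map(labels: Iterable[TruthLabel]) -> dict[str, bool]:
    """patient_id -> binary positivity, checking uniqueness of labels."""
    out: dict[str, bool] = {}
    for label in labels:
        if label.patient_id in out:
            raise ValueError(f"duplicate truth label for patient {label.patient_id}")
        out[label.patient_id] = map_truth(label).positive
    return out


def validate_readings(records: Iterable[ReadingRecord]) -> list[ReadingRecord]:
    """Check the (patient, modality, reader) uniqueness invariant."""
    seen: set[tuple[str, Modality, str]] = set()
    out = []
    for rec in records:
        key = (rec.patient_id, rec.modality, rec.reader_id)
        if key in seen:
            raise ValueError(
                f"duplicate reading for patient {rec.patient_id}, "
                f"modality {rec.modality.value}, reader {rec.reader_id}"
            )
        seen.add(key)
        out.append(rec)
    return out
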