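"""The four stroke-mimic clinical prediction scales.

FABS, simplified FABS (sFABS) and the Khan score are oriented so that a
*higher* value means a *more likely* mimic; the TeleStroke Mimic Score
(TMS) is oriented the opposite way (higher = more likely true stroke).
All threshold comparisons (age < 50, SBP < 150 mmHg, NIHSS > 14) are
strict, and ages are integer completed years.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .cohort import Cohort, PatientRecord


class MimicDirection(Enum):
    HIGHER_IS_MIMIC = "higher_is_mimic"
    LOWER_IS_MIMIC = "lower_is_mimic"


#: Orientation of each scale: which direction indicates a stroke mimic.
ORIENTATIONS: dict[str, MimicDirection] = {
    "fabs": MimicDirection.HIGHER_IS_MIMIC,
    "sfabs": MimicDirection.HIGHER_IS_MIMIC,
    "tms": MimicDirection.LOWER_IS_MIMIC,
    "khan": MimicDirection.HIGHER_IS_MIMIC,
}

SCALE_NAMES = tuple(ORIENTATIONS)


@dataclass(frozen=True)
class ScaleResult:
    """The four scale values for one patient."""

    fabs: int
    sfabs: int
    tms: float
    khan: int

    def __post_init__(self) -> None:
        if not 0 <= self.fabs <= 6:
            raise ValueError(f"FABS out of range [0, 6]: {self.fabs}")
        if not 0 <= self.sfabs <= 4:
            raise ValueError(f"sFABS out of range [0, 4]: {self.sfabs}")
        if self.sfabs > self.fabs:
            raise ValueError("sFABS items are a subset of FABS items")
        if self.tms < -6:
            raise ValueError(f"TMS below its minimum of -6: {self.tms}")
        if not 0 <= self.khan <= 9:
            raise ValueError(f"Khan score out of range [0, 9]: {self.khan}")


def sfabs(record: PatientRecord) -> int:
    """Simplified FABS: 1 point each for absent facial droop, age < 50,
    absent atrial fibrillation, and SBP < 150 mmHg (0-4)."""
    return (
        int(not record.facial_droop)
        + int(record.age < 50)
        + int(not record.atrial_fibrillation)
        + int(record.sbp < 150)
    )


def fabs(record: PatientRecord) -> int:
    """FABS: the four sFABS items plus 1 point each for an isolated
    sensory deficit and a history of seizure disorder (0-6)."""
    return sfabs(record) + int(record.isolated_sensory_deficit) + int(record.seizure_history)


def tms(record: PatientRecord) -> float:
    """TeleStroke Mimic Score: 0.2/year of age, +6 atrial fibrillation,
    +3 hypertension, -6 seizures, +9 facial weakness, +5 if NIHSS > 14.

    Reported to one decimal place (the score moves in 0.2 steps).
    """
    score = (
        0.2 * record.age
        + 6 * record.atrial_fibrillation
        + 3 * record.hypertension
        - 6 * record.seizure_history
        + 9 * record.facial_droop
        + 5 * (record.nihss > 14)
    )
    return round(score, 1)


def khan(record: PatientRecord) -> int:
    """Khan score (0-9): age band + vascular-factor band + history items.

    Age: < 50 -> 2, 50-70 inclusive -> 1, > 70 -> 0. Vascular factors
    {hypertension, hyperlipidemia, diabetes, AF}: none -> 3, one
    (without AF) -> 2, two or three (without AF) -> 1, AF present -> 0
    regardless of the rest. Plus 2 for migraine, 1 for epilepsy
    (seizure history), 1 for psychiatric illness.
    """
    if record.age < 50:
        age_pts = 2
    elif record.age <= 70:
        age_pts = 1
    else:
        age_pts = 0

    if record.atrial_fibrillation:
        vasc_pts = 0
    else:
        n_factors = sum((record.hypertension, record.hyperlipidemia, record.diabetes))
        vasc_pts = {0: 3, 1: 2, 2: 1, 3: 1}[n_factors]

    return (
        age_pts
        + vasc_pts
        + 2 * record.migraine
        + record.seizure_history
        + record.psychiatric_history
    )


def score_record(record: PatientRecord) -> ScaleResult:
    return ScaleResult(fabs=fabs(record), sfabs=sfabs(record), tms=tms(record), khan=khan(record))


def score_cohort(cohort: Cohort) -> list[ScaleResult]:
    """Rate all four scales for every record, order-preserving."""
    return [score_record(r) for r in cohort.records]
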