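"""Shared domain types for first-day clinical state, organ failure, and scores.

All quantities live on conventional clinical units: bilirubin and creatinine
in mg/dL, albumin in g/dL, sodium and potassium in mEq/L, WBC in 10^9 cells/L,
hemoglobin in g/dL, mean arterial pressure in mmHg.  Hepatic encephalopathy
(HE) uses West Haven grades 0-4; ascites is 0 (none), 1 (mild), 2
(moderate/severe).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class DomainError(ValueError):
    """An input lies outside the domain an operation is defined on."""


class MissingFieldError(DomainError):
    """A required clinical variable is absent (None/NaN)."""

    def __init__(self, field_name: str) -> None:
        self.field_name = field_name
        super().__init__(f"required field '{field_name}' is missing")


ASCITES_NONE = 0
ASCITES_MILD = 1
ASCITES_MODERATE_SEVERE = 2

#: Organ systems in the fixed order used by the CLIF organ-failure score.
ORGANS = ("liver", "kidney", "brain", "coagulation", "circulation", "respiration")


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return math.isnan(value)
    except TypeError:
        return False


@dataclass
class PatientSnapshot:
    """Worst first-day clinical/laboratory state of one ICU admission.

    Laboratory values are the first-day extremes in the direction of
    severity (maximum bilirubin, minimum albumin, ...); aggregation from
    repeated measurements is the loader's job, not this container's.
    """

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    bilirubin: float
    albumin: float
    inr: float
    creatinine: float
    sodium: float
    potassium: float
    wbc: float
    hemoglobin: float
    mean_arterial_pressure: float
    he_grade: int  # West Haven 0-4
    ascites_grade: int  # 0 none, 1 mild, 2 moderate/severe
    pao2_fio2: Optional[float] = None
    spo2_fio2: Optional[float] = None
    on_vasopressors: bool = False
    on_mechanical_ventilation: bool = False
    mv_airway_protection_only: bool = False
    on_rrt: bool = False
    meld_precomputed: Optional[float] = None

    def validate(self) -> "PatientSnapshot":
        """Check the container invariants; return self for chaining."""
        if self.age < 18:
            raise DomainError(f"age must be >= 18 years, got {self.age}")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("bilirubin", "albumin", "inr", "creatinine", "sodium",
                     "potassium", "wbc", "hemoglobin", "mean_arterial_pressure"):
            value = getattr(self, name)
            if _is_missing(value):
                raise MissingFieldError(name)
            if value <= 0:
                raise DomainError(f"{name} must be strictly positive, got {value}")
        if _is_missing(self.pao2_fio2) and _is_missing(self.spo2_fio2):
            raise MissingFieldError("pao2_fio2/spo2_fio2 (at least one oxygenation ratio)")
        if self.he_grade not in (0, 1, 2, 3, 4):
            raise DomainError(f"he_grade must be in 0..4, got {self.he_grade}")
        if self.ascites_grade not in (0, 1, 2):
            raise DomainError(f"ascites_grade must be in 0..2, got {self.ascites_grade}")
        if self.mv_airway_protection_only and not self.on_mechanical_ventilation:
            raise DomainError("mv_airway_protection_only requires on_mechanical_ventilation")
        return self


@dataclass(frozen=True)
class ScoreSet:
    """All prognostic scores for one patient.

    Exactly one of ``clif_c_aclf`` / ``clif_c_ad`` is defined, matching the
    score's target population (with / without ACLF respectively).
    """

    ctp_points: int
    ctp_class: str  # "A" | "B" | "C"
    meld: float
    meld_na: float
    clif_of: int
    clif_of_subscores: tuple  # six ints in {1,2,3}, order per ORGANS
    clif_c_aclf: Optional[float] = None
    clif_c_ad: Optional[float] = None


@dataclass(frozen=True)
class OrganFailurePanel:
    """Flags for the six organ-system failures of the EASL-CLIF definition."""

    liver: bool
    kidney: bool
    brain: bool
    coagulation: bool
    circulation: bool
    respiration: bool

    @property
    def n_failures(self) -> int:
        return sum((self.liver, self.kidney, self.brain,
                    self.coagulation, self.circulation, self.respiration))

    def failed_organs(self) -> tuple:
        return tuple(o for o in ORGANS if getattr(self, o))


class GradeRule(str, Enum):
    """Which diagnostic sub-rule produced the ACLF grade."""

    NONE = "none"
    SINGLE_KIDNEY = "single_kidney"
    SINGLE_OTHER_WITH_CR_OR_HE = "single_other_with_cr_or_he"
    SINGLE_BRAIN_WITH_CR = "single_brain_with_cr"
    TWO_FAILURES = "two_failures"
    THREE_PLUS_FAILURES = "three_plus_failures"


@dataclass(frozen=True)
class ACLFAssessment:
    has_aclf: bool
    grade: int  # 0 (AD) .. 3
    rule_applied: GradeRule

    def __post_init__(self) -> None:
        if self.has_aclf != (self.grade >= 1):
            raise DomainError("has_aclf must equal grade >= 1")


@dataclass
class SurvivalRecord:
    """Per-patient time-to-event outcome over the 42-day follow-up window.

    ``event`` is death; censored records carry ``time`` equal to the
    follow-up horizon.
    """

    patient_id: str
    group: str  # "AD" | "ACLF"
    grade: int  # 0..3
    time: float  # days, in (0, follow_up]
    event: bool
    scores: Optional[ScoreSet] = None
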