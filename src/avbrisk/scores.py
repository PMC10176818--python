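"""Prognostic liver scores: Child-Turcotte-Pugh, MELD, MELD-Na, CLIF-OF,
CLIF-C ACLF and CLIF-C AD.

Conventions
-----------
* CTP uses the INR-based component table (bilirubin / albumin / INR /
  ascites / HE, each 1-3 points; class A 5-6, B 7-9, C 10-15).
* MELD is the UNOS formula 9.57 ln(cr) + 3.78 ln(bili) + 11.2 ln(INR) + 6.43
  with each analyte floored at 1.0, creatinine capped at 4.0 (and set to 4.0
  under renal replacement therapy), rounded to the nearest integer.  A
  database-provided MELD (``meld_precomputed``) takes precedence when set.
* MELD-Na = MELD + 1.59 (135 - Na) with Na clamped into [120, 135].
* CLIF-OF scores six organ systems 1-3 (total 6-18); subscore 3 coincides
  with organ failure as defined in :mod:`avbrisk.grading` for the liver,
  brain, coagulation, circulation and respiration systems.  The kidney
  subscore follows the published bands (creatinine < 2 / 2-<3.5 / >= 3.5
  mg/dL or RRT), so kidney *failure* (creatinine > 2 or RRT) corresponds to
  kidney subscore >= 2 rather than 3.
* CLIF-C ACLF and CLIF-C AD are the CLIF Consortium linear formulas; no
  rounding is applied so outputs are exactly testable.

Only MELD is rounded; every other score is returned at full precision.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

from . import grading
from .types import (
    ASCITES_MILD,
    ASCITES_MODERATE_SEVERE,
    ASCITES_NONE,
    DomainError,
    MissingFieldError,
    PatientSnapshot,
    ScoreSet,
    _is_missing,
)


def _require(snapshot: PatientSnapshot, *names: str) -> None:
    for name in names:
        if _is_missing(getattr(snapshot, name)):
            raise MissingFieldError(name)


def compute_ctp(snapshot: PatientSnapshot) -> Tuple[int, str]:
    """Child-Turcotte-Pugh points (5-15) and class (A/B/C)."""
    _require(snapshot, "bilirubin", "albumin", "inr", "ascites_grade", "he_grade")

    if snapshot.bilirubin < 2.0:
        bili = 1
    elif snapshot.bilirubin <= 3.0:
        bili = 2
    else:
        bili = 3

    if snapshot.albumin > 3.5:
        alb = 1
    elif snapshot.albumin >= 2.8:
        alb = 2
    else:
        alb = 3

    if snapshot.inr < 1.7:
        coag = 1
    elif snapshot.inr <= 2.3:
        coag = 2
    else:
        coag = 3

    ascites = {ASCITES_NONE: 1, ASCITES_MILD: 2, ASCITES_MODERATE_SEVERE: 3}[snapshot.ascites_grade]

    if snapshot.he_grade == 0:
        he = 1
    elif snapshot.he_grade <= 2:
        he = 2
    else:
        he = 3

    points = bili + alb + coag + ascites + he
    return points, ctp_class(points)


def ctp_class(points: int) -> str:
    """Map CTP points to class: A 5-6, B 7-9, C 10-15."""
    if not 5 <= points <= 15:
        raise DomainError(f"CTP points must lie in [5, 15], got {points}")
    if points <= 6:
        return "A"
    if points <= 9:
        return "B"
    return "C"


def compute_meld(snapshot: PatientSnapshot) -> int:
    """UNOS MELD, integer-rounded; ignores any precomputed override."""
    _require(snapshot, "bilirubin", "inr", "creatinine")
    for name in ("bilirubin", "inr", "creatinine"):
        if getattr(snapshot, name) <= 0:
            raise DomainError(f"{name} must be strictly positive")
    creatinine = 4.0 if snapshot.on_rrt else min(max(snapshot.creatinine, 1.0), 4.0)
    bilirubin = max(snapshot.bilirubin, 1.0)
    inr = max(snapshot.inr, 1.0)
    raw = 9.57 * math.log(creatinine) + 3.78 * math.log(bilirubin) + 11.2 * math.log(inr) + 6.43
    return int(round(raw))


def resolve_meld(snapshot: PatientSnapshot) -> float:
    """MELD for downstream use: the precomputed value when present, else
    :func:`compute_meld`."""
    if not _is_missing(snapshot.meld_precomputed):
        return float(snapshot.meld_precomputed)
    return float(compute_meld(snapshot))


def compute_meld_na(meld: float, sodium: float) -> float:
    """MELD-Na = MELD + 1.59 (135 - Na), Na clamped into [120, 135]."""
    if meld < 6:
        raise DomainError(f"MELD must be >= 6, got {meld}")
    if sodium <= 0:
        raise DomainError(f"sodium must be strictly positive, got {sodium}")
    na = min(max(sodium, 120.0), 135.0)
    return meld + 1.59 * (135.0 - na)


def _respiration_subscore(snapshot: PatientSnapshot) -> int:
    if grading.respiratory_failure(snapshot):
        return 3
    # moderate band decided on PaO2/FiO2 when available, else SpO2/FiO2
    if not _is_missing(snapshot.pao2_fio2):
        return 2 if snapshot.pao2_fio2 <= 300 else 1
    if not _is_missing(snapshot.spo2_fio2):
        return 2 if snapshot.spo2_fio2 <= 357 else 1
    raise MissingFieldError("pao2_fio2/spo2_fio2")


def compute_clif_of(snapshot: PatientSnapshot) -> Tuple[int, Tuple[int, int, int, int, int, int]]:
    """CLIF organ-failure score: total (6-18) and the six subscores.

    Subscores come back in the order liver, kidney, brain, coagulation,
    circulation, respiration.
    """
    _require(snapshot, "bilirubin", "creatinine", "inr",
             "mean_arterial_pressure", "he_grade")

    if snapshot.bilirubin < 6.0:
        liver = 1
    elif snapshot.bilirubin < 12.0:
        liver = 2
    else:
        liver = 3

    if snapshot.on_rrt or snapshot.creatinine >= 3.5:
        kidney = 3
    elif snapshot.creatinine >= 2.0:
        kidney = 2
    else:
        kidney = 1

    if snapshot.he_grade == 0:
        brain = 1
    elif snapshot.he_grade <= 2:
        brain = 2
    else:
        brain = 3

    if snapshot.inr < 2.0:
        coag = 1
    elif snapshot.inr < 2.5:
        coag = 2
    else:
        coag = 3

    if snapshot.on_vasopressors:
        circ = 3
    elif snapshot.mean_arterial_pressure < 70.0:
        circ = 2
    else:
        circ = 1

    resp = _respiration_subscore(snapshot)

    subscores = (liver, kidney, brain, coag, circ, resp)
    return sum(subscores), subscores


def compute_clif_c_aclf(clif_of: float, age: float, wbc: float) -> float:
    """CLIF-C ACLF = 10 [0.33 CLIF-OF + 0.04 Age + 0.63 ln WBC - 2]."""
    if not 6 <= clif_of <= 18:
        raise DomainError(f"CLIF-OF must lie in [6, 18], got {clif_of}")
    if age < 18:
        raise DomainError(f"age must be >= 18, got {age}")
    if wbc <= 0:
        raise DomainError(f"WBC must be strictly positive, got {wbc}")
    return 10.0 * (0.33 * clif_of + 0.04 * age + 0.63 * math.log(wbc) - 2.0)


def compute_clif_c_ad(age: float, creatinine: float, inr: float,
                      wbc: float, sodium: float) -> float:
    """CLIF-C AD = 10 [0.03 Age + 0.66 ln Cr + 1.71 ln INR + 0.88 ln WBC
    - 0.05 Na + 8]."""
    if age < 18:
        raise DomainError(f"age must be >= 18, got {age}")
    for name, value in (("creatinine", creatinine), ("inr", inr),
                        ("wbc", wbc), ("sodium", sodium)):
        if value <= 0:
            raise DomainError(f"{name} must be strictly positive, got {value}")
    return 10.0 * (0.03 * age + 0.66 * math.log(creatinine) + 1.71 * math.log(inr)
                   + 0.88 * math.log(wbc) - 0.05 * sodium + 8.0)


def compute_scores(snapshot: PatientSnapshot) -> ScoreSet:
    """All scores for one patient.

    CLIF-C ACLF is attached when the patient meets the ACLF definition,
    CLIF-C AD otherwise — each score is specific to its target population.
    """
    ctp_points, klass = compute_ctp(snapshot)
    meld = resolve_meld(snapshot)
    meld_na = compute_meld_na(meld, snapshot.sodium)
    clif_of, subscores = compute_clif_of(snapshot)

    clif_c_aclf: Optional[float] = None
    clif_c_ad: Optional[float] = None
    if grading.assess_aclf(snapshot).has_aclf:
        clif_c_aclf = compute_clif_c_aclf(clif_of, snapshot.age, snapshot.wbc)
    else:
        clif_c_ad = compute_clif_c_ad(snapshot.age, snapshot.creatinine,
                                      snapshot.inr, snapshot.wbc, snapshot.sodium)

    return ScoreSet(
        ctp_points=ctp_points,
        ctp_class=klass,
        meld=meld,
        meld_na=meld_na,
        clif_of=clif_of,
        clif_of_subscores=subscores,
        clif_c_aclf=clif_c_aclf,
        clif_c_ad=clif_c_ad,
    )
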