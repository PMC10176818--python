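"""EASL-CLIF organ-failure assessment and ACLF diagnosis/grading.

Failure definitions (first-day state):

* liver        — total bilirubin >= 12 mg/dL
* coagulation  — INR >= 2.5
* kidney       — creatinine > 2 mg/dL (strict) or renal replacement therapy
* circulation  — vasopressor requirement
* respiration  — PaO2/FiO2 <= 200 or SpO2/FiO2 <= 214, or mechanical
  ventilation for reasons other than airway protection in the absence of
  HE grade III-IV
* brain        — HE grade III or IV (West Haven)

ACLF grading: grade 3 for >= 3 failures, grade 2 for exactly 2; a single
failure is grade 1 only when one of three sub-rules applies (single kidney
failure; single liver/coagulation/circulation/respiration failure with
creatinine 1.5-1.9 mg/dL and/or HE I-II; single brain failure with
creatinine 1.5-1.9 mg/dL).  Otherwise the patient is graded 0, i.e. acute
decompensation (AD) without ACLF.
"""

from __future__ import annotations

from .types import (
    ACLFAssessment,
    GradeRule,
    OrganFailurePanel,
    PatientSnapshot,
    _is_missing,
)

#: Closed creatinine band for the grade-1 sub-rules, mg/dL.  The upper edge
#: stops below the strict > 2 kidney-failure threshold; values in (1.9, 2.0]
#: fall outside the band by the literal wording of the rule.
CREATININE_BAND = (1.5, 1.9)


def respiratory_failure(snapshot: PatientSnapshot) -> bool:
    """Respiratory failure, including the ventilation caveat.

    Mechanical ventilation counts only when given for reasons other than
    airway protection and in the absence of HE grade III-IV (where the
    airway itself, not gas exchange, is usually the indication).
    """
    if not _is_missing(snapshot.pao2_fio2) and snapshot.pao2_fio2 <= 200:
        return True
    if not _is_missing(snapshot.spo2_fio2) and snapshot.spo2_fio2 <= 214:
        return True
    return (
        snapshot.on_mechanical_ventilation
        and not snapshot.mv_airway_protection_only
        and snapshot.he_grade < 3
    )


def assess_organ_failures(snapshot: PatientSnapshot) -> OrganFailurePanel:
    """Apply the six failure definitions to a first-day snapshot.

    A missing optional oxygenation ratio never triggers respiratory failure
    by itself.
    """
    return OrganFailurePanel(
        liver=snapshot.bilirubin >= 12.0,
        kidney=snapshot.creatinine > 2.0 or snapshot.on_rrt,
        brain=snapshot.he_grade >= 3,
        coagulation=snapshot.inr >= 2.5,
        circulation=snapshot.on_vasopressors,
        respiration=respiratory_failure(snapshot),
    )


def grade_aclf(panel: OrganFailurePanel, creatinine: float, he_grade: int) -> ACLFAssessment:
    """Grade ACLF from the failure panel plus creatinine and HE grade."""
    n = panel.n_failures
    if n >= 3:
        return ACLFAssessment(True, 3, GradeRule.THREE_PLUS_FAILURES)
    if n == 2:
        return ACLFAssessment(True, 2, GradeRule.TWO_FAILURES)
    if n == 1:
        in_band = CREATININE_BAND[0] <= creatinine <= CREATININE_BAND[1]
        if panel.kidney:
            return ACLFAssessment(True, 1, GradeRule.SINGLE_KIDNEY)
        if panel.brain:
            if in_band:
                return ACLFAssessment(True, 1, GradeRule.SINGLE_BRAIN_WITH_CR)
            return ACLFAssessment(False, 0, GradeRule.NONE)
        # single liver / coagulation / circulation / respiration failure:
        # creatinine band and/or mild-to-moderate (I-II) HE qualifies
        if in_band or he_grade in (1, 2):
            return ACLFAssessment(True, 1, GradeRule.SINGLE_OTHER_WITH_CR_OR_HE)
        return ACLFAssessment(False, 0, GradeRule.NONE)
    return ACLFAssessment(False, 0, GradeRule.NONE)


def assess_aclf(snapshot: PatientSnapshot) -> ACLFAssessment:
    """Convenience: organ-failure assessment followed by grading."""
    panel = assess_organ_failures(snapshot)
    return grade_aclf(panel, snapshot.creatinine, snapshot.he_grade)
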