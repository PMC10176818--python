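"""Seeded synthetic cohorts of cirrhotic acute-variceal-bleeding admissions.

The generator reproduces the statistical structure of the study cohort it
emulates: per-group (AD vs ACLF) lab marginals summarised as median (IQR),
organ-failure and organ-support prevalences, the ACLF grade mix, and
grade-dependent 42-day mortality under constant (exponential) hazards.
Strictly positive, right-skewed labs use a lognormal parameterised from the
median/IQR; sodium and mean arterial pressure use a truncated normal.

Stratum consistency is enforced constructively: each patient is first
assigned a stratum (AD or ACLF grade 1-3), then a set of failing organs is
drawn and the relevant labs/flags are sampled from their group marginals
*conditioned* on the failure thresholds (truncated draws), so that the
rule-based grading recovers the assigned stratum exactly.  Labs are drawn
independently within a stratum; correlation structure is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from . import grading, scores
from .types import DomainError, PatientSnapshot, SurvivalRecord

_Z75 = norm.ppf(0.75)  # 0.67449, quartile z-score


class GenerationError(RuntimeError):
    """The requested cohort specification could not be realised."""


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """Log-scale (mu, sigma) of the lognormal with the given median and IQR.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 z_0.75).  A degenerate
    spread (q1 = q3 = median) yields sigma = 0, a point mass.
    """
    if not (0 < q1 <= median <= q3):
        raise DomainError(
            f"need 0 < q1 <= median <= q3, got q1={q1}, median={median}, q3={q3}")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def normal_from_median_iqr(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """(mean, sd) of the normal with the given median and IQR."""
    if not q1 <= median <= q3:
        raise DomainError(
            f"need q1 <= median <= q3, got q1={q1}, median={median}, q3={q3}")
    return median, (q3 - q1) / (2.0 * _Z75)


def hazard_from_mortality(mortality: float, horizon: float) -> float:
    """Constant daily hazard whose exponential survival hits the given
    cumulative mortality at the horizon: rate = -ln(1 - mortality)/horizon."""
    if not 0 <= mortality < 1:
        raise DomainError(f"mortality must lie in [0, 1), got {mortality}")
    if horizon <= 0:
        raise DomainError(f"horizon must be positive, got {horizon}")
    return -math.log1p(-mortality) / horizon


# ---------------------------------------------------------------------------
# study-calibrated defaults (AD n=154, ACLF n=181 of 335 admissions)
# ---------------------------------------------------------------------------

#: median, q1, q3 per lab and group; lognormal family unless listed in
#: :data:`NORMAL_LABS`.
DEFAULT_LAB_PARAMS: Dict[str, Dict[str, Tuple[float, float, float]]] = {
    "AD": {
        "wbc": (7.7, 5.4, 11.3),
        "hemoglobin": (8.5, 7.3, 9.8),
        "bilirubin": (2.0, 1.1, 3.9),
        "albumin": (2.9, 2.8, 3.3),
        "inr": (1.6, 1.4, 1.8),
        "creatinine": (0.8, 0.7, 1.0),
        "potassium": (4.4, 4.0, 4.7),
        "spo2_fio2": (456.0, 198.0, 464.0),
        "sodium": (138.0, 135.0, 141.0),
        "mean_arterial_pressure": (79.0, 71.0, 87.0),
    },
    "ACLF": {
        "wbc": (13.9, 9.7, 20.8),
        "hemoglobin": (7.8, 6.9, 9.1),
        "bilirubin": (5.0, 2.6, 12.9),
        "albumin": (2.9, 2.4, 3.1),
        "inr": (2.0, 1.7, 2.7),
        "creatinine": (1.8, 1.1, 2.8),
        "potassium": (4.8, 4.2, 5.8),
        "spo2_fio2": (246.0, 138.0, 461.0),
        "sodium": (136.0, 130.0, 140.0),
        "mean_arterial_pressure": (72.0, 68.0, 78.0),
    },
}

#: approximately symmetric, bounded vitals drawn from a truncated normal
NORMAL_LABS = ("sodium", "mean_arterial_pressure")

DEFAULT_SUPPORT_PREVALENCE: Dict[str, Dict[str, float]] = {
    "AD": {"vasopressors": 12 / 154, "mechanical_ventilation": 38 / 154, "rrt": 0.0},
    "ACLF": {"vasopressors": 100 / 181, "mechanical_ventilation": 96 / 181, "rrt": 40 / 181},
}

#: organ-failure counts among the 181 ACLF admissions -> sampling weights
ACLF_FAILURE_WEIGHTS: Dict[str, float] = {
    "liver": 50, "kidney": 96, "brain": 78,
    "coagulation": 62, "circulation": 85, "respiration": 103,
}

#: single (non-qualifying) failures observed among the 154 AD admissions
AD_FAILURE_WEIGHTS: Dict[str, float] = {
    "liver": 4, "kidney": 0, "brain": 16,
    "coagulation": 2, "circulation": 9, "respiration": 2,
}
AD_SINGLE_FAILURE_PROB = sum(AD_FAILURE_WEIGHTS.values()) / 154  # 33/154

#: number of failing organs within grade 3 (>= 3 required; mix is a modelling
#: choice, most grade-3 patients sit near the minimum)
GRADE3_FAILURE_COUNT_WEIGHTS = {3: 0.55, 4: 0.27, 5: 0.13, 6: 0.05}

DEFAULT_HE_DIST = {  # P(none), P(I-II), P(III-IV) at admission
    "AD": (96 / 154, 42 / 154, 16 / 154),
    "ACLF": (38 / 181, 65 / 181, 78 / 181),
}
DEFAULT_ASCITES_PREVALENCE = {"AD": 63 / 154, "ACLF": 137 / 181}
DEFAULT_MALE_PROPORTION = {"AD": 101 / 154, "ACLF": 128 / 181}
DEFAULT_AGE = {"AD": (55.7, 12.1), "ACLF": (54.9, 11.7)}  # mean, sd
RRT_GIVEN_KIDNEY_FAILURE = 40 / 96


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; defaults are study-calibrated."""

    n: int = 335
    aclf_prevalence: float = 181 / 335
    grade_mix: Tuple[float, float, float] = (0.182, 0.337, 0.481)
    lab_params: Dict[str, Dict[str, Tuple[float, float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_LAB_PARAMS.items()})
    organ_support_prevalence: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_SUPPORT_PREVALENCE.items()})
    mortality_by_stratum: Dict[str, float] = field(
        default_factory=lambda: {"AD": 0.084, "grade1": 0.225,
                                 "grade2": 0.342, "grade3": 0.638})
    follow_up_days: float = 42.0
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n <= 0:
            raise DomainError("n must be positive")
        if not 0 <= self.aclf_prevalence <= 1:
            raise DomainError("aclf_prevalence must lie in [0, 1]")
        if abs(sum(self.grade_mix) - 1.0) > 1e-9:
            raise DomainError("grade_mix must sum to 1")
        if any(p < 0 for p in self.grade_mix):
            raise DomainError("grade_mix proportions must be non-negative")
        for m in self.mortality_by_stratum.values():
            if not 0 <= m < 1:
                raise DomainError("stratum mortality must lie in [0, 1)")
        if self.follow_up_days <= 0:
            raise DomainError("follow_up_days must be positive")
        for group, labs in self.lab_params.items():
            for name, (median, q1, q3) in labs.items():
                if not (0 < q1 <= median <= q3):
                    raise DomainError(f"{group}/{name}: need 0 < q1 <= median <= q3")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# truncated draws
# ---------------------------------------------------------------------------

_EPS = 1e-12


def _trunc_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                     low: float = 0.0, high: float = math.inf) -> float:
    """One draw from Lognormal(mu, sigma) conditioned on [low, high]."""
    if sigma == 0.0:
        return min(max(math.exp(mu), low), high)
    a = ndtr((math.log(low) - mu) / sigma) if low > 0 else 0.0
    b = ndtr((math.log(high) - mu) / sigma) if math.isfinite(high) else 1.0
    u = a + rng.random() * (b - a)
    u = min(max(u, _EPS), 1.0 - _EPS)
    return math.exp(mu + sigma * ndtri(u))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  low: float = 0.0, high: float = math.inf) -> float:
    if sd == 0.0:
        return min(max(mean, low), high)
    a = ndtr((low - mean) / sd) if math.isfinite(low) else 0.0
    b = ndtr((high - mean) / sd) if math.isfinite(high) else 1.0
    u = a + rng.random() * (b - a)
    u = min(max(u, _EPS), 1.0 - _EPS)
    return mean + sd * ndtri(u)


def _draw_lab(rng: np.random.Generator, spec: CohortSpec, group: str, name: str,
              low: float = 0.0, high: float = math.inf) -> float:
    median, q1, q3 = spec.lab_params[group][name]
    if name in NORMAL_LABS:
        mean, sd = normal_from_median_iqr(median, q1, q3)
        return _trunc_normal(rng, mean, sd, max(low, 0.0), high)
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    return _trunc_lognormal(rng, mu, sigma, low, high)


def _below(x: float) -> float:
    return float(np.nextafter(x, -math.inf))


def _above(x: float) -> float:
    return float(np.nextafter(x, math.inf))


# ---------------------------------------------------------------------------
# single-patient construction
# ---------------------------------------------------------------------------


def _choose_failures(rng: np.random.Generator, grade: int) -> List[str]:
    """Failing organs for the assigned stratum."""
    if grade == 0:
        if rng.random() >= AD_SINGLE_FAILURE_PROB:
            return []
        organs = list(AD_FAILURE_WEIGHTS)
        w = np.array([AD_FAILURE_WEIGHTS[o] for o in organs], dtype=float)
        return [organs[rng.choice(len(organs), p=w / w.sum())]]
    if grade == 1:
        k = 1
    elif grade == 2:
        k = 2
    else:
        counts = list(GRADE3_FAILURE_COUNT_WEIGHTS)
        probs = np.array([GRADE3_FAILURE_COUNT_WEIGHTS[c] for c in counts])
        k = int(rng.choice(counts, p=probs / probs.sum()))
    organs = list(ACLF_FAILURE_WEIGHTS)
    w = np.array([ACLF_FAILURE_WEIGHTS[o] for o in organs], dtype=float)
    idx = rng.choice(len(organs), size=k, replace=False, p=w / w.sum())
    return [organs[i] for i in sorted(idx)]


def _draw_he(rng: np.random.Generator, group: str, allowed_max2: bool) -> int:
    """HE grade from the group distribution, optionally restricted to 0-II."""
    p_none, p_mild, p_severe = DEFAULT_HE_DIST[group]
    if allowed_max2:
        total = p_none + p_mild
        u = rng.random() * total
        band = 0 if u < p_none else 1
    else:
        u = rng.random()
        band = 0 if u < p_none else (1 if u < p_none + p_mild else 2)
    if band == 0:
        return 0
    if band == 1:
        return int(rng.integers(1, 3))  # I or II
    return int(rng.integers(3, 5))  # III or IV


def _build_snapshot(rng: np.random.Generator, spec: CohortSpec,
                    patient_id: str, grade: int) -> PatientSnapshot:
    group = "ACLF" if grade >= 1 else "AD"
    failures = _choose_failures(rng, grade)
    fail = {organ: (organ in failures) for organ in
            ("liver", "kidney", "brain", "coagulation", "circulation", "respiration")}

    # creatinine / HE constraints from the grade rules
    cr_low, cr_high = 0.0, 2.0  # not kidney-failed by default
    he_forced: Optional[int] = None
    he_max2 = not fail["brain"]
    if fail["kidney"]:
        cr_low, cr_high = _above(2.0), math.inf
    if grade == 0 and failures:
        # a single failure must NOT satisfy any grade-1 sub-rule
        cr_high = _below(1.5)
        if not fail["brain"]:
            he_forced = 0
    if grade == 1 and not fail["kidney"]:
        if fail["brain"]:
            cr_low, cr_high = 1.5, 1.9
        elif rng.random() < 0.5:
            cr_low, cr_high = 1.5, 1.9  # qualify via the creatinine band
        else:
            he_forced = int(rng.integers(1, 3))  # qualify via HE I-II

    creatinine = _draw_lab(rng, spec, group, "creatinine", cr_low, cr_high)

    if he_forced is not None:
        he_grade = he_forced
    elif fail["brain"]:
        he_grade = int(rng.integers(3, 5))
    else:
        he_grade = _draw_he(rng, group, allowed_max2=True)

    bilirubin = _draw_lab(rng, spec, group, "bilirubin",
                          *( (12.0, math.inf) if fail["liver"] else (0.0, _below(12.0)) ))
    inr = _draw_lab(rng, spec, group, "inr",
                    *( (2.5, math.inf) if fail["coagulation"] else (0.0, _below(2.5)) ))
    if fail["respiration"]:
        spo2_fio2 = _draw_lab(rng, spec, group, "spo2_fio2", 0.0, 214.0)
    else:
        spo2_fio2 = _draw_lab(rng, spec, group, "spo2_fio2", _above(214.0), math.inf)

    support = spec.organ_support_prevalence[group]
    on_vasopressors = fail["circulation"]
    on_rrt = fail["kidney"] and (rng.random() < RRT_GIVEN_KIDNEY_FAILURE)
    on_mv = rng.random() < support["mechanical_ventilation"]
    # ventilation of a patient without respiratory failure and without deep HE
    # must be airway-protective only, or it would itself constitute failure
    mv_airway_only = bool(on_mv and not fail["respiration"] and he_grade < 3)

    snapshot = PatientSnapshot(
        patient_id=patient_id,
        age=_trunc_normal(rng, *DEFAULT_AGE[group], low=18.0),
        sex="male" if rng.random() < DEFAULT_MALE_PROPORTION[group] else "female",
        bilirubin=bilirubin,
        albumin=_draw_lab(rng, spec, group, "albumin"),
        inr=inr,
        creatinine=creatinine,
        sodium=_draw_lab(rng, spec, group, "sodium"),
        potassium=_draw_lab(rng, spec, group, "potassium"),
        wbc=_draw_lab(rng, spec, group, "wbc"),
        hemoglobin=_draw_lab(rng, spec, group, "hemoglobin"),
        mean_arterial_pressure=_draw_lab(rng, spec, group, "mean_arterial_pressure"),
        he_grade=he_grade,
        ascites_grade=(int(rng.integers(1, 3))
                       if rng.random() < DEFAULT_ASCITES_PREVALENCE[group] else 0),
        spo2_fio2=spo2_fio2,
        on_vasopressors=on_vasopressors,
        on_mechanical_ventilation=on_mv,
        mv_airway_protection_only=mv_airway_only,
        on_rrt=on_rrt,
    )
    return snapshot


_MAX_RETRIES = 100


def generate_cohort(spec: CohortSpec) -> Tuple[List[PatientSnapshot], List[SurvivalRecord]]:
    """Draw a full cohort; deterministic given ``spec.seed``.

    Every generated snapshot round-trips through the rule-based grading to
    its assigned stratum; a snapshot that fails to (possible only at exact
    threshold ties) is redrawn up to a bounded retry count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    stratum_names = {0: "AD", 1: "grade1", 2: "grade2", 3: "grade3"}
    hazards = {g: hazard_from_mortality(spec.mortality_by_stratum[s], spec.follow_up_days)
               for g, s in stratum_names.items()}

    snapshots: List[PatientSnapshot] = []
    records: List[SurvivalRecord] = []
    grade_values = np.array([1, 2, 3])
    grade_probs = np.asarray(spec.grade_mix, dtype=float)
    grade_probs = grade_probs / grade_probs.sum()

    for i in range(spec.n):
        if rng.random() < spec.aclf_prevalence:
            grade = int(rng.choice(grade_values, p=grade_probs))
        else:
            grade = 0
        pid = f"P{i:05d}"
        snapshot = None
        for _ in range(_MAX_RETRIES):
            candidate = _build_snapshot(rng, spec, pid, grade)
            candidate.validate()
            if grading.assess_aclf(candidate).grade == grade:
                snapshot = candidate
                break
        if snapshot is None:
            raise GenerationError(
                f"could not realise stratum grade={grade} within {_MAX_RETRIES} draws; "
                "check the lab parameters against the failure thresholds")

        rate = hazards[grade]
        if rate == 0.0:
            time, event = spec.follow_up_days, False
        else:
            t = rng.exponential(1.0 / rate)
            if t >= spec.follow_up_days:
                time, event = spec.follow_up_days, False
            else:
                time, event = float(t), True

        snapshots.append(snapshot)
        records.append(SurvivalRecord(
            patient_id=pid,
            group="ACLF" if grade >= 1 else "AD",
            grade=grade,
            time=time,
            event=event,
            scores=scores.compute_scores(snapshot),
        ))
    return snapshots, records


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "patient_id", "age", "sex", "bilirubin", "albumin", "inr", "creatinine",
    "sodium", "potassium", "wbc", "hemoglobin", "mean_arterial_pressure",
    "pao2_fio2", "spo2_fio2", "he_grade", "ascites_grade", "on_vasopressors",
    "on_mechanical_ventilation", "mv_airway_protection_only", "on_rrt",
    "meld_precomputed", "group", "aclf_grade", "time", "event",
]


def cohort_to_frame(snapshots: List[PatientSnapshot],
                    records: List[SurvivalRecord]) -> pd.DataFrame:
    """One row per admission in the documented cohort CSV schema."""
    rows = []
    for snap, rec in zip(snapshots, records):
        row = dataclasses.asdict(snap)
        for flag in ("on_vasopressors", "on_mechanical_ventilation",
                     "mv_airway_protection_only", "on_rrt"):
            row[flag] = int(row[flag])
        row.update(group=rec.group, aclf_grade=rec.grade,
                   time=rec.time, event=int(rec.event))
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(frame: pd.DataFrame, path, spec: Optional[CohortSpec] = None) -> None:
    """Write the cohort CSV plus a JSON sidecar echoing the generating spec.

    A fixed float format keeps reruns under the same seed byte-identical.
    """
    frame.to_csv(path, index=False, float_format="%.10g")
    if spec is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump(spec.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_frame(spec: CohortSpec) -> pd.DataFrame:
    snapshots, records = generate_cohort(spec)
    return cohort_to_frame(snapshots, records)
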