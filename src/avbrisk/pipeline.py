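"""End-to-end orchestration: cohort in, report tables out.

The pipeline mirrors the structure of a prognostic-validation study on
cirrhotic acute variceal bleeding: baseline comparison of AD vs ACLF
admissions, Kaplan-Meier/log-rank survival by group and by ACLF grade,
univariate plus backward-stepwise multivariate Cox regression on 42-day
mortality, and per-score discrimination/calibration/overall performance
computed separately within the ACLF stratum (CTP, MELD, MELD-Na, CLIF-C
ACLF) and the AD stratum (CTP, MELD, MELD-Na, CLIF-C AD) — each CLIF-C
score is validated only in its target population.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import evaluation, grading, scores
from .cohort import CohortSpec
from .types import DomainError, PatientSnapshot

log = logging.getLogger("avbrisk")

REQUIRED_COLUMNS = [
    "patient_id", "age", "sex", "bilirubin", "albumin", "inr", "creatinine",
    "sodium", "potassium", "wbc", "hemoglobin", "mean_arterial_pressure",
    "he_grade", "ascites_grade", "on_vasopressors", "on_mechanical_ventilation",
    "mv_airway_protection_only", "on_rrt",
]

#: per-stratum score lists; the CLIF-C scores are population-specific
ACLF_SCORES = ["ctp", "meld", "meld_na", "clif_c_aclf"]
AD_SCORES = ["ctp", "meld", "meld_na", "clif_c_ad"]

NUMERIC_BASELINE_VARS = [
    "age", "mean_arterial_pressure", "spo2_fio2", "wbc", "hemoglobin",
    "bilirubin", "albumin", "inr", "creatinine", "sodium", "potassium",
    "ctp", "meld", "meld_na",
]
CATEGORICAL_BASELINE_VARS = [
    "sex", "ascites_any", "he_band", "on_vasopressors",
    "on_mechanical_ventilation", "on_rrt",
]

COX_CANDIDATES = [
    "has_aclf", "age", "female", "mean_arterial_pressure", "wbc", "hemoglobin",
    "albumin", "bilirubin", "inr", "creatinine", "sodium", "potassium",
    "ascites_any",
]


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or load one from CSV."""

    mode: str  # "simulate" | "load"
    out_dir: Path
    input_path: Optional[Path] = None
    spec: Optional[CohortSpec] = None
    horizon: float = 42.0
    seed: Optional[int] = None
    make_figures: bool = False
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.mode not in ("simulate", "load"):
            raise DomainError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load" and self.input_path is None:
            raise DomainError("load mode requires input_path")
        if self.mode == "simulate" and self.input_path is not None:
            raise DomainError("exactly one of input_path / spec may be given")
        if self.horizon <= 0:
            raise DomainError("horizon must be positive")
        return self


def load_cohort(path) -> pd.DataFrame:
    """Read and schema-check a cohort CSV (wide, one row per admission)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"cohort CSV {path} lacks required columns: {missing}")
    has_ratio = pd.Series(False, index=df.index)
    for c in ("pao2_fio2", "spo2_fio2"):
        if c in df.columns:
            has_ratio |= df[c].notna()
    if not has_ratio.all():
        rows = list(df.index[~has_ratio][:5])
        raise DomainError(
            f"rows {rows} lack both oxygenation ratios (pao2_fio2/spo2_fio2)")
    return df


def snapshot_from_row(row) -> PatientSnapshot:
    def _opt(name):
        value = getattr(row, name, None)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        return float(value)

    return PatientSnapshot(
        patient_id=str(row.patient_id),
        age=float(row.age),
        sex=str(row.sex),
        bilirubin=float(row.bilirubin),
        albumin=float(row.albumin),
        inr=float(row.inr),
        creatinine=float(row.creatinine),
        sodium=float(row.sodium),
        potassium=float(row.potassium),
        wbc=float(row.wbc),
        hemoglobin=float(row.hemoglobin),
        mean_arterial_pressure=float(row.mean_arterial_pressure),
        he_grade=int(row.he_grade),
        ascites_grade=int(row.ascites_grade),
        pao2_fio2=_opt("pao2_fio2"),
        spo2_fio2=_opt("spo2_fio2"),
        on_vasopressors=bool(row.on_vasopressors),
        on_mechanical_ventilation=bool(row.on_mechanical_ventilation),
        mv_airway_protection_only=bool(row.mv_airway_protection_only),
        on_rrt=bool(row.on_rrt),
        meld_precomputed=_opt("meld_precomputed"),
    )


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Compute scores and ACLF grades for every row of a cohort frame."""
    out = df.copy()
    computed: Dict[str, list] = {k: [] for k in (
        "ctp", "ctp_class", "meld", "meld_na", "clif_of", "n_failures",
        "aclf_grade", "has_aclf", "grade_rule", "clif_c_aclf", "clif_c_ad")}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            snap = snapshot_from_row(row).validate()
        except DomainError as exc:
            raise DomainError(f"row {i} (patient_id={row.patient_id}): {exc}") from exc
        panel = grading.assess_organ_failures(snap)
        assessment = grading.grade_aclf(panel, snap.creatinine, snap.he_grade)
        ss = scores.compute_scores(snap)
        computed["ctp"].append(ss.ctp_points)
        computed["ctp_class"].append(ss.ctp_class)
        computed["meld"].append(ss.meld)
        computed["meld_na"].append(ss.meld_na)
        computed["clif_of"].append(ss.clif_of)
        computed["n_failures"].append(panel.n_failures)
        computed["aclf_grade"].append(assessment.grade)
        computed["has_aclf"].append(int(assessment.has_aclf))
        computed["grade_rule"].append(assessment.rule_applied.value)
        computed["clif_c_aclf"].append(ss.clif_c_aclf)
        computed["clif_c_ad"].append(ss.clif_c_ad)
    for name, values in computed.items():
        out[name] = values
    out["group"] = np.where(out["has_aclf"] == 1, "ACLF", "AD")
    out["ascites_any"] = (out["ascites_grade"] > 0).astype(int)
    out["female"] = (out["sex"] == "female").astype(int)
    out["he_band"] = pd.cut(out["he_grade"], bins=[-1, 0, 2, 4],
                            labels=["none", "I-II", "III-IV"])
    return out


def _fmt_median_iqr(x: pd.Series) -> str:
    return f"{x.median():.1f} ({x.quantile(0.25):.1f}-{x.quantile(0.75):.1f})"


def baseline_table(scored: pd.DataFrame) -> pd.DataFrame:
    """AD-vs-ACLF baseline comparison with distribution-routed tests."""
    ad = scored[scored["group"] == "AD"]
    aclf = scored[scored["group"] == "ACLF"]
    rows = []
    for var in NUMERIC_BASELINE_VARS:
        if var not in scored.columns or scored[var].isna().all():
            continue
        a = ad[var].dropna().to_numpy()
        b = aclf[var].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        test, statistic, p = evaluation.group_compare(a, b)
        rows.append({"variable": var, "ad": _fmt_median_iqr(ad[var]),
                     "aclf": _fmt_median_iqr(aclf[var]),
                     "test": test, "statistic": statistic, "p": p})
    for var in CATEGORICAL_BASELINE_VARS:
        if var not in scored.columns:
            continue
        table = pd.crosstab(scored["group"], scored[var])
        if table.shape[0] < 2 or table.shape[1] < 2:
            continue
        test, statistic, p = evaluation.group_compare(table.to_numpy())
        summary = {g: "/".join(str(v) for v in table.loc[g]) for g in table.index}
        rows.append({"variable": var, "ad": summary.get("AD", ""),
                     "aclf": summary.get("ACLF", ""),
                     "test": test, "statistic": statistic, "p": p})
    return pd.DataFrame(rows)


def survival_summary(scored: pd.DataFrame, horizon: float) -> dict:
    """KM survival at the horizon by group and grade, with log-rank tests."""
    out: dict = {"horizon_days": horizon, "by_group": {}, "by_grade": {}}
    for group, sub in scored.groupby("group"):
        out["by_group"][group] = {
            "n": int(len(sub)),
            "deaths": int(sub["event"].sum()),
            "survival_pct": round(100 * evaluation.km_estimate(
                sub["time"], sub["event"].astype(bool), horizon), 1),
        }
    _, p_group = evaluation.log_rank(scored["time"], scored["event"].astype(bool),
                                     scored["group"])
    out["log_rank_p_group"] = p_group
    for grade, sub in scored.groupby("aclf_grade"):
        if sub["event"].sum() == 0 and len(sub) == 0:
            continue
        out["by_grade"][str(int(grade))] = {
            "n": int(len(sub)),
            "deaths": int(sub["event"].sum()),
            "mortality_pct": round(100 * (1 - evaluation.km_estimate(
                sub["time"], sub["event"].astype(bool), horizon)), 1),
        }
    if scored["aclf_grade"].nunique() > 1:
        _, p_grade = evaluation.log_rank(scored["time"], scored["event"].astype(bool),
                                         scored["aclf_grade"])
        out["log_rank_p_grade"] = p_grade
    return out


def cox_tables(scored: pd.DataFrame, alpha: float = 0.05):
    """Univariate screen plus backward-stepwise multivariate Cox model."""
    candidates = [c for c in COX_CANDIDATES
                  if c in scored.columns and scored[c].notna().all()
                  and np.ptp(scored[c].astype(float)) > 0]
    final, univariate = evaluation.backward_stepwise(scored, candidates, alpha=alpha)
    uni_rows = []
    for c, res in univariate.items():
        uni_rows.append({"covariate": c, "HR": res.hazard_ratio[c],
                         "ci_low": res.ci_low[c], "ci_high": res.ci_high[c],
                         "p": res.p_value[c]})
    uni = pd.DataFrame(uni_rows)
    multi = final.summary_frame().reset_index(names="covariate") if final.covariates \
        else pd.DataFrame(columns=["covariate", "coef", "HR", "ci_low", "ci_high", "p"])
    return uni, multi, final


def performance_table(scored: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Per-score validation inside one stratum ('ACLF' or 'AD')."""
    sub = scored[scored["group"] == stratum]
    score_names = ACLF_SCORES if stratum == "ACLF" else AD_SCORES
    rows = []
    for name in score_names:
        values = sub[name]
        mask = values.notna()
        y = sub.loc[mask, "event"].astype(bool).to_numpy()
        if y.sum() == 0 or (~y).sum() == 0:
            warnings.warn(f"stratum {stratum}: outcome degenerate, skipping {name}",
                          RuntimeWarning, stacklevel=2)
            continue
        perf = evaluation.evaluate_score(name, values[mask].to_numpy(), y)
        row = dataclasses.asdict(perf)
        row.pop("calibration_bins")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write its report bundle.

    Writes, under ``config.out_dir``: the (scored) cohort CSV, the baseline
    table, survival/log-rank JSON, Cox tables, per-stratum performance
    tables and a consolidated ``metrics.json``.  Returns the metrics bundle.
    Outputs are deterministic given the seed.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        spec = config.spec or CohortSpec()
        if config.seed is not None:
            spec = dataclasses.replace(spec, seed=config.seed)
        log.info("simulating cohort: n=%d seed=%d", spec.n, spec.seed)
        df = cohort_mod.simulate_frame(spec)
        cohort_mod.write_cohort(df, out_dir / "cohort.csv", spec)
    else:
        df = load_cohort(config.input_path)

    scored = score_frame(df)
    scored.to_csv(out_dir / "scored.csv", index=False, float_format="%.10g")

    metrics: dict = {"n": int(len(scored)),
                     "n_aclf": int((scored["group"] == "ACLF").sum()),
                     "n_ad": int((scored["group"] == "AD").sum())}

    baseline = baseline_table(scored)
    baseline.to_csv(out_dir / "baseline_table.csv", index=False, float_format="%.6g")

    has_outcome = "time" in scored.columns and "event" in scored.columns
    if not has_outcome or scored["event"].sum() == 0:
        warnings.warn("no events in cohort: survival/Cox/performance evaluation "
                      "skipped; scoring and grading outputs were still written",
                      RuntimeWarning, stacklevel=2)
        metrics["evaluation"] = None
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
        return metrics

    surv = survival_summary(scored, config.horizon)
    uni, multi, _ = cox_tables(scored)
    uni.to_csv(out_dir / "cox_univariate.csv", index=False, float_format="%.6g")
    multi.to_csv(out_dir / "cox_multivariate.csv", index=False, float_format="%.6g")

    perf = {}
    for stratum in ("ACLF", "AD"):
        table = performance_table(scored, stratum)
        table.to_csv(out_dir / f"performance_{stratum.lower()}.csv",
                     index=False, float_format="%.6g")
        perf[stratum] = table.to_dict(orient="records")

    metrics.update(survival=surv,
                   cox_univariate=uni.to_dict(orient="records"),
                   cox_multivariate=multi.to_dict(orient="records"),
                   performance=perf)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    if config.make_figures:
        _write_figures(scored, out_dir, config.horizon)
    return metrics


def _write_figures(scored: pd.DataFrame, out_dir: Path, horizon: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for group, sub in scored.groupby("group"):
        KaplanMeierFitter(label=group).fit(
            sub["time"], sub["event"].astype(bool)).plot_survival_function(ax=axes[0])
    axes[0].set(title="Survival by group", xlabel="days", ylabel="S(t)")
    for grade, sub in scored.groupby("aclf_grade"):
        label = "AD" if grade == 0 else f"ACLF grade {int(grade)}"
        KaplanMeierFitter(label=label).fit(
            sub["time"], sub["event"].astype(bool)).plot_survival_function(ax=axes[1])
    axes[1].set(title="Survival by ACLF grade", xlabel="days")
    fig.tight_layout()
    fig.savefig(out_dir / "km_curves.png", dpi=150)
    plt.close(fig)
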