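"""Statistical validation of prognostic scores against 42-day mortality.

Covers the full validation toolbox: distribution-routed two-group
comparisons, Kaplan-Meier / log-rank survival, Cox proportional hazards with
backward stepwise selection, ROC discrimination with DeLong inference,
Youden operating points and confusion metrics, logistic score recalibration,
Hosmer-Lemeshow and calibration curves, Brier score and Nagelkerke R².

Kaplan-Meier, log-rank and Cox fits are delegated to lifelines (Efron tie
handling); logistic recalibration to statsmodels; routed univariate tests to
scipy/statsmodels.  DeLong variance components, the Hosmer-Lemeshow
statistic, Youden scanning, equal-count calibration bins and Nagelkerke R²
are computed here directly.

Conventions: higher score means higher risk; the classification rule is
``score >= cutoff``; all p-values are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
import statsmodels.api as sm

from .types import DomainError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# group comparison with normality routing
# ---------------------------------------------------------------------------

def group_compare(values_a, values_b=None) -> Tuple[str, float, float]:
    """Two-group comparison routed by a Kolmogorov-Smirnov normality check.

    Numeric inputs: a KS (Lilliefors) test on the pooled sample decides the
    route — p > 0.05 means approximately normal and a two-sample t-test is
    used, otherwise Mann-Whitney.  A 2-D contingency table (with
    ``values_b=None``) is compared by chi-square.

    Returns ``(test_name, statistic, p_value)``.
    """
    if values_b is None:
        table = np.asarray(values_a, dtype=float)
        if table.ndim != 2:
            raise DomainError("contingency-table input must be 2-D")
        if table.size == 0 or (table < 0).any():
            raise DomainError("contingency table must be complete and non-negative")
        stat, p, _, _ = stats.chi2_contingency(table)
        return "chi_square", float(stat), float(p)

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # degenerate constant sample: normality undefined, ranks carry it
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return "mann_whitney", float(stat), float(p)
    _, ks_p = lilliefors(pooled, dist="norm")
    if ks_p > ALPHA:
        stat, p = stats.ttest_ind(a, b)
        return "t_test", float(stat), float(p)
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann_whitney", float(stat), float(p)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_estimate(times: Sequence[float], events: Sequence[bool], at: float) -> float:
    """Product-limit survival probability at time ``at``."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise DomainError("km_estimate needs at least one record")
    if (times <= 0).any():
        raise DomainError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    return float(kmf.predict(at))


def log_rank(times: Sequence[float], events: Sequence[bool],
             labels: Sequence) -> Tuple[float, float]:
    """k-sample log-rank chi-square (k-1 df) and its p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DomainError("log-rank needs at least two non-empty groups")
    if not events.any():
        raise DomainError("log-rank statistic undefined with no events")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Fitted Cox proportional-hazards summary."""

    covariates: List[str]
    coef: Dict[str, float]
    hazard_ratio: Dict[str, float]
    ci_low: Dict[str, float]
    ci_high: Dict[str, float]
    p_value: Dict[str, float]
    log_likelihood: float
    converged: bool = True
    flagged: List[str] = field(default_factory=list)  # suspect (separation) coefficients

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef,
            "HR": self.hazard_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_value,
        }).loc[self.covariates]


_SEPARATION_COEF = 10.0  # |log-HR| beyond this on standardized-ish clinical data


def cox_fit(data: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "time", event_col: str = "event") -> CoxResult:
    """Cox PH fit (Efron ties) with Wald CIs and p-values per covariate."""
    covariates = list(covariates)
    if not covariates:
        return CoxResult([], {}, {}, {}, {}, {}, log_likelihood=float("nan"))
    if data[event_col].sum() < 1:
        raise DomainError("Cox fit needs at least one event")
    for c in covariates:
        if np.ptp(np.asarray(data[c], dtype=float)) == 0:
            raise DomainError(f"covariate '{c}' is constant (non-identifiable)")

    df = data[[duration_col, event_col, *covariates]].astype(float)
    fitter = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fitter.fit(df, duration_col=duration_col, event_col=event_col,
                       fit_options={"precision": 1e-10})
        except Exception as exc:  # monotone likelihood etc.
            raise DomainError(f"Cox fit failed to converge: {exc}") from exc
        converged = not any("onvergence" in str(w.message) for w in caught)

    summary = fitter.summary
    flagged = [c for c in covariates if abs(summary.loc[c, "coef"]) > _SEPARATION_COEF]
    if flagged or not converged:
        warnings.warn(
            f"possible monotone likelihood / separation in covariates {flagged}",
            RuntimeWarning, stacklevel=2)
    return CoxResult(
        covariates=covariates,
        coef={c: float(summary.loc[c, "coef"]) for c in covariates},
        hazard_ratio={c: float(summary.loc[c, "exp(coef)"]) for c in covariates},
        ci_low={c: float(summary.loc[c, "exp(coef) lower 95%"]) for c in covariates},
        ci_high={c: float(summary.loc[c, "exp(coef) upper 95%"]) for c in covariates},
        p_value={c: float(summary.loc[c, "p"]) for c in covariates},
        log_likelihood=float(fitter.log_likelihood_),
        converged=converged,
        flagged=flagged,
    )


def backward_stepwise(data: pd.DataFrame, candidates: Sequence[str],
                      alpha: float = ALPHA, duration_col: str = "time",
                      event_col: str = "event") -> Tuple[CoxResult, Dict[str, CoxResult]]:
    """Univariate screen at ``alpha`` then backward elimination by Wald p.

    Returns the final multivariate fit and the per-candidate univariate
    fits.  Ties in the worst p-value break on input order (first listed is
    removed).  An empty post-screen set yields an empty model, not an error.
    """
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    univariate: Dict[str, CoxResult] = {}
    retained = []
    for c in candidates:
        res = cox_fit(data, [c], duration_col, event_col)
        univariate[c] = res
        if res.p_value[c] < alpha:
            retained.append(c)

    while retained:
        fit = cox_fit(data, retained, duration_col, event_col)
        worst = max(retained, key=lambda c: (fit.p_value[c], -retained.index(c)))
        if fit.p_value[worst] < alpha:
            return fit, univariate
        retained.remove(worst)
    return CoxResult([], {}, {}, {}, {}, {}, log_likelihood=float("nan")), univariate


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def _check_two_class(outcomes: np.ndarray) -> None:
    if outcomes.all() or not outcomes.any():
        raise DomainError("both outcome classes must be present")


def roc_auc(score: Sequence[float], outcomes: Sequence[bool]) -> float:
    """AUC via the rank (Mann-Whitney) estimator; ties count one half."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    _check_two_class(y)
    ranks = stats.rankdata(s)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(score: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (cases) and V01."""
    pos = score[y]
    neg = score[~y]
    # psi(x, y) = 1[x > y] + 0.5 1[x == y], vectorised over all pairs
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return float(psi.mean()), v10, v01


def delong_ci(score: Sequence[float], outcomes: Sequence[bool],
              level: float = 0.95) -> Tuple[float, float, Tuple[float, float]]:
    """Single-score DeLong AUC, variance, and Wald confidence interval."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    _check_two_class(y)
    auc, v10, v01 = _delong_components(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, float(var), (max(0.0, auc - half), min(1.0, auc + half))


def delong_test(score_1: Sequence[float], score_2: Sequence[float],
                outcomes: Sequence[bool]) -> Tuple[float, float, np.ndarray, float, float]:
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns ``(auc_1, auc_2, covariance, z, p)``.  A zero-variance
    difference with a zero AUC difference (identical rankings) gives
    z = 0, p = 1; a zero variance with a non-zero difference is degenerate.
    """
    s1 = np.asarray(score_1, dtype=float)
    s2 = np.asarray(score_2, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s1.shape != s2.shape or s1.shape != y.shape:
        raise DomainError("paired scores must share the subject axis")
    _check_two_class(y)
    auc1, v10_1, v01_1 = _delong_components(s1, y)
    auc2, v10_2, v01_2 = _delong_components(s2, y)
    v10 = np.vstack([v10_1, v10_2])
    v01 = np.vstack([v01_1, v01_2])
    cov = np.cov(v10) / v10.shape[1] + np.cov(v01) / v01.shape[1]
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc1 - auc2
    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            return auc1, auc2, cov, 0.0, 1.0
        raise DomainError("degenerate DeLong variance with unequal AUCs")
    z = diff / np.sqrt(var_diff)
    p = 2 * stats.norm.sf(abs(z))
    return auc1, auc2, cov, float(z), float(p)


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def youden_cutoff(score: Sequence[float], outcomes: Sequence[bool]
                  ) -> Tuple[float, float, float, float]:
    """Cutoff maximising Youden's J over the observed score values.

    The classification rule is ``score >= cutoff``.  Ties in J break
    toward the smallest cutoff (maximal sensitivity).
    Returns ``(cutoff, J, sensitivity, specificity)``.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    _check_two_class(y)
    best = None
    for c in np.unique(s):  # ascending, so first max wins = smallest cutoff
        pred = s >= c
        sens = float((pred & y).sum() / y.sum())
        spec = float((~pred & ~y).sum() / (~y).sum())
        j = youden_index(sens, spec)
        if best is None or j > best[1] + 1e-12:
            best = (float(c), j, sens, spec)
    return best


def confusion_metrics(score: Sequence[float], outcomes: Sequence[bool],
                      cutoff: float) -> Tuple[float, float, float, float]:
    """Sensitivity, specificity, PPV and NPV at ``score >= cutoff``.

    An empty predicted-positive or predicted-negative margin leaves the
    corresponding predictive value NaN (flagged by a warning) rather than
    silently zero.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    _check_two_class(y)
    pred = s >= cutoff
    tp = float((pred & y).sum())
    fp = float((pred & ~y).sum())
    fn = float((~pred & y).sum())
    tn = float((~pred & ~y).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no predicted positives: PPV undefined", RuntimeWarning, stacklevel=2)
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no predicted negatives: NPV undefined", RuntimeWarning, stacklevel=2)
        npv = float("nan")
    else:
        npv = tn / (tn + fn)
    return sens, spec, ppv, npv


# ---------------------------------------------------------------------------
# calibration and overall performance
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """Univariable logistic recalibration of a score to event probabilities."""

    probabilities: np.ndarray
    intercept: float
    slope: float
    separation: bool = False


_PROB_CLIP = 1e-10


def score_to_risk(score: Sequence[float], outcomes: Sequence[bool]) -> RiskModel:
    """Maximum-likelihood logistic recalibration of outcome on score.

    Raw prognostic scores are not probabilities; this is the standard bridge
    to the probability scale needed by Hosmer-Lemeshow, calibration curves
    and the Brier score.  Under complete separation the fitted probabilities
    are clamped away from 0/1 and the model is flagged.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _check_two_class(y.astype(bool))
    X = sm.add_constant(s)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            params = np.asarray(fit.params, dtype=float)
        except Exception:
            separation = True
            params = None
        else:
            separation = any("erfect" in str(w.message) or "eparation" in str(w.message)
                             for w in caught) or np.abs(params[1]) > 50
    if params is None:
        # fall back to the separation limit: a hard step at the class boundary
        boundary = (s[y == 1].min() + s[y == 0].max()) / 2
        probs = np.where(s >= boundary, 1.0 - _PROB_CLIP, _PROB_CLIP)
        return RiskModel(probs, float("nan"), float("nan"), separation=True)
    probs = np.clip(1 / (1 + np.exp(-(params[0] + params[1] * s))),
                    _PROB_CLIP, 1 - _PROB_CLIP)
    if separation:
        warnings.warn("separation detected in logistic recalibration; "
                      "probabilities clamped", RuntimeWarning, stacklevel=2)
    return RiskModel(probs, float(params[0]), float(params[1]), separation=separation)


def _equal_count_bins(probabilities: np.ndarray, outcomes: np.ndarray,
                      n_bins: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    # stable sort by probability: tied probabilities keep input order
    order = np.argsort(probabilities, kind="stable")
    return [(probabilities[idx], outcomes[idx])
            for idx in np.array_split(order, n_bins) if idx.size]


def hosmer_lemeshow(probabilities: Sequence[float], outcomes: Sequence[bool],
                    groups: int = 10) -> Tuple[float, float]:
    """Hosmer-Lemeshow chi-square over deciles of risk (``groups - 2`` df).

    Bins are equal-count after a stable sort on predicted probability.
    A bin with zero expected events (or non-events) is merged into its
    neighbour with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if groups < 2:
        raise DomainError("need at least 2 groups")
    if p.size < groups:
        raise DomainError("need at least as many observations as groups")
    bins = _equal_count_bins(p, y, groups)

    merged: List[Tuple[np.ndarray, np.ndarray]] = []
    for pb, yb in bins:
        expected = pb.sum()
        if merged and (expected == 0 or expected == pb.size):
            warnings.warn("merging a degenerate Hosmer-Lemeshow bin",
                          RuntimeWarning, stacklevel=2)
            prev_p, prev_y = merged.pop()
            merged.append((np.concatenate([prev_p, pb]), np.concatenate([prev_y, yb])))
        else:
            merged.append((pb, yb))

    statistic = 0.0
    for pb, yb in merged:
        n = pb.size
        expected = pb.sum()
        observed = yb.sum()
        mean_p = expected / n
        denom = n * mean_p * (1 - mean_p)
        if denom > 0:
            statistic += (observed - expected) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return float(statistic), float(stats.chi2.sf(statistic, df))


def brier(probabilities: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Mean squared error of probabilistic predictions."""
    p = np.asarray(probabilities, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DomainError("probabilities must lie in [0, 1]")
    y = np.asarray(outcomes, dtype=float)
    return float(np.mean((p - y) ** 2))


def r_squared(probabilities: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Nagelkerke pseudo-R² from the fitted and null Bernoulli likelihoods."""
    p = np.clip(np.asarray(probabilities, dtype=float), _PROB_CLIP, 1 - _PROB_CLIP)
    y = np.asarray(outcomes, dtype=float)
    n = y.size
    prevalence = y.mean()
    if prevalence in (0.0, 1.0):
        raise DomainError("both outcome classes must be present")
    ll_fit = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    ll_null = float(n * (prevalence * np.log(prevalence)
                         + (1 - prevalence) * np.log1p(-prevalence)))
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_fit) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    return float(cox_snell / max_cs)


def calibration_curve(probabilities: Sequence[float], outcomes: Sequence[bool],
                      bins: int = 10) -> List[Tuple[float, float, int]]:
    """Equal-count calibration bins: (mean predicted, observed rate, n).

    The count-weighted mean of observed rates equals the overall prevalence.
    """
    if bins < 2:
        raise DomainError("need at least 2 bins")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    return [(float(pb.mean()), float(yb.mean()), int(pb.size))
            for pb, yb in _equal_count_bins(p, y, bins)]


# ---------------------------------------------------------------------------
# per-score bundle
# ---------------------------------------------------------------------------

@dataclass
class ScorePerformance:
    """Discrimination, calibration and overall performance of one score."""

    score_name: str
    n: int
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    cutoff: float
    youden: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    brier: float
    r_squared: float
    hl_statistic: float
    hl_p: float
    calibration_bins: List[Tuple[float, float, int]]


def evaluate_score(name: str, score: Sequence[float], outcomes: Sequence[bool],
                   hl_groups: int = 10, calibration_bins: int = 10) -> ScorePerformance:
    """Full single-score evaluation against a binary 42-day outcome."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    auc, _, (lo, hi) = delong_ci(s, y)
    cutoff, j, sens, spec = youden_cutoff(s, y)
    _, _, ppv, npv = confusion_metrics(s, y, cutoff)
    risk = score_to_risk(s, y)
    hl_stat, hl_p = hosmer_lemeshow(risk.probabilities, y, groups=min(hl_groups, max(2, s.size // 5)))
    return ScorePerformance(
        score_name=name,
        n=int(s.size),
        auc=auc, auc_ci_low=lo, auc_ci_high=hi,
        cutoff=cutoff, youden=j, sensitivity=sens, specificity=spec,
        ppv=ppv, npv=npv,
        brier=brier(risk.probabilities, y),
        r_squared=r_squared(risk.probabilities, y),
        hl_statistic=hl_stat, hl_p=hl_p,
        calibration_bins=calibration_curve(risk.probabilities, y,
                                           bins=min(calibration_bins, max(2, s.size // 5))),
    )
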