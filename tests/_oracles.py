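"""Independent brute-force oracles used by the test suite.

Each oracle re-derives its quantity from first principles (enumeration,
hand tabulation, direct likelihood maximisation) without calling the
implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize_scalar

ORGANS = ("liver", "kidney", "brain", "coagulation", "circulation", "respiration")


def brute_force_grade(flags: Dict[str, bool], creatinine: float, he_grade: int) -> int:
    """Literal re-coding of the ACLF grading rules.

    >= 3 failures -> grade 3; exactly 2 -> grade 2; a single failure is
    grade 1 iff (a) it is the kidney, (b) it is liver/coagulation/
    circulation/respiration with creatinine 1.5-1.9 mg/dL and/or HE I-II,
    or (c) it is the brain with creatinine 1.5-1.9 mg/dL; else grade 0.
    """
    failed = [o for o in ORGANS if flags[o]]
    n = len(failed)
    if n >= 3:
        return 3
    if n == 2:
        return 2
    if n == 0:
        return 0
    organ = failed[0]
    band = 1.5 <= creatinine <= 1.9
    if organ == "kidney":
        return 1
    if organ == "brain":
        return 1 if band else 0
    return 1 if (band or he_grade in (1, 2)) else 0


def auc_by_enumeration(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """AUC as the average over all case-control pairs (ties count 1/2)."""
    scores = list(map(float, scores))
    cases = [s for s, y in zip(scores, outcomes) if y]
    controls = [s for s, y in zip(scores, outcomes) if not y]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def youden_by_enumeration(scores: Sequence[float], outcomes: Sequence[bool]
                          ) -> Tuple[float, float, float, float]:
    """Scan every observed threshold under the `score >= cutoff` rule;
    smallest cutoff wins ties on J."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    best = None
    for c in sorted(set(scores.tolist())):
        sens = float(((scores >= c) & y).sum() / y.sum())
        spec = float(((scores < c) & ~y).sum() / (~y).sum())
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12:
            best = (c, j, sens, spec)
    return best


def cox_binary_mle(times: Sequence[float], events: Sequence[bool],
                   x: Sequence[float]) -> float:
    """1-D Cox partial-likelihood maximiser by direct numeric optimisation.

    Assumes no tied event times, where Efron and Breslow coincide with the
    exact partial likelihood.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    assert len(np.unique(times[events])) == events.sum(), "oracle requires no ties"

    def neg_log_pl(beta: float) -> float:
        total = 0.0
        for t in times[events]:
            at_risk = times >= t
            i = np.flatnonzero(events & (times == t))[0]
            total += beta * x[i] - math.log(np.sum(np.exp(beta * x[at_risk])))
        return -total

    res = minimize_scalar(neg_log_pl, bounds=(-20, 20), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def log_rank_by_tabulation(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square by explicit observed-minus-expected
    tabulation over the distinct event times."""
    times = np.concatenate([times_a, times_b]).astype(float)
    events = np.concatenate([events_a, events_b]).astype(bool)
    group = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events].tolist())):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e ** 2 / var)


def hosmer_lemeshow_by_tabulation(bin_probs: List[np.ndarray],
                                  bin_outcomes: List[np.ndarray]) -> float:
    """Sum of (O - E)^2 / (n p(1-p)) over explicitly supplied bins."""
    stat = 0.0
    for p, y in zip(bin_probs, bin_outcomes):
        n = len(p)
        e = float(np.sum(p))
        o = float(np.sum(y))
        mean_p = e / n
        stat += (o - e) ** 2 / (n * mean_p * (1 - mean_p))
    return stat


def km_by_product_limit(times, events, at: float) -> float:
    """Hand product-limit estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    s = 1.0
    for t in sorted(set(times[events].tolist())):
        if t > at:
            break
        n_at_risk = (times >= t).sum()
        d = (events & (times == t)).sum()
        s *= 1 - d / n_at_risk
    return s


def logistic_irls(x: Sequence[float], y: Sequence[bool],
                  tol: float = 1e-12, max_iter: int = 200) -> Tuple[float, float]:
    """Hand-written Newton/IRLS for intercept + slope logistic regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(beta[0]), float(beta[1])


def all_failure_combinations():
    """All 2^6 organ-failure flag dictionaries."""
    for bits in itertools.product((False, True), repeat=6):
        yield dict(zip(ORGANS, bits))
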