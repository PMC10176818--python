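# Methods

## Clinical scores

**Child-Turcotte-Pugh.** The INR-based component table is used: bilirubin
<2 / 2–3 / >3 mg/dL, albumin >3.5 / 2.8–3.5 / <2.8 g/dL, INR <1.7 / 1.7–2.3
/ >2.3, ascites none / mild / moderate-severe, hepatic encephalopathy (HE)
none / I–II / III–IV, each scored 1–3; classes A 5–6, B 7–9, C 10–15. INR
rather than prothrombin time is used for the coagulation component because
INR is the coagulation variable the cohort schema collects.

**MELD.** The UNOS formula 9.57 ln(creatinine) + 3.78 ln(bilirubin) +
11.2 ln(INR) + 6.43 (mg/dL, dimensionless INR), with each analyte floored at
1.0, creatinine capped at 4.0 mg/dL and set to 4.0 under renal replacement
therapy (RRT), rounded to the nearest integer. ICU databases usually
distribute a precomputed MELD; a `meld_precomputed` column overrides the
formula so that cohort-supplied values can be reproduced exactly. Classic
MELD (not the sodium-revised variant) is assumed since MELD-Na is computed
separately from it.

**MELD-Na.** MELD + 1.59 (135 − Na) with sodium clamped into [120, 135]
mEq/L; the clamp guarantees MELD-Na ≥ MELD with equality iff Na ≥ 135.

**CLIF-OF.** Six organ subscores in {1,2,3}: liver bilirubin <6 / 6–<12 /
≥12 mg/dL; kidney creatinine <2 / 2–<3.5 / ≥3.5 mg/dL or RRT; brain HE 0 /
I–II / III–IV; coagulation INR <2 / 2–<2.5 / ≥2.5; circulation MAP ≥70 /
<70 mmHg / vasopressors; respiration PaO₂/FiO₂ >300 / ≤300 / ≤200
(SpO₂/FiO₂ >357 / ≤357 / ≤214), preferring PaO₂/FiO₂ when both ratios are
present. The respiratory subscore-3 condition is exactly the respiratory
*failure* definition, including the ventilation caveat below. Subscore 3
coincides with organ failure for five of the six organs; the kidney is the
exception by construction — kidney *failure* is creatinine > 2 mg/dL
(strict) or RRT, i.e. subscore ≥ 2 or RRT, while subscore 3 keeps the
published ≥ 3.5 mg/dL band.

**CLIF-C ACLF / CLIF-C AD.** Linear formulas (see README). Neither is
rounded, so outputs are exactly testable; each is computed only for its
target population (with / without ACLF respectively). Apart from MELD's
integer rounding and 1-decimal report formatting, no rounding is applied
anywhere.

## ACLF diagnosis and grading

Organ failures on first-day worst values: liver bilirubin ≥ 12 mg/dL;
coagulation INR ≥ 2.5; kidney creatinine > 2 mg/dL or RRT; circulation
vasopressor requirement; respiration PaO₂/FiO₂ ≤ 200 or SpO₂/FiO₂ ≤ 214 or
mechanical ventilation given for reasons other than airway protection in
the absence of HE III–IV; brain HE III–IV. A missing oxygenation ratio
never triggers respiratory failure by itself.

Grading: ≥3 failures → grade 3; exactly 2 → grade 2; a single failure is
grade 1 iff (a) it is the kidney, (b) it is liver/coagulation/circulation/
respiration with creatinine 1.5–1.9 mg/dL and/or HE I–II ("and/or" is a
logical OR), or (c) it is the brain with creatinine 1.5–1.9 mg/dL; anything
else is grade 0, i.e. acute decompensation (AD) without ACLF. The
creatinine band is read literally as the closed interval [1.5, 1.9]; values
in (1.9, 2.0] qualify no sub-rule (a measure-zero sliver under continuous
labs). Kidney failure reached through RRT at low creatinine still counts as
"single kidney failure". The HE clause of sub-rule (b) is taken as West
Haven I–II; covert/minimal HE is not modelled.

## Synthetic cohort generator

The generator emulates a 335-admission ICU cohort of cirrhotic AVB:
54% ACLF (grade mix 18.2/33.7/48.1%), per-group (AD vs ACLF) lab summaries
given as median (IQR), organ-support prevalences, HE/ascites distributions,
and 42-day mortality of 8.4% (AD), 22.5% (grade 1), 34.2% (grade 2) and
63.8% (grade 3). Those figures are the generator's defaults; every one can
be overridden through `CohortSpec`.

*Distribution families.* Strictly positive, right-skewed labs use a
lognormal with mu = ln(median) and sigma = (ln q3 − ln q1)/(2 z₀.₇₅),
z₀.₇₅ ≈ 0.6745. A two-parameter lognormal reproduces the median and the
quartile *ratio* q3/q1 exactly; when the printed quartiles are asymmetric
on the log scale the individual quartiles are approximated (the tests pin
the unconstrained labs to within 5% on the median and 7% on each quartile).
Sodium and mean arterial pressure, approximately symmetric and bounded, use
a truncated normal with sd = IQR/(2 z₀.₇₅).

*Stratum consistency.* Each patient is assigned a stratum first; a set of
failing organs is then drawn (weights proportional to the observed
organ-failure counts: within ACLF liver/kidney/brain/coagulation/
circulation/respiration = 50/96/78/62/85/103; within AD the single
non-qualifying failures 4/0/16/2/9/2 with overall probability 33/154) and
the relevant labs are drawn from their group marginals *truncated* at the
failure thresholds, so the rule-based grading recovers the assigned stratum
by construction. Grade-1 patients qualify through the kidney, the
creatinine band, or HE I–II (the two non-kidney routes are used with equal
probability); AD patients carrying a single failure are forced below every
grade-1 sub-rule. Within grade 3 the failure count 3/4/5/6 is drawn with
weights 0.55/0.27/0.13/0.05 — the study reports no within-grade failure
distribution, and most grade-3 patients sit near the minimum. Ventilated
patients who must not meet respiratory failure are marked as
airway-protective ventilation unless HE III–IV already explains the
ventilation. A bounded retry (100 draws) guards the exact-threshold edge;
an unrealisable stratum raises a generation error.

*Outcomes.* Death times are exponential with the constant stratum hazard
−ln(1 − mortality)/42 per day, censored administratively at day 42, and
kept continuous to avoid ties in survival fits. Only 42-day totals are
reported by such studies, so the constant-hazard shape is an assumption,
not an inference.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: labs are independent within stratum (no inter-lab
correlation structure); the hazard depends on the stratum only, so within a
stratum the scores carry no survival signal beyond their association with
grade. Within-stratum discrimination (AUCs) of the synthetic cohort is
therefore structurally modest and is not calibrated to any real cohort's
AUC. Longitudinal trajectories, treatment effects and transplant competing
risks are out of scope.

## Evaluation

*Group comparisons.* A Kolmogorov-Smirnov normality check (Lilliefors,
estimated parameters) on the pooled sample routes numeric variables to a
two-sample t-test (p > 0.05, i.e. compatible with normality) or Mann-Whitney
otherwise; categorical variables use chi-square. All p-values two-sided at
alpha = 0.05.

*Survival.* Kaplan-Meier product-limit estimates and the k-sample log-rank
test (k−1 df) are delegated to lifelines. Cox proportional-hazards fits use
lifelines with Efron tie handling and a Newton precision of 1e-10 (so that
coefficients agree with a direct partial-likelihood maximiser to ≤1e-6);
Wald CIs and p-values per covariate. Backward stepwise selection screens
candidates univariately at alpha, then repeatedly drops the largest
Wald p until all retained p < alpha; ties break on input order. Monotone
likelihood is flagged (|log-HR| > 10) with a warning rather than silently
reported.

*Discrimination.* AUC is the rank/Mann-Whitney estimator (ties count ½),
identical to the trapezoidal area under the empirical ROC. DeLong
structural components provide the single-AUC variance/Wald CI (clipped to
[0,1]) and the paired two-score z-test; identical rankings short-circuit to
z = 0, p = 1, while a zero-variance difference with unequal AUCs is an
error. The operating convention throughout is higher score = higher risk
and `score >= cutoff` = predicted event; the Youden scan maximises
sensitivity + specificity − 1 over observed values and breaks ties toward
the smallest cutoff (maximal sensitivity). Empty predicted margins leave
PPV/NPV as flagged NaN.

*Calibration and overall performance.* Raw scores are not probabilities;
they are bridged to the probability scale by univariable logistic
recalibration (maximum likelihood via statsmodels), with clamping to
(1e-10, 1 − 1e-10) and a separation flag when the fit degenerates.
Hosmer-Lemeshow uses equal-count bins after a stable sort (tied
probabilities keep input order), the statistic Σ (O−E)²/(n p̄(1−p̄)) with
groups − 2 df, and merges degenerate bins with a warning. Calibration
curves use the same equal-count binning; the count-weighted mean of
observed rates equals the overall prevalence by construction. Overall
performance is the Brier score (mean squared error) and Nagelkerke's
pseudo-R² computed from the fitted and null Bernoulli log-likelihoods.
Which R² such studies report is typically unstated; Nagelkerke is the
conventional choice and is what this package means by R².

## Pipeline

The cohort CSV schema is wide (one row per admission), snake_case, with HE
as ordinal 0–4, ascites 0–2, flags 0/1 and missing optional oxygenation
ratios as empty cells; first-day worst-value aggregation is the loader's
concern only for long-format input (wide input is taken as aggregated).
The report bundle comprises the baseline AD-vs-ACLF table, survival by
group and grade with log-rank tests, univariate and stepwise Cox tables,
and per-stratum score-performance tables — CLIF-C ACLF evaluated only
within the ACLF stratum and CLIF-C AD only within AD. The outcome horizon
is fixed at 42 days. Transplanted patients receive no special censoring. A
zero-event cohort skips evaluation with an explicit warning but still
writes scoring/grading outputs. All outputs are deterministic given the
seed; CSV floats use a fixed `%.10g` format so reruns are byte-identical.

## Problem sizes

The statistical tests run at the sizes that make their guarantees sharp yet
cheap: marginal/mortality recovery on one shared 10,000-patient cohort;
grade-mortality recovery at 10,000 per stratum; Cox parameter recovery at
n = 5,000 (≈650 events, log-HR SE ≈ 0.086); DeLong-vs-bootstrap at n = 200
with 10,000 resamples; stepwise-selection behaviour over 100 replicates of
n = 250. The analysis drivers use the study-sized n = 335, where grade-level
mortality estimates are accordingly noisy (a grade-1 stratum of ~30 patients
has a ±15pp binomial 95% interval).

## Known limitations

* The generator's independence and constant-hazard assumptions make
  within-stratum calibration/discrimination targets synthetic; only
  stratum-level quantities (grade mix, mortality, survival contrasts) are
  calibrated to the emulated cohort.
* The grade-1 creatinine band edge (1.9 vs 2.0) and the covert-HE question
  are resolved by fiat (literal reading; HE I–II); both affect only
  threshold-straddling patients.
* Backward stepwise selection inherits the usual instability of stepwise
  procedures; pure-noise covariates that survive the univariate screen are
  retained in a non-trivial fraction of replicates, which the tests bound
  rather than eliminate.
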