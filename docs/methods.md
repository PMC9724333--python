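# Methods

## The design

`graymatch` operationalizes a two-stage restriction design for estimating the
effect of red-cell transfusion on a composite adverse outcome (death or any
in-hospital complication) from observational perioperative data.

**Base population.** Major surgery (anesthesiologist present), hospital stay
≥ 24 h, not residing at 2000–5000 m altitude (where transfusion thresholds do
not transfer). This emulates the inclusion rules of conventional
observational transfusion studies and is deliberately heterogeneous.

**Trigger value.** Time is discrete: measurement occasions are admission,
pre-op, and post-operative days 1..k; transfusion events carry half-integer
occasion indices strictly between measurements. The trigger value is the
hemoglobin at the greatest occasion strictly before the first transfusion
(exposed) or the minimum over all in-stay measurements, including the
preoperative ones (controls). Ties at one occasion resolve to the minimum
value. A transfused patient with no measurement before their first event is
unresolvable and excluded with a count. Whether the exposed trigger is pre-
or postoperative is not constrained; the occasion index is recorded.

**Study population.** Base members with no intraoperative bleeding ≥ 500 mL
and trigger value inside the gray-zone window, default [7.5, 9.5] g/dL with
*inclusive* bounds (the bracket semantics are not dictated by convention; the
window is configurable). Any sub-10 upper bound automatically excludes
transfusion at Hb ≥ 10 g/dL, i.e. beyond the clinical standard.

**Balance monitoring.** SMDs in percent, binary form using the p(1−p)
population variance exactly as written, continuous form using the unbiased
sample variance. Multi-level covariates are dichotomized before entry
(ASA ≥ 3, age ≥ 75). Propensity-score overlap is summarized as per-group
quantiles plus the interval [max of minima, min of maxima].

**Propensity model and matching.** Maximum-likelihood logistic regression of
transfusion on ASA ≥ 3, preoperative hemoglobin, operation ≥ 3 h, bleeding
≥ 500 mL and ICU admission (base population); the study set drops bleeding,
which is excluded by design. Matching is greedy 1:1 nearest-neighbor without
replacement. The caliper is 0.2 × SD of the score, SD pooled over both
groups, on the raw probability scale by default; the common logit-scale
convention is a flag (`caliper_on_logit`). Exposed members are processed in
seeded random order (descending-score order selectable); distance ties break
to the smallest control identifier, making results fully deterministic given
the seed.

**Effect estimation.** Odds ratios from unconditional multivariable logistic
regression, Wald 95% CIs on the log scale, two-tailed α = 0.05. Adjustment
sets: ASA ≥ 3, age ≥ 75, any preoperative comorbidity (any of hypertension,
coronary heart disease, diabetes, stroke, COPD — the coding is configurable),
preoperative hemoglobin, operation ≥ 3 h, plus bleeding and ICU admission in
the base population. Matched sets are analyzed with ordinary (unconditional)
logistic regression; a conditional-on-pair variant is a config flag, default
off, because pair membership is not part of the estimand here. The crude 2×2
cross-product OR with SE = √(1/a+1/b+1/c+1/d) serves as a closed-form oracle;
a zero cell raises an error unless the Haldane–Anscombe 0.5 correction is
requested. Complete-case handling throughout: rows missing a model covariate
are dropped at model time with logged counts; no imputation.

Logistic fits use statsmodels' Newton/IRLS maximum-likelihood machinery
(monotone likelihood ascent, 100-iteration budget); non-convergence,
perfect separation, and quasi-separation (|coefficient| > 50) raise typed
errors rather than returning silently unstable estimates.

## The synthetic cohort generator

No real perioperative dataset ships with the package, so the generator
produces cohorts whose *statistical structure* — not whose data-generating
coefficients — mirrors a multicenter cohort of older general-surgery
inpatients. All coefficients are artifact inventions, calibrated once by
simulation against the published marginal distributions; there is no claim of
matching the real process.

Per patient: demographics and comorbidity flags are independent Bernoullis /
normals at the configured margins (male 52%, ASA ≥ 3 23%, operation ≥ 3 h
22%, ICU ≈ 9.5%, bleeding ≈ 2% short-op / 15% long-op, preoperative
hemoglobin N(13.5, 1.8²) g/dL, age 60 + Exp(8.2) years). The counterfactual
(never-transfused) hemoglobin trajectory drops after surgery by
1.2 + 0.8·(long op) + 3.0·(bleeding) ± 0.7 g/dL and then recovers by
N(0.35, 0.25²) g/dL per day; all values clip to [3, 20] g/dL.

**Transfusion decision.** At each post-operative occasion, a Bernoulli draw
with logit = b₀ + 1.4·(9 − lowest Hb so far) + 1.6·bleeding + 0.7·ASA≥3 +
0.6·long-op. The intercept b₀ is solved by bisection at run time so the
expected ever-transfused rate equals the configured target (default 10.8%) —
exact for the first event because the running minimum is unaffected by later
transfusions. Each transfusion raises all subsequent measurements by 1 g/dL
(configurable), so transfusion probability rises steeply below ~9 g/dL and
the marginal rate is stable across sample sizes.

**Outcome.** Composite-outcome logit = c₀ + s·[burden(nadir) + 1.0·bleeding +
0.8·ASA≥3] + 0.5·(age ≥ 75) + 0.4·(any comorbidity) + β·transfused, where
s is `confounding_strength` (0 switches confounding off), β is
`true_transfusion_log_or` (default 0, an exact null), and the anemia burden
is a linear spline in the *counterfactual* nadir: 0 above 10 g/dL,
0.18/g/dL through the 7.5–10 gray zone, an additional 1.2/g/dL below
7.5 g/dL. Two of these choices are load-bearing:

- *Counterfactual nadir.* Using the observed (post-transfusion) trajectory
  would give transfusion a mechanical protective pathway and β would no
  longer be the causal effect; the untransfused trajectory keeps β = 0 an
  exact null, which the coverage tests require.
- *Spline rather than a single slope.* The gray zone is a gray zone
  precisely because outcome risk is relatively insensitive to hemoglobin
  within it; a single steep slope would build residual confounding into the
  study population that no measured-covariate adjustment could remove,
  contradicting the design premise being simulated. Severe anemia below the
  restrictive threshold carries the steep risk, and it is what the gray-zone
  restriction excludes.

The intercept c₀ is again solved analytically for the target marginal outcome
rate (default 5.7%). Realized outcomes are split into death / ischemic /
infection / other components at fixed conditional proportions (18/13/50/19%).
An optional switch injects ≤7% missing operation times to exercise
complete-case handling (default off). A 1% high-altitude flag exercises the
exclusion filter.

**What the generator does not emulate.** Hospital/site effects, surgical
specialty structure, competing risks, long-term outcomes, continuous
timestamps, correlated comorbidities, and informative measurement schedules.
Passing tests therefore demonstrate that the pipeline removes
indication-confounding of the kind modeled — selection on hemoglobin,
bleeding and physical status — not that it would de-bias any real dataset,
where unmeasured confounding and outcome-transfusion temporality remain.

## Problem sizes and numerical choices

- Calibration-sensitive properties run at n = 50,000 (crude-OR bias under the
  null and its removal in the matched study population) and 200 replicates of
  n = 6,000 (CI coverage of the null in Study Match+, accepted in the 90–99%
  band). Replicates whose matched-set fit is inestimable (separation or too
  few events at ~100 pairs) are excluded from the coverage denominator and
  must not exceed 10% of replicates.
- Intercept bisection: 80 iterations on [−25, 10], deterministic.
- Matching is O(exposed × controls) with exact tie-breaking; at the sizes
  here (≤ ~5,000 exposed) this is faster and simpler than a tree-based
  neighbor search.
- Degenerate inputs: zero pooled variance yields SMD 0 (equal summaries) or
  +∞ (different); empty groups are typed errors; empty cohorts flow through
  the filters with zero counts.

## Known limitations

- The SMD threshold (10%) and the caliper rule (0.2 SD) are conventions, not
  optimized quantities.
- Greedy matching is order-dependent by nature; the seeded random order makes
  it reproducible, not optimal. Optimal/full matching and weighting are out
  of scope.
- The adjusted base-population OR understates the paradox relative to the
  crude OR because, unlike in real data, all confounders except the
  within-window anemia severity are measured and correctly specified here;
  the crude OR is the headline bias quantity in the tests.
- Trigger semantics assume measurement occasions are comparable across
  patients; calendar-time modeling is not attempted.
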