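# graymatch

**Hemoglobin-based observational study design for surgical transfusion-outcome
research.**

Observational studies persistently find that red-cell transfusion is
associated with higher mortality and morbidity, while randomized trials of
restrictive versus liberal transfusion thresholds do not — the "transfusion
kills patients" paradox. The driver is confounding by indication: the clinical
reasons for transfusing (anemia, active bleeding) independently predict bad
outcomes, and propensity-score matching alone does not fix it.

`graymatch` implements a cohort-design pipeline that addresses the paradox at
the design stage rather than the analysis stage:

1. **Redefine the study population** to the *gray zone* of the transfusion
   decision — patients whose hemoglobin sits in a stable range (default
   7.5–9.5 g/dL) where clinical equipoise genuinely exists. This excludes, by
   construction, active bleeding (≥500 mL), unexplained non-transfusion at
   severe anemia, and transfusion beyond the clinical standard (Hb ≥ 10 g/dL).
2. **Define exposure groups by a trigger value**: the last hemoglobin
   measurement before the initial transfusion (exposed) or the in-stay nadir
   (controls), so both groups are compared at the same decision criterion.
3. **Monitor patient heterogeneity** throughout with the standardized mean
   difference (SMD), in percent:

   SMD = |x̄₁ − x̄₂| / √((s₁² + s₂²)/2) × 100%  (continuous)
   SMD = |p₁ − p₂| / √((p₁(1−p₁) + p₂(1−p₂))/2) × 100%  (binary)

   with SMD < 10% read as a minor difference.

Effects are estimated as odds ratios from multivariable logistic regression
(Wald 95% CIs) on four datasets: the base population before/after 1:1
nearest-neighbor propensity-score matching (caliper 0.2 SD of the score), and
the gray-zone study population before/after matching.

Because the motivating clinical dataset is not public, the package includes a
seeded synthetic perioperative cohort generator that reproduces the
confounding-by-indication structure (transfusion decided on the current
hemoglobin; anemia, bleeding, ASA ≥ 3 and long operations driving both
transfusion and the composite outcome) with a configurable — by default null —
true transfusion effect. It is first-class, tested code: every downstream
stage is validated against it.

Intended users: epidemiologists and biostatisticians designing or teaching
real-world-evidence studies of transfusion (or other indication-confounded
interventions), and methodologists who need a reproducible test bed for
design-based confounding control.

## Worked example

```bash
graymatch simulate --n 50000 --seed 1 --out sim/
graymatch analyze --patients sim/patients.csv --hemoglobin sim/hemoglobin.csv \
    --transfusions sim/transfusions.csv --seed 1 --out report/
```

prints (true transfusion effect = null, OR 1.0):

```
BaseMatchMinus: n=46045, OR 1.27 (95% CI 1.10-1.47)
BaseMatchPlus: n=5722, OR 1.13 (95% CI 0.91-1.41)
StudyMatchMinus: n=3282, OR 1.09 (95% CI 0.80-1.50)
StudyMatchPlus: n=2246, OR 1.09 (95% CI 0.76-1.56)
```

and `report/effects.csv` carries the crude odds ratios alongside:

| dataset         | crude OR (95% CI)  | adjusted OR (95% CI) |
|-----------------|--------------------|----------------------|
| Base Match−     | 2.88 (2.62–3.16)   | 1.27 (1.10–1.47)     |
| Base Match+     | 1.12 (0.90–1.39)   | 1.13 (0.91–1.41)     |
| Study Match−    | 1.12 (0.84–1.49)   | 1.09 (0.80–1.50)     |
| Study Match+    | 1.07 (0.75–1.53)   | 1.09 (0.76–1.56)     |

Read it like this: the naive base-population comparison says transfusion
triples the odds of death-or-complication (crude OR 2.88) even though the
simulated truth is null; restricting to the gray zone collapses the bias
(Study Match− crude OR 1.12), and after matching the CI comfortably covers
1.0. The balance trajectory in `report/balance_trajectory.csv` shows why:
SMDs of the strong indications fall from 88.5% (bleeding), 76.0% (operation
time) and 135.2% (preoperative hemoglobin) in Base Match− to ≤1% in Study
Match+. `report/manifest.json` records the seed and every per-filter
exclusion count.

The same analysis runs from the library (`graymatch.run_four_dataset_analysis`)
for use in notebooks or simulation studies; a sensitivity window (default
8–10 g/dL) is analyzed alongside the main one.

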