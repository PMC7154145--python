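# touchlimits

Simulation and analysis toolkit for yes/no tactile detection studies run
with von Frey filaments and the method of limits, built around a question
that matters for interpreting "elevated thresholds" in clinical groups:
**is a higher measured threshold a sensory deficit, or a more conservative
decision criterion?**

Signal detection theory separates the two. From a session's hit rate *H*
(over stimulus trials) and false-alarm rate *F* (over catch trials, i.e.
trials with no stimulus), the package computes the equal-variance
sensitivity index

> A_z = Φ((Φ⁻¹(H) − Φ⁻¹(F)) / 2)

and the response criterion

> c = −(Φ⁻¹(H) + Φ⁻¹(F)) / 2,

where Φ is the standard normal CDF; c > 0 means a conservative observer who
says "no" when unsure.  Perfect or empty counts are replaced by the
log-linear correction (k + 0.5)/(n + 1) before the quantile transform.

Because a criterion difference masquerades as a threshold difference under
the method of limits, the package pairs the estimator with a generative
observer model — evidence X ~ Normal(d(force), 1), answer "yes" iff
X > λ, with d(f) = max(0, β·(log₁₀ f − log₁₀ α) + 1) — so that every
statistic can be validated by parameter recovery on cohorts with known
ground truth.

What's inside (`src/touchlimits/`):

- `sdt` — corrected rates, A_z, c.
- `observer` — the generative observer and cohort simulator (ASD/NT ×
  child/adult groups with age, sex, IQ and SRS-2 covariates).
- `protocol` — the four-block alternating ascending/descending staircase
  over a 10-filament 0.008–2.0 g ladder, with 3 catch trials per ascending
  and 7 per descending block, two-consecutive-response termination,
  before/after threshold averaging, and the catch-trial exclusion rule.
- `stats` — Cliff's dominance delta with consistent-variance CI, Spearman
  correlations, Zou's CI for comparing independent correlations, Pearson
  χ² without continuity correction, ICC(3,k).
- `cpm` — a cumulative probability model (proportional-odds regression
  treating each distinct outcome value as an ordered category; the
  multi-predictor generalisation of the Wilcoxon–Mann–Whitney test), with
  Wald/LR/score inference, Nagelkerke R², and best-subset BIC selection
  with BIC weights and approximate Bayes factors.
- `studies` — Monte-Carlo studies over all of the above (mechanism
  replication, recovery sweeps, calibration checks).
- `pipeline` / `cli` — config-driven end-to-end runs and a `touchlimits`
  command (`simulate`, `score`, `compare`, `regress`, `run`, `mechanism`).

The numbered scripts under `analysis/` run the whole arc:
`01_simulate_cohort.py` → `02_group_comparisons.py` →
`03_criterion_mechanism.py` → `04_parameter_recovery.py` →
`05_statistical_calibration.py`, each writing tidy tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/03_criterion_mechanism.py
```

prints, for one simulated cohort of 147 participants:

```
single cohort (n = 90):
  baseline model:
                       aOR  ci_low  ci_high  wald_chi2      p
diagnosis_asd        6.099   2.434   15.278     14.890  0.000
...
  with criterion c added:
                         aOR  ci_low   ci_high  wald_chi2      p
diagnosis_asd          2.009   0.756     5.335      1.959  0.162
c                    385.811  58.377  2549.821     38.204  0.000

across 100 simulated child cohorts:
  diagnosis significant at baseline:      86%
  c selected by best-subset BIC:          100%
  diagnosis non-significant once c added: 76%
  c carries the largest Wald chi2:        100%
  full pattern:                           64%
  type-I rate under no criterion gap:     5%
```

Reading: in the baseline proportional-odds model, an ASD child is ~6 times
as likely to exceed any given threshold value (aOR 6.1, p < 0.001) — yet
the two child groups were simulated with *identical* sensitivity (α, β)
and differed only in criterion.  Once the estimated criterion c joins the
model, the diagnosis effect collapses to non-significance and c dominates
(Wald χ² = 38.2).  The replication rates show this is the typical outcome,
not a lucky cohort, while cohorts with no criterion gap produce a spurious
baseline "diagnosis effect" at just the nominal 5% rate.

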