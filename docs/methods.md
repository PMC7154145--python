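# Methods

## The measurement problem

A method-of-limits detection task reports a threshold: the force at which a
participant's yes/no response reverses.  But the reversal point confounds
two latent quantities — how well the observer's sensory system separates
signal from noise, and where the observer places the decision cut on the
evidence axis.  A conservative observer (high criterion) keeps saying "no"
to forces they partly sense, so their measured threshold rises with no
sensory change at all.  The package implements the estimator side (signal
detection metrics and the downstream statistical battery) and the
generative side (observers with known parameters run through the full
protocol), so that the estimator's behaviour can be checked against ground
truth rather than assumed.

## Generative observer model

Per trial the observer draws evidence X ~ Normal(d, 1) and answers "yes"
iff X > λ, with a lapse probability (default mean 0.02, truncated to
[0, 0.05]) of responding at random.  Signal strength follows

    d(f) = max(0, β · (log₁₀ f − log₁₀ α) + 1),

so α (grams) is the force at which the signal sits 1 SD above noise, β
(SD per log₁₀-gram) is the psychometric slope, and catch trials have
d = 0.  This is exactly the equal-variance Gaussian model under which the
A_z and c formulas are the right estimators, which is what makes recovery
tests interpretable: any bias they reveal comes from the protocol (finite
trial counts, the stimulus mix, staircase truncation), not from model
mismatch.  The hard clip at zero encodes that forces far below α are
indistinguishable from no stimulus.

Two scales must not be conflated: λ lives on the evidence axis, while the
estimated c is computed from a session's pooled hit rate, most of whose
stimulus trials are sub-threshold rungs.  Pooling deflates Φ⁻¹(H), so
E[c] ≈ (λ − Φ⁻¹(H))/2 sits well below λ and the mapping λ → E[c] depends
on the stimulus mix.  The recovery sweep therefore asserts monotonicity of
the mapping, never identity.  Conversely, choosing generative λ values
equal to target c values would be a category error: it yields false-alarm
rates near 30% and mass exclusions, nothing like the behaviour the
estimator is meant to summarise.

## Protocol engine

Sessions have four alternating blocks (which direction opens is
counterbalanced across participants by alternation over a shuffled order).
The ladder is 10 log-spaced filaments, 0.008–2.0 g.  Descending blocks
start at 2.0 g and end after two consecutive "no" responses on stimulus
trials; ascending blocks start at 0.008 g and end after two consecutive
"yes".  Catch-trial responses never touch the termination counter.  Each
ascending block carries 3 catch trials and each descending block 7 (the
heavier descending quota reflects the stronger yes-bias in descending
series); a "yes" on a catch trial is logged with false-positive feedback,
which by default does not alter observer state.  Catch placement is
decided online: before each stimulus trial a catch trial is inserted with
probability (quota remaining)/(expected trials remaining), any unplaced
remainder going in just before the final trial — quotas are therefore
exact while positions vary.

The block threshold averages the force presented immediately before the
first terminating response with the force of that response itself
(`threshold_rule="adjacent"`); the alternative reading that brackets the
whole terminating pair is available as `"pair"`.  The session threshold is
the mean of the four block thresholds.  A block that walks the whole
ladder without meeting its termination rule is flagged and scored at the
extreme rung; flagged sessions are reported, not auto-excluded.  Sessions
are excluded when any contiguous 10-trial window within a block contains
more than three catch-trial "yes" responses (`exclusion_rule="window"`;
the per-block-total reading is the `"block"` switch).  Hit rate pools all
stimulus trials of the session — the only reading consistent with one H
per participant — and is documented prominently because it couples H (and
hence c and A_z) to the stimulus mix.

## SDT estimators

A_z = Φ((Φ⁻¹(H) − Φ⁻¹(F))/2) and c = −(Φ⁻¹(H) + Φ⁻¹(F))/2, with
H = 1 → (hits + 0.5)/(trials + 1) and F = 0 → 0.5/(catch + 1).  The
mirrored corrections for H = 0 and F = 1 use the same ±0.5/(n + 1) rule so
Φ⁻¹ stays finite for every count vector; double-precision normal
CDF/quantile functions throughout.  A_z is the only sensitivity index
exposed (it is a monotone transform of d′ and outperforms the
"non-parametric" A′ in simulation studies); unequal-variance SDT and
likelihood-ratio criterion indices are out of scope.

## Default cohort

Four cells: 55/35 ASD/NT children, 33/24 ASD/NT adults, with age, sex
ratio, verbal/performance/full-scale IQ and SRS-2 T-scores drawn from
truncated normals (rejection sampling, 1000-attempt cap) matching the
emulated study's descriptive tables, and SRS-2 coupled to λ through a
Gaussian copula (default r = 0.3) so criterion–symptom correlations are
exercisable.  Generative parameters were calibrated once, by forward
simulation against the study's descriptive pattern, and then frozen:

| group     | α (g)        | β   | λ           | target pattern        |
|-----------|--------------|-----|-------------|-----------------------|
| NT child  | 0.05 (0.015) | 2.0 | 1.25 (0.28) | mean c ≈ 0.55         |
| ASD child | 0.05 (0.015) | 2.0 | 1.70 (0.42) | mean c ≈ 0.76         |
| NT adult  | 0.035 (0.012)| 2.4 | 1.70 (0.45) | highest A_z           |
| ASD adult | 0.065 (0.02) | 2.0 | 1.65 (0.50) | adult-only A_z gap    |

The two child groups share identical sensitivity parameters, so the
simulated child threshold gap (Cliff's δ ≈ −0.4) is criterion-driven *by
construction* — that is the point of the design.  Exclusions run ~1–2% and
block-threshold pooling shows ICC(3,4) ≈ 0.6.  Simulated A_z levels
(~0.76–0.81) sit below typical empirical values because the pooled-H
convention charges every sub-threshold rung against the hit rate; the
group *ordering* is what the defaults aim to reproduce, and the adult
sensitivity gap is correspondingly compressed relative to real data.

## Cumulative probability model

The CPM treats each of the K distinct outcome values as an ordered
category: P(Y ≥ y₍ₖ₎ | x) = expit(θₖ + x′β) with θ non-increasing.  The
likelihood depends on Y only through ranks, so slopes are invariant to
monotone outcome transforms (asserted to machine precision) and exp(β) is
an adjusted odds ratio of exceeding any cut point.  Fitting is Newton with
step-halving in the natural parametrisation, where the log-likelihood is
concave; the θ-block of the Hessian is tridiagonal, so each iteration is a
banded solve plus a p × p Schur complement (also the slope covariance),
giving O(K) cost per step and exact fits at n = K = 1600 in milliseconds.
Gradient tolerance 1e−8; a quasi-Newton fallback on an
ordering-preserving reparametrisation handles non-PD corners, and
unconverged fits are flagged, never silently reported.

Inference: Wald χ² per slope with 95% profile-free CIs exp(b ± 1.96·SE);
model LR χ² against the closed-form intercept-only likelihood
Σ nₖ log(nₖ/n); Nagelkerke R².  The score test uses the expected (Fisher)
information at the null MLE; for one binary predictor it equals n/(n−1)
times the tie-corrected Wilcoxon–Mann–Whitney χ² (no continuity
correction) exactly — the precise sense in which the CPM generalises that
test, and the comparison the equivalence check uses.

Best-subset search enumerates all subsets of ≤ 15 candidates on top of the
(always retained) baseline predictors — diagnosis, sex, age,
counterbalance — ranking by BIC = −2ℓ + p·log n with p counting slopes
only: all candidates share the same outcome, so the identical intercept
count cancels from every ΔBIC.  BIC weights are exp(−Δᵢ/2) normalised;
BF₁₀ of best over baseline is exp((BIC_baseline − BIC_best)/2).  A
pure-all-subsets mode (`force_base=False`) is available; interaction terms
enter as caller-supplied derived columns.

## Robust statistics

Cliff's δ is the mean of the dominance kernel sign(xᵢ − yⱼ) (ties 0); its
variance is the consistent estimator built from row/column dominance means,
CI = δ ± z·SE truncated to [−1, 1], p from the normal test.  Orientation
follows the emulated study's table convention: the NT sample is passed as
the reference, so ASD-elevated variables come out negative.  Spearman and
the 2×2 Pearson χ² (no continuity correction) delegate to scipy; Zou's
modified-asymptotic CI compares two independent correlations via their
back-transformed Fisher-z intervals; ICC(3,k) is the two-way mixed,
average-measures consistency form (BMS − EMS)/BMS with the F-based CI.
P-values are reported unadjusted, matching the exploratory convention of
the analyses they mirror.

## What the simulations do and do not show

The Monte-Carlo studies run at sizes chosen to keep the whole battery
around a minute on one CPU: 100–200 cohorts for the mechanism replication,
200 sessions per criterion level in the recovery sweep, 2000 simulations
for CI coverage, 1000 for the LR null, 15 replicates per n for BIC-weight
growth.  They demonstrate that *under the stated generative model* the
estimator pipeline recovers criterion effects, calibrates its tests, and
reproduces the criterion-supplants-diagnosis regression pattern in about
two-thirds of cohorts (with the baseline diagnosis test rejecting at the
nominal rate when no criterion gap exists).  They cannot certify the
generative model itself: real observers drift within sessions, may shift
criterion after false-alarm feedback (a hook exists, default off, since
available data cannot identify it), have non-Gaussian or unequal-variance
evidence, and produce lapses that correlate with age and attention.
Adaptive staircases and forced-choice designs are out of scope.

## Numerical and degenerate-case choices

Strict-inequality decision rule X > λ (measure-zero ties); thresholds from
a block that terminates on its first two trials fall back to the extreme
force, since no preceding rung exists; constant outcomes raise rather than
fit; empty candidate sets return the baseline with weight 1 and BF₁₀ = 1;
complete-separation dominance (δ = ±1) yields a degenerate SE of 0 and
p = 0; rejection sampling failures after 1000 draws raise a configuration
error rather than silently re-truncating.
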