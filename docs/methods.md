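# Methods

## Staging conventions

eGFR is the Japanese serum-creatinine equation
`194 · Cr^−1.094 · age^−0.287 (× 0.739 for women)`; creatinine in mg/dL,
age in years, result in mL/min/1.73 m². The algebraic inverse
(`inverse_creatinine`) is exact, so eGFR→Cr→eGFR round trips to machine
precision; the test suite checks the forward equation against a 40-digit
evaluation.

G-band boundaries are inclusive for the better category (90 → G1,
60 → G2, 45 → G3a): the guideline grids label bands as e.g. "60–89", and
this convention keeps every positive eGFR in exactly one band. G4/G5
collapse into G3b and dipstick grades above (2+) truncate to (2+), so the
stage space is exactly 4×4. The prognostic-category mapping over
(G, A) is the standard KDIGO heat map restricted to G1–G3b.

Comorbidity definitions (all thresholds inclusive): hypertension —
SBP ≥ 140 mmHg or DBP ≥ 90 mmHg or antihypertensive medication; diabetes
— casual glucose ≥ 200 mg/dL or HbA1c ≥ 6.5 % (NGSP) or antidiabetic
medication; dyslipidemia — LDL ≥ 140 mg/dL or lipid-lowering medication.

The outcome is "prognostic category rose between the first and last
year, or the last-year category meets the end-state rule". Two end-state
rules are supported because the two natural readings differ: the default
`very_high_at_end` (last-year category is very high) and `high_at_end`
(at least high). Nothing downstream depends on which is chosen; the rule
is a parameter of every entry point that computes outcomes.

Percentages in reported tables use round-half-up at one decimal, the
convention that reproduces printed cohort percentages exactly (e.g.
730/7465 → 9.8).

## Synthetic cohort generator

The generator emulates an 8-wave (2009–2016) annual checkup panel of a
middle-aged worksite population. It is the package's substitute for
protected registry data: every statistical property the downstream
analyses rely on is produced by an explicit mechanism.

* **Kidney function.** Subject *i* has a latent baseline eGFR and a
  linear slope; year *y*'s measurement is
  `base_i + slope_i·(y − 2009) + ε_iy`, ε ~ N(0, noise_sd²). Creatinine
  is back-solved through the exact inverse of the staging equation, so
  the equation is exercised in both directions. The baseline is a
  *shifted lognormal* (fixed CV 0.35 of the lognormal part, shift chosen
  so the configured mean and marginal SD are matched exactly): healthy
  checkup populations have a right-skewed eGFR distribution whose low
  tail is much lighter than a Gaussian of the same SD, and the skewed
  baseline reproduces realistic G-category shares
  (≈19/75/5.5/<1 % for G1/G2/G3a/G3b) instead of over-populating G3.
  `egfr_sd` is interpreted as the measured cross-sectional SD, so the
  latent between-subject SD is reduced by the noise variance.
* **Defaults** (units mL/min/1.73 m² and years): egfr_mean 79,
  egfr_sd 14.4, slope_mean −0.3/yr, slope_sd 0.6/yr, noise_sd 4.0.
  Slope and noise were chosen once so the cohort reproduces the observed
  behaviour of annual checkup panels: two-way stage churn (both apparent
  improvement and exacerbation year to year), ~82 % of G2 P(−) subjects
  still G2 P(−) seven years later, ~7–8 % of them in G3a P(−), and an
  outcome prevalence near 11 %.
* **Proteinuria.** The dipstick grade thresholds a standard-normal latent
  severity with cutpoints (1.33, 1.84, 2.35), giving marginal grade
  prevalences ≈ 90.8/6.0/2.3/1.0 %. The latent combines a persistent
  subject effect (loading 0.7) and a coupling to the negative eGFR slope
  (loading 0.5): positivity tracks within subject over years and fast
  decliners spill protein more often. Both loadings are internal
  constants; the cutpoints are configurable.
* **Comorbidities.** Status is drawn first (Bernoulli at the configured
  prevalence: 0.299/0.056/0.357 for hypertension/DM/dyslipidemia), then
  measurements and medication flags are drawn *consistently with the
  status* using truncated normals (negatives strictly below every
  threshold, positives above threshold or flagged as medicated). Hence
  re-classifying a generated record recovers the drawn status exactly and
  empirical prevalence converges to the configuration by construction.
  Comorbidity-relevant measurements are constant within subject across
  years (stable comorbid status).
* **Demographics.** Age ~ N(50.1, 6.3²) at baseline, incrementing
  yearly; 64.2 % male; BMI ~ N(23.3, 3.3²) with waist correlated 0.8.
* **Missingness.** Each subject-year is dropped independently with
  probability `missing_rate` (default 0.25; the 2009&2016 complete-pair
  fraction is then ≈0.56, near the ≈53 % seen in real per-analysis
  denominators). Missingness is MCAR; downstream analyses are
  complete-case per year pair.

A second generator walks subjects over the 16-cell stage grid under an
explicit 16×16 Markov kernel (initial distribution = the baseline cell
proportions of a reference population) and emits creatinine uniformly
inside the assigned G band. It exists to give the trajectory analyses a
known ground truth.

**What the generator does not emulate:** informative dropout, medication
*effects* on trajectories, seasonal/assay drift, within-year repeat
visits, age-dependent slopes, or any correlation between comorbidities
and eGFR decline. Tests passing on this cohort therefore validate the
*methods* (staging arithmetic, estimator correctness, protocol
plumbing), not epidemiological conclusions about any real population.

## Bayesian-network stage

Conditional independence is tested with G² = 2·Σ O·ln(O/E) within each
stratum of the conditioning set, referred to chi-square. Nonempty strata
contribute (|X|−1)(|Y|−1) dof each; empty strata are skipped and
contribute no dof (this mirrors the usual small-sample adjustment in
discrete BN learners and avoids dof inflation); dof is floored at 1. For
an unconditional test, G² = 2n·MI(X,Y) in nats (property-tested).

IAMB: the grow phase admits, among variables outside the blanket, the one
with the largest G² statistic given the current blanket, provided
p < α (default α = 0.05); the shrink phase removes members independent of
the target given the rest. Ties break lexicographically, making the
result deterministic.

Structure: the skeleton keeps X–Y when each is in the other's blanket
(AND rule) **and** no separating set exists inside the union of the two
blankets (subset search, size ≤ 3). The second clause is required for
correctness, not an embellishment: in a collider X→Z←Y the spouses X and
Y sit in each other's blankets, and a pure AND rule would keep a spurious
X–Y edge. V-structures are oriented from the recorded separating sets,
a Meek-style rule propagates orientations without creating new
v-structures or cycles, and remaining edges are oriented from the
lexicographically smaller endpoint — an arbitrary but deterministic
fallback that cannot introduce a cycle. The output is always a DAG
(asserted).

Bootstrap averaging (defaults B = 200, threshold 0.5 — conventional
values; nothing in the analysis pins them): learn on B resamples of size
n, arc strength = direction-specific fraction of replicates containing
the arc, retain arcs with strength ≥ threshold, break any residual cycle
by dropping its weakest arc.

ROC discretization maximizes Youden's J over observed thresholds with the
rule `value ≥ cutoff`; ties resolve to the smallest cutoff. The fixed
default cutoffs for age/BMI/waist are 46 y, 22.8 kg/m², 81.4 cm; passing
`cutoffs="fit"` to the pipeline re-derives them from the baseline data
by ROC against the outcome.

## SVM stage

The C-SVC dual is solved by SMO with maximal-violating-pair working-set
selection; termination at KKT violation ≤ tol (default 1e-3 in the
protocol path, 1e-6 in oracle tests). The solver is deterministic. The
test suite checks the dual objective against an independent SLSQP QP
solve (≤ 1e-4 gap on 20-point problems) and predictions against an
independent C-SVC implementation.

Features are the ordinal-encoded prognostic categories (0–3) at the
baseline and comparison years; one-hot encoding is available as an
option. Defaults C = 1 and gamma = 1/(n_features·Var(X)) (the standard
"scale" heuristic); neither is tuned. "Training error" is the mean
misclassification rate over stratified 3-fold cross-validation on the
2/3 training split — the natural reading of averaging three fold
results — and the test error is measured once on the held-out third.
Platt scaling (regularized ML with target smoothing, Newton with
backtracking) is fitted on the training decision values; the possibility
heat map evaluates the calibrated probability at the 16 discrete
category combinations (a dense grid would interpolate between categories
that cannot occur).

A caveat the test suite makes explicit: the possibility map is only
trustworthy over category pairs represented in training. On realistic
cohorts the rare corners (e.g. baseline low × comparison very-high) may
contain no subjects and the RBF decision surface falls back toward the
bias there; the grid-separation property is therefore asserted on a
cohort constructed to cover all 16 pairs.

## Determinism and seeds

A single global seed is expanded into per-stage child seeds via
`SeedSequence(seed, spawn_key=(stage_index,))` with fixed stage indices,
so adding a stage never perturbs earlier stages' randomness. All
stochastic components (generator, bootstrap, splits) are driven by
`numpy.random.Generator`; no ordering in any output depends on hash or
dict iteration order. Identical configuration yields byte-identical CSV,
TSV and manifest output (tested).

## Problem sizes used in the test suite

Unit and acceptance tests run the generators at n = 1200–5000 subjects,
bootstrap averaging at B = 8–100, and skeleton-recovery checks over 10
seeds at n = 5000, B = 100 — sizes at which the checked statistical
properties (3-SE moment recovery, ≥90 % skeleton recovery, CI-test
calibration) are comfortably identifiable while the whole suite stays
fast.

## Known limitations

* Stage analyses are complete-case per year pair; under MCAR this is
  unbiased, under informative dropout it would not be.
* The BN learner handles discrete variables only; no parameter learning
  or inference on the fitted DAG is provided (the analysis uses the
  structure and arc strengths only).
* The IAMB sepset search is capped at conditioning sets of size 3 —
  ample for 9 variables, but a deliberate bound.
* The SVM stage is intentionally two-feature (the category pair); it is
  a prediction protocol probe, not a full multivariate risk model.
* Printed transition percentages and error rates from any specific real
  cohort are not reproduction targets: they depend on private data. The
  pipeline reproduces their structure and scale on synthetic cohorts
  calibrated to the reference baseline distribution.
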