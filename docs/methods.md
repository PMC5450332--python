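# Methods

This note records the model, the numerical conventions and the design
choices behind `survrules`, in the order a user meets them: data model,
estimation primitives, the induction algorithm, prediction, evaluation,
and the synthetic-data generator the test suite is built on.

## Data model

An observation is a covariate map (nominal or numeric attributes,
missing values allowed), a non-negative follow-up time `T`, a censoring
status `δ` (1 = event observed, 0 = right-censored) and a positive
weight (default 1).  Weights act as fractional multiplicities
everywhere: duplicating a record and doubling its weight are
indistinguishable in every count, estimate and statistic.  Times are
compared by exact floating-point equality; no epsilon bucketing or unit
conversion is ever applied, so times should be supplied as recorded.

## Kaplan-Meier estimation

`km_fit` computes the weighted product-limit estimator.  At a time
carrying both events and censorings, events are processed first: a
record censored at `t` is still at risk at `t`.  Curves are
right-continuous step functions; evaluation before the first event
returns 1 and evaluation past the last jump returns the last value.
The left limit `S(t-)` is exposed separately because the evaluation
side matters for inverse-probability weights (below).

## Log-rank rule quality

Rule quality is the two-sample log-rank chi-square `x²/y` between the
records covered and not covered by the rule, computed over the union of
the groups' event times from weighted event counts `d` and at-risk
counts `r`.  Degenerate cases are mapped to 0 rather than an error — an
empty group, no events at all, or a vanishing variance sum — so that
quality is totally ordered and the induction loop can always compare
candidates.  Variance terms with total at-risk weight ≤ 1 have a zero
denominator and contribute nothing.  The implementation rewrites both
sums as linear/quadratic functionals of the covered group's at-risk
step function, which lets one (segment × value-rank) weight matrix
score every candidate split of an attribute at once; the vectorised
path is tested for exact agreement with the direct record-level
definition and against an independent reference implementation.

## Induction

The covering loop adds rules until every training record is covered.
Growing starts from the empty premise and repeatedly appends the best
admissible candidate condition:

- candidates are recomputed from the currently covered records at
  every step — one equality test per observed nominal value, and `<` /
  `>=` tests at arithmetic means of adjacent distinct numeric values,
  skipping missing values;
- a candidate is admissible when the rule would keep covering at least
  `mincov` weight of *previously uncovered* records (for the final
  rule the bound is relaxed to the remaining uncovered weight so the
  loop terminates);
- the quality of a candidate is always measured on the covered /
  not-covered split of the **entire** training set, not the residual;
- ties on the statistic (within a 1e-9 relative tolerance, which makes
  the two sides of a binary split genuinely tie) are broken toward the
  larger covered weight, then attribute declaration order, then
  ascending split value with `<` before `>=` — builds are bit-for-bit
  deterministic;
- the best admissible candidate is appended even when it does not
  raise the statistic; growing stops only when no admissible candidate
  remains.  Candidates that leave the covered set unchanged are
  excluded (they could recur forever); when the very first step has
  only such candidates — a single-valued nominal attribute — the best
  one is taken and growing stops, yielding the degenerate whole-dataset
  rule.

Pruning hill-climbs on condition deletion: at each step the removal
with the largest improvement of the statistic is performed, and only
strict improvements (beyond the same 1e-9 tolerance) count, so a
deletion that leaves coverage identical never fires.  Finally,
same-attribute numeric conditions are merged into the tightest
threshold or a half-open interval `[x, y)`; merging provably preserves
coverage.  Each rule stores its conclusion (KM curve of the covered
records), its statistic, weighted coverage and raw p-value
(chi-square(1) upper tail).

Two robustness paths exist for inputs the constraint system cannot
express: records whose covariates are all missing can never be covered
by a non-empty premise and are released from the coverage obligation
with a warning (they keep contributing to every statistic and receive
the default curve at prediction); and if even the relaxed `mincov`
admits no condition, the learner retries with the lightest uncovered
record's weight and, failing that, abandons the stragglers with a
warning.  Both trigger only on pathological data.

`mincov` defaults to 7.  Smaller values produce more and more specific
rules; the default gives compact models on datasets of a few hundred
records.  `max_conditions` (unlimited by default) can cap premise
length during growing.

## Prediction

A record's predicted survival curve is the unweighted pointwise mean of
the conclusions of all rules covering it, evaluated right-continuously
on the union of their jump times; each covering rule contributes
equally because the averaging is defined over rules, not records.  A
record covered by no rule receives the default curve, the KM estimate
of the full training set, so prediction is total.

## Evaluation

The Brier score at horizon `t*` for record `i` is

- `(0 − Ŝ(t*))² / Ĝ(T_i⁻)` if `T_i ≤ t*` and `δ_i = 1`,
- `(1 − Ŝ(t*))² / Ĝ(t*⁻)` if `T_i > t*`,
- `0` otherwise (censored at or before the horizon),

where `Ĝ` is the KM estimate fitted on the training records with
status flipped to `1 − δ`.  `Ĝ` is evaluated at the left limit so a
record scored at its own censoring time is not divided by a post-drop
value.  Records whose required `Ĝ` value is exactly 0 (the tail of
follow-up) are dropped from the mean at that horizon.  The integrated
Brier score averages `BS(t*)` over `[0, max T_i]` of the scored set;
since `BS` is a step function between observed times, the integral is
an exact left-rectangle sum over the sorted distinct test times
augmented with 0 and the maximum.  With zero censoring `Ĝ ≡ 1` and the
score reduces to the ordinary Brier score.

Cross-validation stratifies by censoring status: events and censored
records are shuffled separately (from one seed) and dealt round-robin,
so each fold preserves the event/censored proportion up to remainders.
Per fold, the model and `Ĝ` are fitted on the training split only and
the IBS is computed on the test split; folds whose training split has
no events are skipped with a warning.  Aggregates are unweighted means
over folds (fold sizes are near-equal).  Rule-set characterisation
reports the rule count, mean post-merge premise length, mean fraction
of training weight covered per rule, and the fraction of rules with
Benjamini-Hochberg-adjusted log-rank p below 0.05 (adjustment via
statsmodels).

## Synthetic data

The generator draws covariates i.i.d. from declared marginals (normal,
uniform, integer-uniform, categorical), assigns each record the
exponential event-time distribution of the first matching *region* (a
condition list; first-match priority mirrors how overlapping learned
rules coexist) or a baseline rate, and applies independent censoring:
an exponential rate, a uniform bound, or a target censoring *fraction*
for which the exponential censoring rate is solved by bisection from
the realised per-record event rates.  Missingness is injected
completely at random per attribute.  Exponential lifetimes keep every
distributional claim checkable in closed form (mean 1/λ, censoring
probability λ_c/(λ+λ_c)).

Two standard configurations define the test-suite study conditions:

- `planted_structure_config` — one binary `risk_group` covariate with a
  25-fold hazard ratio (baseline rate 0.1/time unit) among ten noise
  covariates, n = 300, 30% censoring.  Used for structure recovery and
  the cross-validated comparison against the KM baseline: the true
  model is essentially two rules, so whether induction finds the factor
  is a sharp question.
- `layered_risk_config` — four regions on a treatment-arm × integer
  severity-score grid with event rates spanning 0.05–2.0, two noise
  covariates, n = 500.  Because the ground truth is a *set* of rules at
  several granularities, the induced model size responds to `mincov`;
  this is the configuration for model-size scaling studies.  Its
  numeric covariates are integer scores, which is both realistic for
  clinical variables and keeps candidate-split sets small.  Model size
  in those studies is the mean rule count over the training splits of a
  stratified 10-fold partition: the greedy grow-and-prune search makes
  single-fit counts noisy, and fold-averaging is also how rule counts
  are conventionally reported alongside cross-validated error.

What the generator does not emulate: informative censoring, time-varying
covariates, competing risks, correlated covariates, and non-exponential
(e.g. Weibull-shaped) hazards.  Passing tests therefore demonstrate the
estimators' and the learner's contracts, not clinical performance on
real registries.

## Problem sizes and numerical choices

The test suite runs induction at n = 200–500 with up to 11 covariates,
100 seeded recovery runs at n = 300, and 10-seed 10-fold
cross-validation — sizes at which a full learn takes well under three
seconds thanks to the vectorised sweep.  Tolerances: statistic ties and
prune improvements use 1e-9 relative; weighted `mincov` comparisons
allow 1e-9 slack; oracle agreement is asserted at 1e-8 relative for the
log-rank statistic and 1e-6..1e-12 for Brier quantities depending on
whether an independent estimator is in the loop.  Model files serialise
floats with `repr` (shortest round-trip), so save/load is bit-exact and
repeated runs with equal seeds produce byte-identical artifacts.

## Known limitations

Growing explores conditions one attribute at a time (no lookahead or
beam), so correlated-covariate structure may be represented by whichever
attribute wins the first greedy step.  Hill-climbing pruning is not
globally optimal (small-scale exhaustive comparisons in the tests
quantify this).  Only right censoring is supported — no left truncation,
interval censoring or competing risks — and the only missing-data
mechanism is the ignored-value strategy.  The ARFF reader handles dense
rows with numeric/nominal declarations only.
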