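# Methods

## The estimation problem

A two-sample cohort study screens a closed population of n subjects at
enrolment with a diagnostic test, enrols the test-negatives as the at-risk
cohort, and re-tests everyone one time unit later to count incident cases.
When the test is imperfect (sensitivity Se < 1 and/or specificity Sp < 1),
two distinct biases arise and compound:

* enrolment errors change *who* is at risk (selection): truly diseased
  baseline false negatives enter the cohort — and, because disease persists
  over the interval, they surface later as spurious "incident" cases —
  while healthy false positives are excluded;
* follow-up errors change *who counts as a case* (misclassification):
  healthy subjects test falsely positive and truly incident cases are
  missed.

The package quantifies each channel and their combination by estimating the
same two quantities — apparent one-interval incidence and apparent exposure
risk ratio (RR) — under three analysis variants that differ only in which
status source defines the at-risk set and the outcome:

| variant                  | at-risk set | outcome |
|--------------------------|-------------|---------|
| `total`                  | test T₁ = 0 | T₂ = 1  |
| `selection_only`         | test T₁ = 0 | D₂ = 1  |
| `misclassification_only` | truth D₁ = 0| T₂ = 1  |

`total` is what a real study observes; the other two isolate the bias
components against the true statuses D₁, D₂ that the simulator knows.

## Generative model and its assumptions

Per subject: exposure E ~ Bernoulli(π_E); true baseline disease
D₁ ~ Bernoulli(p) independent of E; incident disease among the truly
at-risk with probability I_u·RR^E; persistence D₁ = 1 ⇒ D₂ = 1; test
results with P(T=1|D=1) = Se and P(T=1|D=0) = 1 − Sp, errors independent
across subjects and across the two sampling points given true status
(non-differential with respect to exposure).

Assumptions worth making explicit:

* **Closed, stable population.** No births, deaths, or loss to follow-up
  over the single interval.
* **Persistence.** No disease elimination within the interval; a baseline
  case is still a case at follow-up. This is what converts baseline false
  negatives into apparent incident cases.
* **Marginal incidence anchoring.** Scenario incidence I is the incidence
  among truly at-risk subjects *marginal over exposure*; the unexposed rate
  is back-solved as I_u = I / (1 − π_E + π_E·RR) so that
  π_E·I_e + (1 − π_E)·I_u = I exactly. Labelling a disease context by a
  single incidence then means the same thing whatever the exposure model,
  and the incidence expectations below depend only on I.
* **Exposure prevalence π_E = 0.5** by default (configurable): symmetric
  arms maximise the information per cohort for a hypothetical exposure.
* **Baseline disease independent of exposure.** With D₁ ⊥ E both arms share
  the prevalence p, which is what makes the expected apparent RR a ratio of
  incidence expectations. The `exposure_prevalence` argument of
  `expected_apparent_rr` is accepted for forward compatibility with a
  baseline exposure–disease association, under which this factorisation
  would no longer hold.

## Closed-form expectations

A subject enters the observed at-risk set (variants `total` and
`selection_only`) when T₁ = 0, which happens two ways:

* truly healthy and correctly negative, probability (1−p)·Sp; such a
  subject becomes an apparent case at follow-up with probability
  q₀ = I·Se + (1−I)·(1−Sp);
* truly diseased but missed, probability p·(1−Se); disease persists, so the
  follow-up test fires with probability Se.

Mixing the two membership types gives

* total: `[(1−p)·Sp·q₀ + p·(1−Se)·Se] / [(1−p)·Sp + p·(1−Se)]`
* selection-only (true outcome, case probabilities I and 1):
  `[(1−p)·Sp·I + p·(1−Se)] / [(1−p)·Sp + p·(1−Se)]`
* misclassification-only (true at-risk set): `q₀`

The expected apparent RR for a variant is its incidence expression
evaluated at I_e divided by its value at I_u. Useful sanity limits, all
asserted in the test suite: Se = Sp = 1 returns the true estimand; p = 0
collapses `total` onto `misclassification_only`; Sp = 1 makes the
misclassification-only RR exactly the true RR for any Se (the sensitivity
thinning cancels in the ratio); the selection-only incidence never falls
below the truth (its excess subjects are certain cases); and over the whole
default grid the total-bias RR is attenuated into [1, RR_true].

These expectations are the *deterministic limits* of the Monte-Carlo
estimates, not finite-sample means of the ratio estimators; at n = 1,000
the ratio-estimator bias is an order of magnitude below the Monte-Carlo
standard errors used in the tests, and the suite validates the closed forms
against the simulator (mean apparent incidence within 4 SE per grid cell,
median log-RR within 4 SE of its median standard error) before anything
else relies on them as oracles.

Note on the published worked examples: the two crossings of the 0.22
incidence contour (Se = 0.7/Sp = 0.845 and Se = 1.0/Sp = 0.87, p = 5%,
I = 0.1) evaluate to 0.21850 and 0.21700. The 0.02-contour example
(Se = 0.955, Sp = 1.00) is described in the source text as a 5%-prevalence
panel, but only the 20%-prevalence, I = 0.01 surface is consistent with it
under any model that also reproduces the 0.22 example (at p = 5% and Sp = 1
the expected apparent incidence cannot exceed I + p·(1−Se)·Se/denominator
≈ 0.012); the package reproduces the value at p = 20% and documents the
discrepancy rather than resolving it.

## Study design and defaults

The default `GridSpec` is the full factorial design: prevalences
{5%, 20%} × incidences {0.01, 0.05, 0.1} (six disease contexts) ×
Se {0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1} ×
Sp {0.8, 0.85, 0.9, 0.95, 0.98, 0.99, 1} — 378 cells — with 1,000 cohorts
of 1,000 subjects per context and a true RR of 3.0 (a 1.5 variant probes
weaker associations). `mode: scaled_down` drops to 100 replicates per
context for quick runs and CI; the acceptance tests use the scaled grid for
the cell-by-cell oracle comparison and full 1,000-replicate runs for the
single-scenario checks.

Within a context, true cohorts are shared across all (Se, Sp) cells and
only test errors are re-drawn per cell. The re-draw is implemented with
common random numbers: one pair of per-subject uniforms per replicate,
thresholded at each cell's operating characteristics. Every cell's test
results retain the exact Bernoulli margins; cells become positively
correlated, which cancels simulation noise out of between-cell contrasts
(the quantity of interest in a bias surface). Fully independent draws per
cell remain available via `share_true_cohorts=False`.

## Numerical and procedural choices

* **Randomness.** One master seed per run; the generator for (context i,
  replicate r) is spawned as `SeedSequence(master_seed, spawn_key=(i, r))`,
  so any replicate is reproducible in isolation and a grid run is
  bit-identical under the same seed and configuration.
* **Zero cells.** No continuity correction. A replicate's RR is recorded as
  missing (NaN) when there are no unexposed cases or an exposure arm is
  empty; missing RRs are excluded from quantiles and counted per cell
  (`n_missing_rr`). Corrections would distort exactly the bias surfaces
  under study, and the distributional summaries tolerate missingness. A
  zero *numerator* with a positive denominator is a defined estimate of 0.
* **Degenerate replicates.** An empty at-risk set yields NaN estimates for
  that replicate and variant rather than aborting the run; an infeasible
  context (back-solved I_e > 1) is skipped with a warning.
* **Quantiles.** Linear interpolation between order statistics (numpy's
  default), stated because quartile conventions differ.
* **Incidence is a one-interval risk**; there is no person-time
  denominator, as the design has exactly one fixed interval.

## What the simulator does and does not emulate

The generator reproduces the statistical structure of a two-sample cohort
with an imperfect test: persistent disease, exposure-dependent incidence,
and non-differential, conditionally independent test errors. It does not
emulate clustering of observations (e.g. animals within herds), loss to
follow-up or other open-population dynamics, differential or dependent
misclassification, exposure measurement error, confounding, or disease
elimination/recovery. Tests passing against this generator therefore show
that the estimators and closed forms are correct *under these assumptions*,
not that real studies are free of the excluded complications — under
differential or dependent errors, in particular, bias need not be toward
the null and the attenuation guarantee does not apply.

## Known limitations

* The closed-form RR requires baseline disease independent of exposure;
  with a baseline exposure–disease association only the simulation path is
  valid.
* Per-replicate confidence intervals are out of scope; uncertainty is
  summarised across replicates (median, quartiles, mean, SEM).
* Serial/parallel re-testing strategies and bias-correction methods
  (latent-class models, probabilistic bias analysis) are deliberately not
  implemented; the package quantifies the bias, it does not correct it.
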