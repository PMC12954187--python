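# Methods

## Problem and setting

In a 10-week internet-delivered psychotherapy programme for adolescent
depression, weekly self-rated symptom scores (QIDS-A17-SR, integer 0–27)
accumulate from pre-treatment (week 0) onward. The clinical question is
whether, by treatment week 3, a participant can be flagged as *at risk of
non-response* so that their treatment can be adapted while it is still
running. This package implements that early-warning pipeline end to end:
response definition, trajectory-based prediction, model selection against
standard classifiers, evaluation, and a synthetic-cohort generator that
stands in for trial data, which cannot be redistributed.

## Response criterion

Response is defined by the Proportion Improvement (PI) method: observed
change scored against possible change, on two denominators. With pre score
`pre`, post score `post`, scale minimum 0 and clinical cutoff `C = 9` (the
screening threshold below which QIDS-A17-SR indicates no depression):

    PI_overall  = (pre − post) / (pre − 0)
    PI_clinical = (pre − max(post, C)) / (pre − C)        for pre > C

A participant responds when `PI_clinical ≥ 0.50` **and** `PI_overall ≥
0.25`, ties counting as met. Improvement below the cutoff is not credited
to the clinical component. The published source of the PI method does not
print an explicit formula, so these denominators are this package's
codification; they are held behind `CriterionConfig` so an alternative
published formulation can be swapped in. Participants who enter at or below
`C` have no defined clinical range and fall back to the overall proportion
(an error in `strict` mode); a pre score at the scale minimum leaves
improvement undefined and is an error. The post-treatment score is the last
scheduled week's observation — no carry-forward.

## Trajectory model

The predictor is a two-level Gaussian growth curve fitted to weeks 0–3:

    y_it = β0 + β1·f(t) + β2·x_i + u0_i + u1_i·f(t) + ε_it
    u0 ~ N(0, σ_u0²),  u1 ~ N(0, σ_u1²),  ε ~ N(0, σ_e²)

with change term `f(t) ∈ {log(t+1), t, t²}` and baseline covariate x
(PID-5-BF by default). `log(t+1)` keeps the pre-treatment week as the
intercept. Missing weekly ratings drop out of the likelihood
(missing-at-random). Priors are weakly informative on the 0–27 scale:
Normal(0, 10) on fixed effects, half-Normal(5) on all three SDs.

**Estimation.** The random effects are marginalized analytically — each
participant's observed vector is multivariate normal with covariance
`Z_i diag(σ_u0², σ_u1²) Z_iᵀ + σ_e² I` — leaving a posterior over 5–6
global parameters (SDs sampled on the log scale with the Jacobian term).
That posterior is sampled with an affine-invariant ensemble MCMC (emcee),
using an 80/20 mixture of differential-evolution and snooker moves, which
mix several times faster than the stretch move here (autocorrelation time
≈ 15–20 steps). Participants are grouped by observed-week pattern so the
likelihood is evaluated with batched small Cholesky factorizations across
all walkers at once. Default plan: 32 walkers, 500 warmup steps, 1000
retained steps.

**Convergence.** Ensemble walkers are neither independent chains nor long
relative to the autocorrelation time, so split-R̂ is computed on four
super-chains formed by pooling walkers. If any parameter exceeds the
threshold (default 1.01) the sampler retries once with doubled draws, then
raises. Inside cross-validation, candidates run a reduced plan (16 walkers,
300+400 steps) with a 1.05 gate — repeated refits need speed, and the final
selected model is refit at the full plan.

**Prediction (partial pooling).** For any participant with at least a
week-0 rating, each posterior draw conditions `(u0_i, u1_i)` on the
observed early-week residuals — a closed-form Gaussian update — and
simulates the week-10 score including residual noise. With few or no
post-baseline ratings the conditional collapses toward zero and the
prediction shrinks to the population-average trajectory; because most
participants improve, sparsely rated participants are therefore
optimistically classified, the behaviour the missing-data analysis
quantifies. The point summary is the posterior predictive **median**
(robust on a bounded, skewed scale), truncated to [0, 27] before the
criterion; the at-risk flag is the criterion's non-responder label applied
to (observed week-0 score, predicted post score). The posterior probability
of non-response is attached alongside to support later sensitivity
calibration, but classification uses the point summary.

## Model selection

Candidates — the three change-term families plus Random Forest, Gaussian
Naive Bayes and elastic-net logistic regression (scikit-learn) — are scored
by stratified 5-fold cross-validation through one confusion pipeline, with
*non-responder as the positive class*. Comparators see a flat feature table
(weeks 0–3 scores with training-fold mean imputation, the week3−week0
change, baseline covariates) and tune their hyperparameters (`max_features`
as the mtry analogue; `var_smoothing` as the Gaussian-NB smoothing knob;
`C`/`l1_ratio` for the elastic net) by nested 3-fold search inside each
training fold, avoiding leakage. Fold confusion counts are pooled (micro)
before computing F1 — stabler than per-fold averaging at n ≈ 200 with ~37%
positives. Highest pooled F1 wins; ties go to the fewer-parameter
candidate, then declared order. The winner is refit on the full training
split and scored once on the held-out split.

## Evaluation

`ClassificationReport` derives precision/PPV, recall/sensitivity,
specificity, NPV, accuracy, balanced accuracy and F1 from the four
confusion counts; zero-denominator metrics report 0 with a warning so
degenerate CV folds stay scoreable. The missingness contrast between two
cohorts is a 2×2 (missing, observed) table over weeks 0–3 cells (the
printed cell arithmetic of the reference cohorts — 828 = 207×4 and
140 = 35×4 — implies week 0 belongs in the denominator, so it is included
by default and configurable). Fisher's exact test reports the sample odds
ratio `ad/bc` with an exact conditional 95% CI by default (this choice
reproduces the reference interval to printed precision; a Woolf interval is
available).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| β0 | 13.8 | population week-0 intercept (QIDS points) |
| β1 | −2.4 | log-change slope (points per unit log-week) |
| β2 | 1.0 | covariate effect (points per PID-5-BF unit) |
| σ_u0, σ_u1, σ_e | 3.0, 2.5, 2.2 | intercept / slope / residual SD |
| PID-5-BF | N(1.2, 0.5²), clipped ≥ 0 | mean-item 0–3 scale |
| missing rate | 0.059 | per-cell MCAR, weeks 1–3 only |

Scores are rounded then clipped to [0, 27] — a deliberate deviation from
the unbounded Gaussian model that adds ~0.29 SD of rounding noise and a
small (<2%) attenuation of the covariate effect. β1 and σ_u1 were fixed by
a coarse grid search (n = 10 000) so that ~37% of participants are true
non-responders under the PI criterion applied to the *noiseless* pre and
week-10 scores, matching the development cohort's non-response rate, with
week-0 mean ≈ 15 and average improvement ≈ 5.4 points. Ground-truth labels,
random effects and the noiseless week-10 score are stored so parameter
recovery and classification can be tested exactly. The week-0 rating is
never deleted (it anchors enrolment). Therapist judgments are simulated as
fixed-sensitivity/specificity (0.50/0.65) corruptions of the true labels.
One integer seed drives a named substream per operation, so stages can be
re-run independently.

The generator deliberately omits features of real trial data: item-level
responses, informative (non-MCAR) dropout, treatment-adaptation effects,
comorbidity structure, and any covariance between missingness and
trajectory. Passing tests therefore demonstrate correctness of the
machinery under the assumed data model, not clinical validity on real
cohorts. The PID-5-BF enters as a continuous mean-item score (0–3) by
default; a total-score (0–75) convention is configurable.

## Numerical and design choices

- Week-3 deployment: new-participant prediction conditions only on that
  participant's weeks 0–3 and the training posterior; no refit.
- Initial walker positions: pooled OLS on `f(t)` plus jitter; bounded
  log-SDs (|log σ| < 12) guard overflow.
- Conditional covariance of random effects gets a 1e-12 ridge before
  Cholesky against round-off.
- Sub-clinical entries, undefined improvement, non-convergence, degenerate
  (zero-variance) data, and singleton strata all raise typed errors.
- Within-group effect sizes: the pooled-SD variant is the default and the
  change-score variant (d_z = t/√n) is always reported alongside, because
  published within-group d values are frequently ambiguous between the two;
  no attempt is made to reverse-engineer any particular report's variant.
- Experiment sizes used by the test suite and the reproduction script
  (cohorts of 100–300, 20 replicates, reduced CV MCMC plans) were chosen to
  make the full pipeline run comfortably on a single CPU; the
  parameter-recovery experiment at these sizes has a per-cohort sampling SD
  of ≈ 0.33 on the covariate effect, so replicate-averaged estimates carry
  a Monte-Carlo SE of ≈ 0.07 — interval coverage is the sharper calibration
  check at this scale, and both are reported.

## Known limitations

- The marginalized sampler assumes Gaussian random effects and residuals;
  the bounded integer scale makes both approximate at the floor/ceiling.
- MCAR missingness only; the fitted model is MAR-consistent but the
  generator does not exercise MAR mechanisms that depend on observed
  scores.
- Comparator hyperparameter grids are small and fixed; the benchmark is a
  harness correctness exercise, not a leaderboard.
- The exact conditional CI for the odds ratio is conservative for small
  tables; the p-value comes from the standard two-sided hypergeometric
  tail summation.
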