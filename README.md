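# earlywarn

Early warning of non-response in internet-delivered psychotherapy.

In 10-week internet-delivered therapy programmes for adolescent depression,
a third or more of participants finish without a clinically meaningful
response. If those participants could be identified by treatment week 3,
their treatment could be adapted while it still matters. `earlywarn`
implements that pipeline for weekly QIDS-A17-SR symptom ratings (integer
0–27):

- **Response criterion** — the Proportion Improvement (PI) definition:
  a responder improves ≥50% of the possible change within the clinical
  range (down to the cutoff C = 9) *and* ≥25% of the possible change
  overall.
- **Trajectory model** — a Bayesian mixed-effects growth curve fitted to
  weeks 0–3, `y_it = β0 + β1·log(t+1) + β2·x_i + u0_i + u1_i·log(t+1) +
  ε_it`, with random intercepts and slopes marginalized analytically and
  the remaining posterior sampled by ensemble MCMC. Each participant's
  week-10 score is predicted by partial pooling — their random effects
  conditioned on whatever early ratings they gave — and the PI criterion
  applied to the predictive median yields the week-3 at-risk flag.
- **Model selection** — stratified 5-fold cross-validation of the
  trajectory families (logarithmic / linear / quadratic change) against
  Random Forest, Gaussian Naive Bayes and elastic-net logistic regression,
  all through one pooled-confusion F1 pipeline with non-responder as the
  positive class.
- **Evaluation** — confusion-matrix metrics, comparison against (simulated)
  therapist judgment, Fisher's exact test for missingness contrasts, and
  within-group pre/post outcome summaries.
- **Synthetic cohorts** — a calibrated generator (log-shaped improvement,
  ~37% true non-response, intermittent early-week missingness, noisy
  therapist labels) standing in for trial data, which cannot be
  redistributed, with ground truth attached for exact testing.

## Worked example

```python
from earlywarn import (CohortConfig, generate_cohort, ModelSpec, fit,
                       predict_cohort, confusion_report)

cohort = generate_cohort(CohortConfig(n_participants=300, seed=42))
draws = fit(cohort.scores, cohort.baseline, ModelSpec(seed=5))
print(draws.summary().round(3))
preds = predict_cohort(draws, cohort.scores, cohort.baseline, seed=3)
rep = confusion_report(cohort.true_labels.loc[preds.index], preds["at_risk"])
print(f"F1 {rep.f1:.2f}, balanced accuracy {rep.balanced_accuracy:.2f}")
```

prints (generating values β0 = 13.8, β1 = −2.4, β_pid5bf = 1.0, σ = 3.0 /
2.5 / 2.2):

```
               mean     sd    q2.5  median   q97.5   rhat
beta0        13.823  0.492  12.856  13.823  14.796  1.003
beta1        -2.391  0.182  -2.743  -2.394  -2.029  1.001
beta_pid5bf   1.038  0.380   0.295   1.040   1.777  1.003
sd_u0         3.001  0.156   2.713   2.991   3.332  1.003
sd_u1         2.633  0.156   2.335   2.629   2.944  1.004
sd_e          2.220  0.059   2.107   2.219   2.338  1.002
F1 0.75, balanced accuracy 0.80
```

Every generating parameter is recovered within a posterior SD, all split-R̂
are below 1.01, and the week-3 flags reach F1 0.75 against the ground-truth
labels — the model sees only weeks 0–3 of noisy, partially missing integer
ratings, so this is the attainable ceiling under realistic noise, not a fit
to the training horizon.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study flow and write their
tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py   # development (n=261) + trial (n=35) cohorts
python analysis/02_fit_trajectory.py     # fit growth model to training weeks 0-3
python analysis/03_model_selection.py    # 5-fold CV benchmark of all 6 candidates
python analysis/04_evaluate_holdout.py   # held-out flags, therapist + missingness contrast
python analysis/05_outcomes.py           # within-group t-tests, effect sizes, arm table
```

A thin CLI covers the desk-scale stages (`earlywarn simulate / validate /
label / evaluate / report`).

## Layout

```
src/earlywarn/      library: simulate, tables, criterion, trajectory,
                    selection, metrics, outcomes, cli
analysis/           numbered narrative drivers (write to results/)
scripts/            acceptance.py reproduction script
tests/              pytest suite (unit, property-based, end-to-end)
docs/methods.md     model, priors, calibration, design choices, limitations
```
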