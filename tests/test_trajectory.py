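"""Trajectory model: recovery, shrinkage, determinism, at-risk flagging."""

import numpy as np
import pandas as pd
import pytest

from earlywarn.criterion import CriterionConfig
from earlywarn.simulate import CohortConfig, generate_cohort
from earlywarn.trajectory import (
    ConvergenceError,
    ModelSpec,
    PosteriorPrediction,
    fit,
    flag_at_risk,
    predict_cohort,
    predict_post,
)

FAST = dict(walkers=16, warmup=300, draws=400, rhat_threshold=1.1)


def test_model_spec_validation():
    with pytest.raises(ValueError, match="change_term"):
        ModelSpec(change_term="cubic")
    with pytest.raises(ValueError, match="draws"):
        ModelSpec(draws=0)
    assert ModelSpec(covariates=("pid5bf",)).n_parameters == 6
    assert ModelSpec(covariates=()).n_parameters == 5


def test_low_noise_parameter_recovery():
    """With tiny random variation the posterior concentrates on the truth."""
    cfg = CohortConfig(
        n_participants=300, beta0=16.0, beta1=-4.0, beta2=0.5,
        sd_u0=0.5, sd_u1=0.3, sd_e=0.6, missing_rate=0.0, seed=6,
    )
    cohort = generate_cohort(cfg)
    draws = fit(cohort.scores, cohort.baseline, ModelSpec(seed=2, **FAST))
    means = draws.summary()["mean"]
    # rounding to integers adds ~0.29 SD of extra noise, so +-0.2 on betas
    assert means["beta0"] == pytest.approx(16.0, abs=0.2)
    assert means["beta1"] == pytest.approx(-4.0, abs=0.2)
    assert means["beta_pid5bf"] == pytest.approx(0.5, abs=0.2)


def test_fit_is_deterministic_for_fixed_seed(fitted_small):
    cohort, draws = fitted_small
    again = fit(cohort.scores, cohort.baseline, draws.spec)
    np.testing.assert_array_equal(draws.beta, again.beta)
    np.testing.assert_array_equal(draws.sigma, again.sigma)


def test_nested_model_agreement_when_covariate_is_null():
    """Dropping a zero-effect covariate leaves the slope posterior unchanged."""
    cfg = CohortConfig(n_participants=200, beta2=0.0, seed=13, missing_rate=0.0)
    cohort = generate_cohort(cfg)
    with_cov = fit(cohort.scores, cohort.baseline, ModelSpec(seed=3, **FAST))
    without = fit(
        cohort.scores, cohort.baseline, ModelSpec(covariates=(), seed=3, **FAST)
    )
    b1_with = with_cov.summary().loc["beta1", "mean"]
    b1_without = without.summary().loc["beta1", "mean"]
    # the two posteriors differ only through the null covariate; agreement is
    # bounded by MC error of the posterior means (ESS a few hundred) plus a
    # small model-reparametrization effect
    assert b1_with == pytest.approx(b1_without, abs=0.15)


def test_fit_input_validation(small_cohort):
    few = small_cohort.scores[
        small_cohort.scores["participant_id"].isin(
            sorted(small_cohort.baseline.index)[:5]
        )
    ]
    with pytest.raises(ValueError, match=">= 10 participants"):
        fit(few, small_cohort.baseline, ModelSpec(**FAST))
    flat = small_cohort.scores.copy()
    flat["qids"] = 10.0
    with pytest.raises(ValueError, match="degenerate"):
        fit(flat, small_cohort.baseline, ModelSpec(**FAST))


def test_nonconvergence_raises_after_retry(fitted_small):
    cohort, _ = fitted_small
    impossible = ModelSpec(walkers=16, warmup=5, draws=8, seed=1, rhat_threshold=1.0)
    with pytest.raises(ConvergenceError, match="R-hat"):
        fit(cohort.scores, cohort.baseline, impossible)


def test_prediction_without_observations_errors(fitted_small):
    _, draws = fitted_small
    with pytest.raises(ValueError, match="no observations"):
        predict_post(draws, [], [], [1.0])


def test_shrinkage_baseline_only_participant_sits_on_population_curve(fitted_small):
    """A participant whose only rating equals the population week-0 mean is
    predicted onto the population-average trajectory at week 10."""
    _, draws = fitted_small
    m = draws.summary()["mean"]
    x = 1.2
    pop_w0 = m["beta0"] + m["beta_pid5bf"] * x
    pop_w10 = pop_w0 + m["beta1"] * np.log(11.0)
    pred = predict_post(draws, [0], [pop_w0], [x], n_draws=None, seed=0)
    assert pred.median == pytest.approx(pop_w10, abs=0.5)


def test_on_curve_observations_tighten_prediction_monotonically(fitted_small):
    """Adding observations lying exactly on the population curve keeps the
    prediction on the curve and never widens its spread."""
    _, draws = fitted_small
    m = draws.summary()["mean"]
    x = 1.2
    curve = lambda t: m["beta0"] + m["beta_pid5bf"] * x + m["beta1"] * np.log(t + 1.0)
    pop_w10 = curve(10)
    widths, medians = [], []
    for k in (1, 2, 3, 4):
        t_obs = list(range(k))
        pred = predict_post(draws, t_obs, [curve(t) for t in t_obs], [x],
                            n_draws=None, seed=0)
        widths.append(np.var(pred.draws))
        medians.append(pred.median)
    for a, b in zip(widths, widths[1:]):
        assert b <= a * 1.02  # non-increasing up to MC jitter
    for med in medians:
        assert med == pytest.approx(pop_w10, abs=0.5)


def test_noise_free_cohort_predictions_match_true_post():
    cfg = CohortConfig(
        n_participants=60, sd_u0=0.3, sd_u1=0.15, sd_e=0.1,
        missing_rate=0.0, seed=31,
    )
    cohort = generate_cohort(cfg)
    draws = fit(cohort.scores, cohort.baseline, ModelSpec(seed=7, **FAST))
    preds = predict_cohort(draws, cohort.scores, cohort.baseline, seed=1)
    err = preds["median"] - cohort.true_post.loc[preds.index]
    # integer rounding of the observations bounds attainable accuracy
    assert err.abs().median() < 0.5
    assert err.abs().max() < 1.5


def test_flag_at_risk_examples():
    crit = CriterionConfig()

    def pred(median):
        draws = np.full(200, float(median))
        return PosteriorPrediction("p", draws, float(median), float(median), float(median))

    assert flag_at_risk(pred(14), pre_score=14, criterion=crit).at_risk  # no change
    assert not flag_at_risk(pred(0), pre_score=14, criterion=crit).at_risk
    flagged = flag_at_risk(pred(8), pre_score=14, criterion=crit)
    assert not flagged.at_risk  # the worked criterion example: responder
    assert flagged.p_nonresponse == pytest.approx(0.0)
    assert flag_at_risk(pred(14), 14, crit).p_nonresponse == pytest.approx(1.0)


def test_point_summary_lies_inside_interval(fitted_small):
    cohort, draws = fitted_small
    preds = predict_cohort(draws, cohort.scores, cohort.baseline, n_draws=500, seed=2)
    assert ((preds["median"] >= preds["q2.5"]) & (preds["median"] <= preds["q97.5"])).all()
    assert preds["at_risk"].isin([True, False]).all()
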