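"""Confusion metrics and contingency analysis against independent oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import hypergeom

from earlywarn.metrics import (
    ClassificationReport,
    balanced_accuracy,
    compare_to_therapists,
    confusion_report,
    fisher_exact_2x2,
)


def brute_force_metrics(truth, pred):
    """Count-and-divide oracle straight from the label pairs."""
    pairs = list(zip(truth, pred))
    tp = sum(1 for t, p in pairs if t and p)
    fp = sum(1 for t, p in pairs if not t and p)
    fn = sum(1 for t, p in pairs if t and not p)
    tn = sum(1 for t, p in pairs if not t and not p)
    div = lambda a, b: a / b if b else 0.0
    prec, rec = div(tp, tp + fp), div(tp, tp + fn)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "precision": prec,
        "recall": rec,
        "specificity": div(tn, tn + fp),
        "accuracy": div(tp + tn, len(pairs)),
        "f1": div(2 * prec * rec, prec + rec),
        "balanced_accuracy": 0.5 * (rec + div(tn, tn + fp)),
        "ppv": prec,
        "npv": div(tn, tn + fn),
        "sensitivity": rec,
    }


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_confusion_report_matches_brute_force(pairs):
    truth = [t for t, _ in pairs]
    pred = [p for _, p in pairs]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rep = confusion_report(truth, pred).as_dict()
    oracle = brute_force_metrics(truth, pred)
    for key, val in oracle.items():
        assert rep[key] == pytest.approx(val, abs=1e-12), key


def test_study_confusion_matrix_reproduces_reported_metrics():
    # TP=5 FP=1 FN=6 TN=19: 24/31 correct, F1 0.59, balanced accuracy 70%, PPV 83%
    rep = ClassificationReport(tp=5, fp=1, fn=6, tn=19)
    assert rep.accuracy == pytest.approx(24 / 31)
    assert rep.f1 == pytest.approx(0.59, abs=0.005)
    assert rep.balanced_accuracy == pytest.approx(0.70, abs=0.005)
    assert rep.ppv == pytest.approx(0.83, abs=0.005)
    assert rep.sensitivity == pytest.approx(5 / 11)
    assert rep.specificity == pytest.approx(0.95)


def test_perfect_predictions_score_one():
    truth = [True, False, True, False]
    rep = confusion_report(truth, truth)
    d = rep.as_dict()
    for key in ("precision", "recall", "specificity", "accuracy", "f1", "balanced_accuracy"):
        assert d[key] == 1.0


def test_zero_denominator_metrics_warn_and_return_zero():
    with pytest.warns(UserWarning):
        rep = confusion_report([True, True], [False, False])
        assert rep.precision == 0.0
    assert rep.recall == 0.0
    with pytest.warns(UserWarning):
        assert rep.f1 == 0.0


def test_balanced_accuracy_printed_values():
    assert balanced_accuracy(0.80, 0.68) == pytest.approx(0.74)
    assert balanced_accuracy(0.45, 0.95) == pytest.approx(0.70)
    assert balanced_accuracy(1.0, 1.0) == 1.0
    with pytest.raises(ValueError):
        balanced_accuracy(1.2, 0.5)


def test_balanced_accuracy_consistent_with_report():
    rep = ClassificationReport(tp=7, fp=3, fn=2, tn=11)
    assert balanced_accuracy(rep.sensitivity, rep.specificity) == rep.balanced_accuracy


def fisher_p_oracle(table):
    """Exhaustive two-sided Fisher p over all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))


@given(
    st.tuples(
        st.integers(1, 8), st.integers(1, 8), st.integers(1, 8), st.integers(1, 8)
    )
)
def test_fisher_p_matches_enumeration_oracle(cells):
    a, b, c, d = cells
    res = fisher_exact_2x2([[a, b], [c, d]])
    assert res.p_value == pytest.approx(fisher_p_oracle([[a, b], [c, d]]), rel=1e-8)
    assert res.odds_ratio == pytest.approx((a * d) / (b * c))


def test_fisher_missingness_contingency_reproduces_reported_or():
    # early-week missing cells: 23/140 in the small cohort vs 46/828 in training
    res = fisher_exact_2x2([[23, 117], [46, 782]])
    assert res.odds_ratio == pytest.approx(3.34, abs=0.005)
    assert res.ci_low == pytest.approx(1.86, abs=0.005)
    assert res.ci_high == pytest.approx(5.86, abs=0.005)
    assert res.p_value < 0.001


def test_fisher_invariance_under_transpose_and_swaps():
    t = [[3, 9], [7, 2]]
    base = fisher_exact_2x2(t).p_value
    transposed = fisher_exact_2x2(np.array(t).T).p_value
    swapped = fisher_exact_2x2([[2, 7], [9, 3]]).p_value
    assert transposed == pytest.approx(base, rel=1e-12)
    assert swapped == pytest.approx(base, rel=1e-12)


def test_fisher_null_table_and_errors():
    res = fisher_exact_2x2([[10, 10], [10, 10]])
    assert res.odds_ratio == 1.0
    assert res.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 5], [0, 7]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
    woolf = fisher_exact_2x2([[23, 117], [46, 782]], ci_method="sample")
    assert woolf.ci_low < woolf.odds_ratio < woolf.ci_high


def test_compare_to_therapists_deltas():
    truth = [True, True, False, False]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model, therapist, deltas = compare_to_therapists(truth, truth, [False] * 4)
    assert model.f1 == 1.0
    assert deltas["f1"] == pytest.approx(1.0)
    _, _, zero = compare_to_therapists(truth, truth, truth)
    assert all(v == 0.0 for v in zero.values())
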