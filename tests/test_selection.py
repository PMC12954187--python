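"""CV harness: splitting, pooled confusion arithmetic, selection rules."""

import warnings

import numpy as np
import pandas as pd
import pytest

from earlywarn.metrics import ClassificationReport
from earlywarn.selection import (
    ComparatorCandidate,
    CVResult,
    cross_validate,
    evaluate_holdout,
    feature_table,
    select_best,
    split_train_test,
)
from earlywarn.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="module")
def cohort261():
    return generate_cohort(CohortConfig(n_participants=261, seed=17))


def test_split_exact_study_sizes(cohort261):
    train, test = split_train_test(cohort261, seed=1, train_size=207, test_size=54)
    assert len(train.baseline) == 207
    assert len(test.baseline) == 54
    assert set(train.baseline.index).isdisjoint(test.baseline.index)
    assert set(train.baseline.index) | set(test.baseline.index) == set(
        cohort261.baseline.index
    )


def test_split_preserves_label_proportion(cohort261):
    train, test = split_train_test(cohort261, seed=1, train_fraction=0.8)
    overall = cohort261.true_labels.mean()
    assert train.true_labels.mean() == pytest.approx(overall, abs=1 / len(test.baseline))
    assert test.true_labels.mean() == pytest.approx(overall, abs=1.5 / len(test.baseline))


def test_split_same_seed_same_split(cohort261):
    a1, b1 = split_train_test(cohort261, seed=5)
    a2, b2 = split_train_test(cohort261, seed=5)
    assert list(a1.baseline.index) == list(a2.baseline.index)
    assert list(b1.baseline.index) == list(b2.baseline.index)


def test_split_fails_with_singleton_class():
    cohort = generate_cohort(
        CohortConfig(n_participants=20, beta1=-8.0, sd_u1=0.0, seed=2)
    )
    # beta1=-8 with no slope heterogeneity: everyone responds
    assert cohort.true_labels.sum() == 0
    with pytest.raises(ValueError, match="stratification"):
        split_train_test(cohort)


class _ConstantModel:
    """Duck-typed sklearn-style model predicting a fixed label."""

    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value, dtype=bool)


@pytest.fixture
def always_responder_candidate():
    class Candidate:
        candidate_id = "always_responder"
        n_parameters = 0
        covariates = ("pid5bf",)

        def build(self, inner_seed):
            return _ConstantModel(False)

    return Candidate()


def test_always_responder_candidate_scores_zero_f1(small_cohort, always_responder_candidate):
    results = cross_validate([always_responder_candidate], small_cohort, k=5, seed=3)
    (res,) = results
    assert small_cohort.true_labels.sum() > 0
    assert res.pooled.tp == 0
    assert res.f1 == 0.0


def test_cv_counts_partition_training_set(small_cohort, always_responder_candidate):
    (res,) = cross_validate([always_responder_candidate], small_cohort, k=5, seed=3)
    assert len(res.fold_counts) == 5
    assert res.pooled.n == len(small_cohort.baseline)
    truth = small_cohort.true_labels
    assert res.pooled.fn == int(truth.sum())
    assert res.pooled.tn == int((~truth).sum())


def test_pooled_f1_matches_hand_confusion_arithmetic():
    # two folds with hand-set counts: pooled TP=3, FP=2, FN=1, TN=6
    res = CVResult(
        candidate_id="hand", n_parameters=1,
        fold_counts=((2, 1, 0, 3), (1, 1, 1, 3)),
    )
    precision, recall = 3 / 5, 3 / 4
    assert res.f1 == pytest.approx(2 * precision * recall / (precision + recall))


def test_select_best_rules():
    mk = lambda cid, counts, npar, order: CVResult(cid, npar, (counts,), order)
    # F1s 0.65 / 0.52 / 0.40 -> argmax
    a = mk("a", (13, 7, 7, 23), 5, 0)  # F1 = 26/40 = 0.65
    b = mk("b", (13, 14, 10, 13), 5, 1)  # F1 = 26/50 = 0.52
    c = mk("c", (10, 15, 15, 10), 5, 2)  # F1 = 20/50 = 0.40
    assert select_best([b, a, c]) == "a"
    assert select_best([a]) == "a"
    # equal F1: fewer parameters wins, then declared order
    t3 = mk("three_par", (10, 5, 5, 30), 3, 1)
    t5 = mk("five_par", (10, 5, 5, 30), 5, 0)
    assert select_best([t5, t3]) == "three_par"
    t3b = mk("declared_first", (10, 5, 5, 30), 3, 0)
    assert select_best([t3b, t3]) == "declared_first"
    with pytest.raises(ValueError):
        select_best([])


def test_select_best_permutation_invariant():
    rng = np.random.default_rng(4)
    results = [
        CVResult(f"c{i}", 4, ((int(r[0]), int(r[1]), int(r[2]), int(r[3])),), i)
        for i, r in enumerate(rng.integers(1, 20, size=(6, 4)))
    ]
    best = select_best(results)
    for _ in range(5):
        perm = list(rng.permutation(len(results)))
        assert select_best([results[i] for i in perm]) == best


def test_feature_table_imputation_uses_training_means(small_cohort):
    X, means = feature_table(small_cohort.scores, small_cohort.baseline, ("pid5bf",))
    assert list(X.columns) == ["qids_w0", "qids_w1", "qids_w2", "qids_w3", "change_w3", "pid5bf"]
    assert not X.isna().any().any()
    # transforming a second table with the stored means, not its own
    sub = small_cohort.scores[small_cohort.scores["week"] <= 3].copy()
    sub.loc[sub["week"] == 2, "qids"] = np.nan
    X2, _ = feature_table(sub, small_cohort.baseline, ("pid5bf",), impute_means=means)
    assert (X2["qids_w2"] == means["qids_w2"]).all()


def test_comparator_validation_and_holdout(small_cohort):
    with pytest.raises(ValueError, match="family"):
        ComparatorCandidate(family="svm")
    train, test = split_train_test(small_cohort, seed=2)
    cand = ComparatorCandidate(family="naive_bayes")
    rep = evaluate_holdout(cand, train, test, seed=0)
    assert isinstance(rep, ClassificationReport)
    assert rep.n == len(test.baseline)


def test_holdout_perfect_and_all_negative_conventions():
    perfect = ClassificationReport(tp=4, fp=0, fn=0, tn=8)
    assert perfect.f1 == 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        all_negative = ClassificationReport(tp=0, fp=0, fn=4, tn=8)
        assert all_negative.f1 == 0.0
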