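"""Supervised-learning harness: stratified CV, F1 selection, holdout testing.

Candidate predictors of week-3 at-risk status come in two kinds:

* trajectory candidates — the Bayesian growth model with one change-term
  family (logarithmic / linear / quadratic) and a covariate set, scored by
  fit + posterior prediction + response-criterion flagging on held-out
  participants' weeks 0..3;
* comparator classifiers — Random Forest, Gaussian Naive Bayes and
  elastic-net logistic regression (scikit-learn) on a flat feature table of
  weeks 0..3 scores (training-fold mean imputation), the week3-week0 change
  and the baseline covariates, with hyperparameters tuned inside each
  training fold.

Both kinds flow through one confusion pipeline: per fold, boolean at-risk
flags are compared with true non-response labels; fold counts are pooled
(micro) and F1 computed on the pooled counts with non-responder as the
positive class. The candidate with the highest pooled F1 wins; ties go to
the fewer-parameter candidate, then to declared order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .criterion import CriterionConfig
from .metrics import ClassificationReport, confusion_report
from .simulate import TrueCohort
from .trajectory import ModelSpec, fit as fit_trajectory, predict_cohort

__all__ = [
    "TrajectoryCandidate",
    "ComparatorCandidate",
    "CVResult",
    "default_candidates",
    "split_train_test",
    "cross_validate",
    "select_best",
    "evaluate_holdout",
]


@dataclass(frozen=True)
class TrajectoryCandidate:
    """A growth-model candidate identified by its ModelSpec."""

    spec: ModelSpec
    name: str = ""

    @property
    def candidate_id(self) -> str:
        return self.name or f"trajectory_{self.spec.change_term}"

    @property
    def n_parameters(self) -> int:
        return self.spec.n_parameters


# comparator hyperparameter grids, tuned by inner CV within each training fold
_COMPARATORS = {
    "random_forest": (
        lambda seed: RandomForestClassifier(n_estimators=300, random_state=seed),
        {"max_features": [1, "sqrt", 0.5, None]},  # mtry analogue
    ),
    "naive_bayes": (
        lambda seed: GaussianNB(),
        {"var_smoothing": [1e-9, 1e-6, 1e-3]},
    ),
    "glm_elastic_net": (
        lambda seed: Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        penalty="elasticnet", solver="saga", max_iter=5000, random_state=seed
                    ),
                ),
            ]
        ),
        {"clf__C": [0.03, 0.3, 3.0], "clf__l1_ratio": [0.1, 0.5, 0.9]},  # lambda + mixing
    ),
}


@dataclass(frozen=True)
class ComparatorCandidate:
    """A scikit-learn comparator family with its hyperparameter grid."""

    family: str
    covariates: tuple[str, ...] = ("pid5bf",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in _COMPARATORS:
            raise ValueError(
                f"family must be one of {sorted(_COMPARATORS)}, got {self.family!r}"
            )

    @property
    def candidate_id(self) -> str:
        return self.family

    @property
    def n_parameters(self) -> int:
        # coarse count for tie-breaking only: features + intercept for the
        # linear model; tree/kernel families count as effectively unbounded
        n_feat = 4 + 1 + len(self.covariates)
        if self.family == "glm_elastic_net":
            return n_feat + 1
        if self.family == "naive_bayes":
            return 2 * n_feat + 1
        return 10**6

    def build(self, inner_seed: int) -> GridSearchCV:
        maker, grid = _COMPARATORS[self.family]
        return GridSearchCV(
            maker(self.seed),
            grid,
            scoring="f1",
            cv=StratifiedKFold(3, shuffle=True, random_state=inner_seed),
            n_jobs=1,
        )


Candidate = TrajectoryCandidate | ComparatorCandidate


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation outcome for one candidate."""

    candidate_id: str
    n_parameters: int
    fold_counts: tuple[tuple[int, int, int, int], ...]  # (tp, fp, fn, tn) per fold
    order: int = field(default=0)

    @property
    def pooled(self) -> ClassificationReport:
        tp, fp, fn, tn = (sum(c[i] for c in self.fold_counts) for i in range(4))
        return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn)

    @property
    def f1(self) -> float:
        return self.pooled.f1


def default_candidates(
    mcmc_seed: int = 0,
    covariates: tuple[str, ...] = ("pid5bf",),
    walkers: int = 16,
    warmup: int = 300,
    draws: int = 400,
    rhat_threshold: float = 1.05,
) -> list[Candidate]:
    """The benchmark slate: three change-term families plus three comparators.

    Trajectory candidates default to a reduced MCMC plan (fewer walkers and
    draws, a 1.05 R-hat gate) suited to repeated fitting inside CV folds;
    the final selected model should be refit at the full default plan.
    """
    traj = [
        TrajectoryCandidate(
            ModelSpec(
                change_term=ct,
                covariates=covariates,
                walkers=walkers,
                warmup=warmup,
                draws=draws,
                seed=mcmc_seed,
                rhat_threshold=rhat_threshold,
            )
        )
        for ct in ("logarithmic", "linear", "quadratic")
    ]
    comp = [ComparatorCandidate(family=f, covariates=covariates, seed=mcmc_seed)
            for f in ("random_forest", "naive_bayes", "glm_elastic_net")]
    return traj + comp


def split_train_test(
    cohort: TrueCohort,
    train_fraction: float = 0.80,
    seed: int = 0,
    train_size: int | None = None,
    test_size: int | None = None,
) -> tuple[TrueCohort, TrueCohort]:
    """Stratified (on true response label) disjoint, exhaustive train/test split.

    ``train_size``/``test_size`` override the fraction when exact counts are
    required. A label class with fewer than 2 members cannot be stratified.
    """
    labels = cohort.true_labels
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("stratification requires >= 2 members in each label class")
    ids = labels.index.to_numpy()
    train_ids, test_ids = train_test_split(
        ids,
        train_size=train_size if train_size is not None else train_fraction,
        test_size=test_size,
        stratify=labels.to_numpy(),
        random_state=seed,
    )
    return _subset(cohort, train_ids), _subset(cohort, test_ids)


def _subset(cohort: TrueCohort, ids) -> TrueCohort:
    idset = set(ids)
    from dataclasses import replace

    return replace(
        cohort,
        scores=cohort.scores[cohort.scores["participant_id"].isin(idset)].reset_index(drop=True),
        baseline=cohort.baseline.loc[cohort.baseline["participant_id"].isin(idset)],
        random_effects=cohort.random_effects.loc[cohort.random_effects.index.isin(idset)],
        true_post=cohort.true_post.loc[cohort.true_post.index.isin(idset)],
        deleted=None,
    )


def feature_table(
    scores: pd.DataFrame,
    baseline: pd.DataFrame,
    covariates: tuple[str, ...],
    impute_means: pd.Series | None = None,
    max_week: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Flat per-participant features for the comparator classifiers.

    Columns: qids_w0..qids_w3 (missing cells imputed with training means),
    change_w3 = qids_w3 - qids_w0, plus the baseline covariates. Returns the
    table and the column means actually used for imputation (computed from
    this table when ``impute_means`` is None — pass the training means when
    transforming validation/test data).
    """
    obs = scores.dropna(subset=["qids"])
    obs = obs[obs["week"] <= max_week]
    wide = obs.pivot(index="participant_id", columns="week", values="qids")
    wide = wide.reindex(columns=range(max_week + 1))
    wide.columns = [f"qids_w{w}" for w in range(max_week + 1)]
    wide = wide.reindex(sorted(scores["participant_id"].unique()))
    if impute_means is None:
        impute_means = wide.mean()
    wide = wide.fillna(impute_means)
    wide["change_w3"] = wide[f"qids_w{max_week}"] - wide["qids_w0"]
    for c in covariates:
        wide[c] = baseline[c].reindex(wide.index)
    return wide, impute_means


def _score_fold(
    candidate: Candidate,
    train: TrueCohort,
    val: TrueCohort,
    criterion: CriterionConfig,
    inner_seed: int,
) -> tuple[int, int, int, int]:
    """Fit one candidate on a training fold, flag the held-out fold, count."""
    truth = val.true_labels
    if isinstance(candidate, TrajectoryCandidate):
        draws = fit_trajectory(train.scores, train.baseline, candidate.spec)
        preds = predict_cohort(
            draws, val.scores, val.baseline, criterion=criterion,
            n_draws=1000, seed=inner_seed,
        )
        flags = preds["at_risk"].reindex(truth.index)
    else:
        X_train, means = feature_table(train.scores, train.baseline, candidate.covariates)
        X_val, _ = feature_table(
            val.scores, val.baseline, candidate.covariates, impute_means=means
        )
        model = candidate.build(inner_seed)
        model.fit(X_train.to_numpy(), train.true_labels.loc[X_train.index].to_numpy())
        flags = pd.Series(
            model.predict(X_val.to_numpy()).astype(bool), index=X_val.index
        ).reindex(truth.index)
    rep = confusion_report(truth, flags)
    return rep.tp, rep.fp, rep.fn, rep.tn


def cross_validate(
    candidates: list[Candidate],
    train: TrueCohort,
    k: int = 5,
    seed: int = 0,
    criterion: CriterionConfig | None = None,
) -> list[CVResult]:
    """Stratified k-fold CV of every candidate through one confusion pipeline."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not candidates:
        raise ValueError("need at least one candidate")
    criterion = criterion or CriterionConfig()
    labels = train.true_labels
    ids = labels.index.to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(ids, labels.to_numpy()))
    results = []
    for order, cand in enumerate(candidates):
        counts = []
        for fold_i, (tr_idx, va_idx) in enumerate(folds):
            counts.append(
                _score_fold(
                    cand,
                    _subset(train, ids[tr_idx]),
                    _subset(train, ids[va_idx]),
                    criterion,
                    inner_seed=(seed * 1000 + fold_i) % (2**31),
                )
            )
        results.append(
            CVResult(
                candidate_id=cand.candidate_id,
                n_parameters=cand.n_parameters,
                fold_counts=tuple(counts),
                order=order,
            )
        )
    return results


def select_best(results: list[CVResult]) -> str:
    """Argmax of pooled F1; ties to fewest parameters, then declared order."""
    if not results:
        raise ValueError("empty result list")
    best = min(results, key=lambda r: (-r.f1, r.n_parameters, r.order))
    return best.candidate_id


def evaluate_holdout(
    candidate: Candidate,
    train: TrueCohort,
    test: TrueCohort,
    seed: int = 0,
    criterion: CriterionConfig | None = None,
) -> ClassificationReport:
    """Refit one candidate on the full training set and score it on the test set."""
    if len(test.baseline) == 0:
        raise ValueError("empty test set")
    criterion = criterion or CriterionConfig()
    tp, fp, fn, tn = _score_fold(candidate, train, test, criterion, inner_seed=seed)
    return ClassificationReport(tp=tp, fp=fp, fn=fn, tn=tn)
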