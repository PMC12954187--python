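"""Confusion-matrix metrics and contingency analyses for at-risk classification.

The positive class throughout is *non-responder*: a true positive is a
participant correctly flagged as at risk of non-response. Metrics with a zero
denominator are reported as 0.0 (with a warning) so that degenerate
cross-validation folds remain scoreable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "ClassificationReport",
    "ContingencyResult",
    "confusion_report",
    "balanced_accuracy",
    "fisher_exact_2x2",
    "compare_to_therapists",
]


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: denominator is zero, reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts plus all derived metrics for one classifier.

    Counts use non-responder as the positive class; every derived field is a
    pure function of the four counts.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp, "precision")

    @property
    def ppv(self) -> float:
        """Positive predictive value; identical to precision by construction."""
        return self.precision

    @property
    def recall(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn, "recall")

    @property
    def sensitivity(self) -> float:
        return self.recall

    @property
    def specificity(self) -> float:
        return _safe_div(self.tn, self.tn + self.fp, "specificity")

    @property
    def npv(self) -> float:
        return _safe_div(self.tn, self.tn + self.fn, "npv")

    @property
    def accuracy(self) -> float:
        return _safe_div(self.tp + self.tn, self.n, "accuracy")

    @property
    def balanced_accuracy(self) -> float:
        return balanced_accuracy(self.sensitivity, self.specificity)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return _safe_div(2.0 * p * r, p + r, "f1")

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "precision": self.precision,
            "recall": self.recall,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 contingency analysis: sample odds ratio, exact CI and Fisher p."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    ci_method: str = field(default="conditional")


def _align(truth, predicted) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(truth, pd.Series) and isinstance(predicted, pd.Series):
        if set(truth.index) != set(predicted.index):
            raise ValueError("truth and predicted have mismatched participant ids")
        predicted = predicted.reindex(truth.index)
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(
            f"truth ({t.shape}) and predicted ({p.shape}) differ in length"
        )
    return t, p


def confusion_report(truth, predicted) -> ClassificationReport:
    """Confusion counts and metrics for boolean at-risk labels.

    Parameters
    ----------
    truth, predicted
        Boolean arrays (or pd.Series indexed by participant id, aligned on the
        id set) where True marks a non-responder / at-risk flag.
    """
    t, p = _align(truth, predicted)
    return ClassificationReport(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Arithmetic mean of sensitivity and specificity."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return 0.5 * (sensitivity + specificity)


def fisher_exact_2x2(counts, ci_method: str = "conditional") -> ContingencyResult:
    """Fisher's exact test with sample odds ratio and 95% CI for a 2x2 table.

    The reported odds ratio is the unconditional sample OR (a*d)/(b*c); the
    two-sided p-value sums hypergeometric probabilities of tables (at fixed
    margins) no more likely than the observed one. The 95% CI defaults to the
    exact conditional method; ``ci_method='sample'`` gives the Woolf (log-OR
    normal-approximation) interval instead.
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    (a, b), (c, d) = table
    if b * c == 0 or (a == 0 and d == 0):
        raise ValueError("a zero margin/diagonal leaves the odds ratio undefined")
    sample_or = (a * d) / (b * c)
    p_value = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    if ci_method == "conditional":
        ci = _scipy_odds_ratio(table, kind="conditional").confidence_interval(0.95)
        lo, hi = float(ci.low), float(ci.high)
    elif ci_method == "sample":
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z = stats.norm.ppf(0.975)
        lo, hi = float(np.exp(np.log(sample_or) - z * se)), float(
            np.exp(np.log(sample_or) + z * se)
        )
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ContingencyResult(
        counts=((int(a), int(b)), (int(c), int(d))),
        odds_ratio=float(sample_or),
        ci_low=lo,
        ci_high=hi,
        p_value=p_value,
        ci_method=ci_method,
    )


def compare_to_therapists(
    truth, model_flags, therapist_flags
) -> tuple[ClassificationReport, ClassificationReport, dict[str, float]]:
    """Score model and therapist at-risk flags against the same truth.

    Returns the two reports plus metric deltas (model minus therapist).
    """
    model_report = confusion_report(truth, model_flags)
    therapist_report = confusion_report(truth, therapist_flags)
    md, td = model_report.as_dict(), therapist_report.as_dict()
    deltas = {
        k: md[k] - td[k]
        for k in ("precision", "recall", "specificity", "f1", "balanced_accuracy", "accuracy")
    }
    return model_report, therapist_report, deltas
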