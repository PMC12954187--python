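"""Proportion Improvement (PI) response criterion.

The PI method scores change from pre- to post-treatment as the proportion of
*true change* relative to *possible change*, on two denominators:

* overall: possible change is the full distance from the pre score to the
  scale minimum, ``(pre - post) / (pre - scale_min)``;
* within the clinical range: possible change is the distance from the pre
  score down to the clinical cutoff ``C``; improvement below ``C`` is not
  credited to this component, ``(pre - max(post, C)) / (pre - C)``.

A participant responds when both proportions meet their thresholds
(>= 50% within the clinical range and >= 25% overall, ties counting as met).
Participants entering below the clinical cutoff have no defined clinical
range, and fall back to the overall proportion alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CriterionConfig",
    "ResponseLabel",
    "SubClinicalEntryError",
    "UndefinedImprovementError",
    "proportion_improvement",
    "classify_response",
    "label_cohort",
]


class UndefinedImprovementError(ValueError):
    """Raised when pre <= scale_min so that possible change is zero."""


class SubClinicalEntryError(ValueError):
    """Raised in strict mode for participants entering below the cutoff."""


@dataclass(frozen=True)
class CriterionConfig:
    """PI criterion parameters on the QIDS-A17-SR scale (0-27).

    clinical_cutoff is the screening threshold below which scores are
    considered not depressed (QIDS < 9).
    """

    clinical_cutoff: int = 9
    scale_min: int = 0
    scale_max: int = 27
    clinical_threshold: float = 0.50
    overall_threshold: float = 0.25
    strict: bool = False

    def __post_init__(self) -> None:
        if not self.scale_min <= self.clinical_cutoff <= self.scale_max:
            raise ValueError("clinical_cutoff must lie within the scale range")
        for name in ("clinical_threshold", "overall_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


@dataclass(frozen=True)
class ResponseLabel:
    participant_id: str
    pi_clinical: float
    pi_overall: float
    responder: bool

    @property
    def label(self) -> str:
        return "responder" if self.responder else "non-responder"


def proportion_improvement(
    pre: float, post: float, config: CriterionConfig | None = None
) -> tuple[float, float]:
    """Return (pi_clinical, pi_overall) for one pre/post score pair.

    Both proportions are reported unclipped; values below 0 indicate
    deterioration and above 1 cannot occur while post >= scale_min.
    """
    config = config or CriterionConfig()
    C = config.clinical_cutoff
    if pre <= config.scale_min:
        raise UndefinedImprovementError(
            f"pre score {pre} at or below scale minimum {config.scale_min}: "
            "possible change is zero"
        )
    pi_overall = (pre - post) / (pre - config.scale_min)
    if pre > C:
        pi_clinical = (pre - max(post, C)) / (pre - C)
    else:
        if config.strict:
            raise SubClinicalEntryError(
                f"pre score {pre} at or below clinical cutoff {C}"
            )
        pi_clinical = pi_overall
    return float(pi_clinical), float(pi_overall)


def classify_response(
    pre: float,
    post: float,
    config: CriterionConfig | None = None,
    participant_id: str = "",
) -> ResponseLabel:
    """Label one participant: responder iff both PI components meet threshold."""
    config = config or CriterionConfig()
    pi_clinical, pi_overall = proportion_improvement(pre, post, config)
    responder = (
        pi_clinical >= config.clinical_threshold
        and pi_overall >= config.overall_threshold
    )
    return ResponseLabel(
        participant_id=participant_id,
        pi_clinical=pi_clinical,
        pi_overall=pi_overall,
        responder=bool(responder),
    )


def label_cohort(
    scores: pd.DataFrame,
    config: CriterionConfig | None = None,
    final_week: int | None = None,
) -> pd.DataFrame:
    """Label every classifiable participant in a long-format score table.

    A participant is classifiable when both the week-0 and the final-week
    score are observed; the post-treatment score is the final scheduled
    week's observation (no carry-forward). Returns one row per participant
    with columns pi_clinical, pi_overall, label plus an ``unclassifiable``
    flag; the frame carries the cohort non-response rate among classified
    participants in ``frame.attrs['nonresponse_rate']``.
    """
    config = config or CriterionConfig()
    obs = scores.dropna(subset=["qids"])
    if final_week is None:
        final_week = int(obs["week"].max())
    wide = obs.pivot(index="participant_id", columns="week", values="qids")
    rows = []
    for pid in sorted(scores["participant_id"].unique()):
        pre = wide.at[pid, 0] if (pid in wide.index and 0 in wide.columns) else np.nan
        post = (
            wide.at[pid, final_week]
            if (pid in wide.index and final_week in wide.columns)
            else np.nan
        )
        if np.isnan(pre) or np.isnan(post) or pre <= config.scale_min:
            rows.append((pid, np.nan, np.nan, None, True))
            continue
        lab = classify_response(pre, post, config, participant_id=pid)
        rows.append((pid, lab.pi_clinical, lab.pi_overall, lab.label, False))
    out = pd.DataFrame(
        rows,
        columns=["participant_id", "pi_clinical", "pi_overall", "label", "unclassifiable"],
    ).set_index("participant_id")
    classified = out[~out["unclassifiable"]]
    out.attrs["n_classified"] = len(classified)
    out.attrs["nonresponse_rate"] = (
        float((classified["label"] == "non-responder").mean())
        if len(classified)
        else np.nan
    )
    return out
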