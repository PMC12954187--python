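"""Within-group outcome summaries: paired t-tests, effect sizes, group tables.

For each measure, pre/post pairs are listwise-deleted and summarized with a
dependent-samples t-test and a within-group standardized mean change. Two
effect-size variants are supported, since published within-group d values
are frequently ambiguous between them:

* ``pooled`` (default) — mean change divided by the pooled pre/post SD,
  sqrt((sd_pre^2 + sd_post^2)/2);
* ``change`` — mean change divided by the SD of the change scores (d_z,
  which relates to the paired t exactly as d_z = t / sqrt(n)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["OutcomeSummary", "paired_summary", "group_table"]

_D_VARIANTS = ("pooled", "change")


@dataclass(frozen=True)
class OutcomeSummary:
    measure: str
    n: int  # complete pairs after listwise deletion
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    t: float
    df: int
    p: float
    d: float
    d_variant: str


def paired_summary(
    pre, post, d_variant: str = "pooled", measure: str = ""
) -> OutcomeSummary:
    """Paired t and within-group effect size on complete pre/post pairs.

    Improvement (pre > post) yields a positive t and d. Incomplete pairs are
    listwise-deleted; fewer than 2 complete pairs, or zero variance of the
    change scores, is an error.
    """
    if d_variant not in _D_VARIANTS:
        raise ValueError(f"d_variant must be one of {_D_VARIANTS}, got {d_variant!r}")
    pre = pd.Series(np.asarray(pre, dtype=float))
    post = pd.Series(np.asarray(post, dtype=float))
    if len(pre) != len(post):
        raise ValueError("pre and post must be the same length")
    ok = pre.notna() & post.notna()
    pre, post = pre[ok].to_numpy(), post[ok].to_numpy()
    n = len(pre)
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    change = pre - post
    if np.allclose(change.std(ddof=1), 0.0):
        raise ValueError("zero variance of change scores: paired t undefined")
    t_res = stats.ttest_rel(pre, post)
    if d_variant == "pooled":
        denom = np.sqrt((pre.std(ddof=1) ** 2 + post.std(ddof=1) ** 2) / 2.0)
    else:
        denom = change.std(ddof=1)
    return OutcomeSummary(
        measure=measure,
        n=n,
        pre_mean=float(pre.mean()),
        pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()),
        post_sd=float(post.std(ddof=1)),
        t=float(t_res.statistic),
        df=n - 1,
        p=float(t_res.pvalue),
        d=float(change.mean() / denom),
        d_variant=d_variant,
    )


def group_table(
    data: pd.DataFrame,
    arms: pd.Series,
    measures: dict[str, list[str]],
    known_arms: tuple[str, ...] = ("on_track", "usual_at_risk", "adapted_at_risk"),
) -> pd.DataFrame:
    """Per-arm, per-timepoint mean (SD) descriptive table.

    ``data`` holds one row per participant (indexed by id) with one column
    per measure-timepoint; ``measures`` maps a measure name to its timepoint
    columns in display order; ``arms`` assigns each participant an arm label
    drawn from ``known_arms``. Empty arms are omitted with a warning;
    unknown labels are an error.
    """
    unknown = set(arms.dropna().unique()) - set(known_arms)
    if unknown:
        raise ValueError(f"unknown arm labels: {sorted(unknown)}")
    rows = []
    for measure, cols in measures.items():
        for arm in known_arms:
            members = arms[arms == arm].index.intersection(data.index)
            if len(members) == 0:
                import warnings

                warnings.warn(f"arm {arm!r} is empty for {measure}; omitted", stacklevel=2)
                continue
            row: dict[str, object] = {
                "measure": measure,
                "arm": arm,
                "n": len(members),
            }
            for col in cols:
                vals = data.loc[members, col].dropna()
                row[col] = (
                    f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})" if len(vals) > 1
                    else (f"{vals.mean():.2f} (--)" if len(vals) else "--")
                )
            rows.append(row)
    return pd.DataFrame(rows)
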