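"""Read, write and validate the long-format score and baseline tables.

Two CSV schemas are shared by every pipeline stage:

* ``scores.csv`` — participant_id, week, qids; one row per administered
  weekly QIDS-A17-SR measurement, empty qids cell meaning missing.
* ``baseline.csv`` — participant_id, pid5bf, qids_pre, plus optional gad7,
  ders16, true_label, arm columns.

Missing observations may appear either as an absent (participant, week) row
or as an empty qids cell; both are normalized to explicit NaN rows on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_scores",
    "read_baseline",
    "read_tables",
    "write_tables",
    "validate_scores",
    "missingness_table",
]

QIDS_MIN, QIDS_MAX = 0, 27


class SchemaError(ValueError):
    """A table violates the shared schema; message lists offending rows."""


def validate_scores(scores: pd.DataFrame, max_week: int | None = None) -> pd.DataFrame:
    """Validate and normalize a long score table.

    Enforces unique (participant_id, week), integer weeks >= 0 (within
    ``max_week`` when given) and qids in [0, 27] where present. Returns a
    copy with participant_id as string, week as int and qids as float
    (NaN = missing).
    """
    required = {"participant_id", "week", "qids"}
    missing_cols = required - set(scores.columns)
    if missing_cols:
        raise SchemaError(f"scores table lacks columns: {sorted(missing_cols)}")
    out = scores.loc[:, ["participant_id", "week", "qids"]].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    try:
        out["week"] = out["week"].astype(int)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"non-integer week values: {exc}") from exc
    out["qids"] = pd.to_numeric(out["qids"], errors="coerce")

    dup = out.duplicated(subset=["participant_id", "week"], keep=False)
    if dup.any():
        offenders = out.loc[dup, ["participant_id", "week"]].drop_duplicates()
        raise SchemaError(
            "duplicate (participant_id, week) rows: "
            + "; ".join(f"({r.participant_id}, {r.week})" for r in offenders.itertuples())
        )
    bad_week = (out["week"] < 0) | (
        (out["week"] > max_week) if max_week is not None else False
    )
    if bad_week.any():
        raise SchemaError(f"week out of range at rows {list(out.index[bad_week])}")
    present = out["qids"].notna()
    frac = out.loc[present, "qids"] % 1 != 0
    bad_score = present & (
        (out["qids"] < QIDS_MIN) | (out["qids"] > QIDS_MAX) | frac.reindex(out.index, fill_value=False)
    )
    if bad_score.any():
        raise SchemaError(
            f"qids out of [0, 27] or non-integer at rows {list(out.index[bad_score])}"
        )
    return out.sort_values(["participant_id", "week"]).reset_index(drop=True)


def read_scores(path: str | Path, max_week: int | None = None) -> pd.DataFrame:
    return validate_scores(pd.read_csv(path), max_week=max_week)


def read_baseline(path: str | Path) -> pd.DataFrame:
    base = pd.read_csv(path)
    if "participant_id" not in base.columns:
        raise SchemaError("baseline table lacks participant_id column")
    base["participant_id"] = base["participant_id"].astype(str)
    if base["participant_id"].duplicated().any():
        dups = base.loc[base["participant_id"].duplicated(), "participant_id"]
        raise SchemaError(f"duplicate baseline participant ids: {sorted(set(dups))}")
    if "qids_pre" in base.columns:
        bad = base["qids_pre"].notna() & (
            (base["qids_pre"] < QIDS_MIN) | (base["qids_pre"] > QIDS_MAX)
        )
        if bad.any():
            raise SchemaError(f"qids_pre out of range at rows {list(base.index[bad])}")
    return base.set_index("participant_id", drop=False)


def read_tables(
    scores_path: str | Path, baseline_path: str | Path, max_week: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the score and baseline tables.

    Baseline rows without any score row are kept with a warning; a baseline
    qids_pre that contradicts the week-0 score is a schema error.
    """
    scores = read_scores(scores_path, max_week=max_week)
    baseline = read_baseline(baseline_path)
    score_ids = set(scores["participant_id"])
    orphans = [pid for pid in baseline.index if pid not in score_ids]
    if orphans:
        import warnings

        warnings.warn(
            f"baseline ids absent from scores (rows kept): {orphans}", stacklevel=2
        )
    if "qids_pre" in baseline.columns:
        week0 = scores[scores["week"] == 0].set_index("participant_id")["qids"]
        joint = baseline["qids_pre"].dropna()
        common = joint.index.intersection(week0.dropna().index)
        conflict = common[(joint.loc[common] != week0.loc[common])]
        if len(conflict):
            raise SchemaError(
                f"qids_pre disagrees with week-0 score for: {list(conflict)}"
            )
    return scores, baseline


def write_tables(
    scores: pd.DataFrame,
    baseline: pd.DataFrame,
    scores_path: str | Path,
    baseline_path: str | Path,
) -> None:
    """Write the shared CSV schemas (UTF-8, header row, empty cell = missing)."""
    out = scores.copy()
    out["qids"] = out["qids"].map(lambda v: "" if pd.isna(v) else int(v))
    out.to_csv(scores_path, index=False)
    baseline.to_csv(baseline_path, index=False)


def _missing_observed(scores: pd.DataFrame, weeks: list[int]) -> tuple[int, int]:
    participants = scores["participant_id"].unique()
    expected = len(participants) * len(weeks)
    sub = scores[scores["week"].isin(weeks)]
    observed = int(sub["qids"].notna().sum())
    return expected - observed, observed


def missingness_table(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    weeks: list[int] | range | None = None,
) -> np.ndarray:
    """2x2 (missing, observed) counts for two cohorts over an early-week range.

    Expected cells per cohort are participants x |weeks|; a cell is missing
    when its row is absent or its qids value is empty. Default week range is
    0..3 (pre-treatment through treatment week 3). Rows are (table_a,
    table_b), columns (missing, observed).
    """
    weeks = list(weeks) if weeks is not None else [0, 1, 2, 3]
    if not weeks:
        raise ValueError("week range must be nonempty")
    ma, oa = _missing_observed(table_a, weeks)
    mb, ob = _missing_observed(table_b, weeks)
    return np.array([[ma, oa], [mb, ob]], dtype=int)
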