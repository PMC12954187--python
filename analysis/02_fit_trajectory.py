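"""Fit the Bayesian growth model to the development cohort's weeks 0-3.

Reads the cohort written by 01_simulate_cohorts.py, splits it 207/54
stratified on the true response label, fits the logarithmic-change model
with the PID-5-BF covariate to the training split, and reports the
posterior summary with convergence diagnostics. The posterior summary and
the training-split ids go to results/ so later stages reuse the same split.
"""

from pathlib import Path

import pandas as pd

from earlywarn.criterion import label_cohort
from earlywarn.tables import read_tables
from earlywarn.trajectory import ModelSpec, fit

SEED = 20240101
ROOT = Path(__file__).resolve().parent.parent / "results"


def load_development():
    scores, baseline = read_tables(
        ROOT / "cohorts" / "development_scores.csv",
        ROOT / "cohorts" / "development_baseline.csv",
    )
    return scores, baseline


def main() -> None:
    scores, baseline = load_development()
    from sklearn.model_selection import train_test_split

    labels = baseline["true_label"] == "non-responder"
    train_ids, test_ids = train_test_split(
        baseline.index.to_numpy(), train_size=207, test_size=54,
        stratify=labels.to_numpy(), random_state=SEED % (2**31),
    )
    pd.DataFrame({"participant_id": train_ids}).to_csv(ROOT / "train_ids.csv", index=False)
    pd.DataFrame({"participant_id": test_ids}).to_csv(ROOT / "test_ids.csv", index=False)

    train_scores = scores[scores["participant_id"].isin(train_ids)]
    draws = fit(train_scores, baseline, ModelSpec(seed=SEED % (2**31)))
    summary = draws.summary()
    summary.to_csv(ROOT / "posterior_summary.csv")
    print(f"fitted logarithmic trajectory model on {draws.n_participants} participants")
    print(summary.round(3).to_string())
    worst = max(draws.rhat.values())
    print(f"worst split R-hat {worst:.4f} (threshold {draws.spec.rhat_threshold})")
    rate = label_cohort(train_scores).attrs["nonresponse_rate"]
    print(f"criterion non-response rate among training completers: {rate:.1%}")


if __name__ == "__main__":
    main()
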