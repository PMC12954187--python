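"""Within-group outcomes for the trial-sized cohort.

Labels the 35-participant synthetic trial cohort with the PI criterion,
summarizes pre-to-post change with dependent-samples t-tests and
within-group effect sizes (both variants), and prints a per-arm descriptive
table where arms are defined by the week-3 at-risk flag of the trajectory
model fitted to the development cohort (flagged participants alternately
assigned adapted/usual, mimicking 1:1 randomization). Tables go to
results/outcomes_summary.csv and results/outcomes_by_arm.csv.
"""

from pathlib import Path

import pandas as pd

from earlywarn.criterion import label_cohort
from earlywarn.outcomes import group_table, paired_summary
from earlywarn.simulate import TrueCohort
from earlywarn.tables import read_tables
from earlywarn.trajectory import ModelSpec, fit, predict_cohort

SEED = 20240101
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    trial_scores, trial_baseline = read_tables(
        ROOT / "cohorts" / "trial_scores.csv", ROOT / "cohorts" / "trial_baseline.csv"
    )
    dev_scores, dev_baseline = read_tables(
        ROOT / "cohorts" / "development_scores.csv",
        ROOT / "cohorts" / "development_baseline.csv",
    )

    wide = trial_scores.dropna(subset=["qids"]).pivot(
        index="participant_id", columns="week", values="qids"
    )
    rows = []
    for variant in ("pooled", "change"):
        s = paired_summary(wide.get(0), wide.get(10), d_variant=variant, measure="qids")
        rows.append(vars(s))
    summary = pd.DataFrame(rows)
    summary.to_csv(ROOT / "outcomes_summary.csv", index=False)
    s = rows[0]
    print(
        f"QIDS pre {s['pre_mean']:.2f} ({s['pre_sd']:.2f}) -> post "
        f"{s['post_mean']:.2f} ({s['post_sd']:.2f}), n={s['n']}: "
        f"t({s['df']})={s['t']:.2f}, p={s['p']:.2g}; d_pooled={s['d']:.2f}, "
        f"d_change={rows[1]['d']:.2f}"
    )
    labels = label_cohort(trial_scores, final_week=10)
    print(
        f"criterion labels: {labels.attrs['n_classified']} classifiable, "
        f"non-response rate {labels.attrs['nonresponse_rate']:.0%}"
    )

    # arms from the deployed week-3 at-risk flag (adapted/usual alternation)
    draws = fit(dev_scores, dev_baseline, ModelSpec(seed=SEED % (2**31)))
    preds = predict_cohort(draws, trial_scores, trial_baseline, seed=SEED % (2**31))
    arms = pd.Series("on_track", index=preds.index, name="arm")
    flagged = [pid for pid in preds.index if preds.loc[pid, "at_risk"]]
    for i, pid in enumerate(flagged):
        arms.loc[pid] = "adapted_at_risk" if i % 2 == 0 else "usual_at_risk"
    print(f"week-3 flags: {len(flagged)}/{len(preds)} at risk")

    data = wide.rename(columns=lambda w: f"qids_w{w}")
    table = group_table(
        data, arms, {"QIDS-A17-SR": ["qids_w0", "qids_w3", "qids_w10"]}
    )
    table.to_csv(ROOT / "outcomes_by_arm.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
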