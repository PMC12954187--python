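"""Held-out evaluation of the trajectory model and therapist comparison.

Refits the logarithmic trajectory model on the full training split at the
full MCMC plan, flags the 54 held-out participants at treatment week 3,
and scores the flags against the true response labels. Also benchmarks
simulated therapist judgments (sensitivity 50%, specificity 65%) on the
same participants, and tests the early-week missingness contrast between
the development and trial cohorts with Fisher's exact test. Everything
goes to results/holdout_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from earlywarn.metrics import compare_to_therapists, fisher_exact_2x2
from earlywarn.selection import TrajectoryCandidate, evaluate_holdout
from earlywarn.simulate import TrueCohort, generate_therapist_labels
from earlywarn.tables import missingness_table, read_tables
from earlywarn.trajectory import ModelSpec, predict_cohort, fit

SEED = 20240101
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores, baseline = read_tables(
        ROOT / "cohorts" / "development_scores.csv",
        ROOT / "cohorts" / "development_baseline.csv",
    )
    train_ids = set(pd.read_csv(ROOT / "train_ids.csv")["participant_id"].astype(str))
    test_ids = set(pd.read_csv(ROOT / "test_ids.csv")["participant_id"].astype(str))
    pick = lambda ids: TrueCohort.from_tables(
        scores[scores["participant_id"].isin(ids)],
        baseline[baseline["participant_id"].isin(ids)],
    )
    train, test = pick(train_ids), pick(test_ids)

    candidate = TrajectoryCandidate(ModelSpec(seed=SEED % (2**31)))
    report = evaluate_holdout(candidate, train, test, seed=SEED % (2**31))
    print(
        f"holdout (n={report.n}): F1 {report.f1:.2f}, sensitivity "
        f"{report.sensitivity:.0%}, specificity {report.specificity:.0%}, "
        f"balanced accuracy {report.balanced_accuracy:.0%}, PPV {report.ppv:.0%}"
    )

    # model vs therapist judgment on the same held-out participants
    draws = fit(train.scores, train.baseline, candidate.spec)
    preds = predict_cohort(draws, test.scores, test.baseline, seed=SEED % (2**31))
    truth = test.true_labels.loc[preds.index]
    therapist = generate_therapist_labels(truth, 0.50, 0.65, seed=(SEED + 7) % (2**31))
    model_rep, ther_rep, deltas = compare_to_therapists(
        truth, preds["at_risk"], therapist
    )
    print(
        f"therapist judgment: F1 {ther_rep.f1:.2f}, balanced accuracy "
        f"{ther_rep.balanced_accuracy:.0%}; model advantage in balanced "
        f"accuracy {deltas['balanced_accuracy']:+.2f}"
    )

    # early-week missingness: trial cohort vs development cohort
    trial_scores, _ = read_tables(
        ROOT / "cohorts" / "trial_scores.csv", ROOT / "cohorts" / "trial_baseline.csv"
    )
    table = missingness_table(trial_scores, scores)
    fisher = fisher_exact_2x2(table)
    print(
        f"missingness weeks 0-3: trial {table[0,0]}/{table[0].sum()}, development "
        f"{table[1,0]}/{table[1].sum()}; OR {fisher.odds_ratio:.2f} "
        f"[{fisher.ci_low:.2f}, {fisher.ci_high:.2f}], p={fisher.p_value:.2g}"
    )

    out = {
        "holdout": report.as_dict(),
        "therapist": ther_rep.as_dict(),
        "deltas_model_minus_therapist": deltas,
        "missingness": {
            "table": table.tolist(),
            "odds_ratio": fisher.odds_ratio,
            "ci": [fisher.ci_low, fisher.ci_high],
            "p_value": fisher.p_value,
        },
    }
    (ROOT / "holdout_report.json").write_text(json.dumps(out, indent=2))
    print(f"report written to {ROOT/'holdout_report.json'}")


if __name__ == "__main__":
    main()
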