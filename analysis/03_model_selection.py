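"""Cross-validated F1 benchmark of all candidate at-risk classifiers.

Reads the development cohort and the training split saved by the previous
stages, runs stratified 5-fold cross-validation of the three trajectory
change-term families and the three comparator classifiers through one
confusion pipeline, and reports the pooled-F1 ranking and the selected
candidate. Per-candidate fold counts go to results/cv_results.csv.
"""

from pathlib import Path

import pandas as pd

from earlywarn.selection import cross_validate, default_candidates, select_best
from earlywarn.simulate import TrueCohort
from earlywarn.tables import read_tables

SEED = 20240101
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    scores, baseline = read_tables(
        ROOT / "cohorts" / "development_scores.csv",
        ROOT / "cohorts" / "development_baseline.csv",
    )
    train_ids = set(pd.read_csv(ROOT / "train_ids.csv")["participant_id"].astype(str))
    train = TrueCohort.from_tables(
        scores[scores["participant_id"].isin(train_ids)],
        baseline[baseline["participant_id"].isin(train_ids)],
    )
    candidates = default_candidates(mcmc_seed=SEED % (2**31))
    results = cross_validate(candidates, train, k=5, seed=SEED % (2**31))

    rows = []
    for res in results:
        pooled = res.pooled
        for fold_i, (tp, fp, fn, tn) in enumerate(res.fold_counts):
            rows.append(
                {"candidate": res.candidate_id, "fold": fold_i,
                 "tp": tp, "fp": fp, "fn": fn, "tn": tn}
            )
        print(
            f"{res.candidate_id:25s} pooled F1 {pooled.f1:.3f} "
            f"(precision {pooled.precision:.2f}, recall {pooled.recall:.2f})"
        )
    pd.DataFrame(rows).to_csv(ROOT / "cv_results.csv", index=False)
    best = select_best(results)
    (ROOT / "selected_candidate.txt").write_text(best + "\n")
    print(f"\nselected by pooled CV F1 (ties: fewest parameters): {best}")
    print(f"fold counts written to {ROOT/'cv_results.csv'}")


if __name__ == "__main__":
    main()
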