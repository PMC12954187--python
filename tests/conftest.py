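import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-participant cohort with default (calibrated) parameters."""
    from earlywarn.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def fitted_small():
    """A reduced-draws fit on a 60-participant cohort, shared across tests."""
    from earlywarn.simulate import CohortConfig, generate_cohort
    from earlywarn.trajectory import ModelSpec, fit

    cohort = generate_cohort(CohortConfig(n_participants=60, seed=21))
    spec = ModelSpec(walkers=16, warmup=300, draws=400, seed=4, rhat_threshold=1.1)
    return cohort, fit(cohort.scores, cohort.baseline, spec)


def make_scores(rows):
    """Long score table from (pid, week, qids) triples; qids None = missing."""
    return pd.DataFrame(
        [
            {"participant_id": pid, "week": w, "qids": (np.nan if q is None else float(q))}
            for pid, w, q in rows
        ]
    )
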