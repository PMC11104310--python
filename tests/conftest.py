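import numpy as np
import pandas as pd
import pytest

from pavlearn import ModelSpec, Parameters, gen_task_cohort
from pavlearn.task import CONDITIONS, GO, NOGO


@pytest.fixture(scope="session")
def full_spec():
    return ModelSpec.from_name("RW+noise+bias+2Pav+session")


@pytest.fixture(scope="session")
def dual_spec():
    return ModelSpec.from_name("RW+noise+bias+2Pav")


@pytest.fixture(scope="session")
def generic_params():
    return Parameters(
        alpha=0.25, beta=2.5, b=0.3, xi=0.08,
        pi_app=0.6, pi_av=0.4, pi_app_post=1.1, pi_av_post=0.9,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small task cohort (6 subjects, 5 administrations, 12 per condition).

    All five administrations are kept so the session-varying Pavlovian
    parameters stay identifiable at reduced trial counts.
    """
    trials, truth = gen_task_cohort(
        n_subjects=6, n_administrations=5, n_per_condition=12, seed=11
    )
    return trials, truth


def random_trial_frame(rng, n_trials, subject_id="S", administrations=(1,)):
    """Arbitrary (non-generative) trial sequences for likelihood tests."""
    rows = []
    for admin in administrations:
        for i in range(1, n_trials + 1):
            cond = CONDITIONS[rng.integers(4)]
            rows.append(
                {
                    "subject_id": subject_id,
                    "administration": admin,
                    "trial_index": i,
                    "condition": cond.name,
                    "action": GO if rng.random() < 0.5 else NOGO,
                    "outcome": int(rng.integers(-1, 2)),
                    "rt": np.nan,
                }
            )
    return pd.DataFrame(rows)
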