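import numpy as np
import pandas as pd
import pytest

from seqhabit.agents import MODELS
from seqhabit.simulate import CohortConfig, simulate_cohort
from seqhabit.task import make_task


@pytest.fixture(scope="session")
def graded_task():
    return make_task("graded_expt1")


@pytest.fixture(scope="session")
def orig_task():
    return make_task("original_binary", "reward_based")


@pytest.fixture(scope="session")
def expt2_task():
    return make_task("redstate_expt2")


@pytest.fixture(scope="session")
def small_mf_cohort(graded_task):
    """200 hybrid (flat mixture) agents on the graded task; used by the
    signature unit tests where direction, not power, is at stake."""
    cfg = CohortConfig(model=MODELS["No sequences"], task=graded_task,
                       n_agents=200, n_trials=125, seed=301)
    return simulate_cohort(cfg)


def toy_trials(rows):
    """Build a trial table from (subject, trial, a1, transition, s2, a2, r) tuples."""
    return pd.DataFrame(
        rows,
        columns=["subject", "trial", "s1_choice", "transition",
                 "s2_state", "s2_choice", "reward"],
    )


@pytest.fixture
def hand_table():
    """A 4-trial single-subject table with every lag feature exercised."""
    return toy_trials([
        (1, 1, "L1", "common", "green", "L2", 3.0),
        (1, 2, "L1", "rare", "yellow", "R2", -1.0),
        (1, 3, "R1", "common", "yellow", "R2", 2.0),
        (1, 4, "R1", "rare", "green", "L2", 0.0),
    ])
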