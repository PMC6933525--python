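"""Complete human-like datasets: model-generated choices plus reaction times.

The agent models produce choices but not latencies, so reaction times
are attached by a small additive generator grounded in the open-loop
logic of sequence execution: while running a chunked sequence no further
decision is needed at Stage 2, so those responses are faster.  The RT
model is deliberately minimal -- a baseline, a sequence-execution
speedup, a switch cost, and truncated Gaussian noise -- enough to make
the RT signature analyses testable end to end; it makes no attempt to
match human RT distributions quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import ModelSpec
from .simulate import CohortConfig, simulate_cohort
from .task import make_task

__all__ = ["RtModel", "generate_dataset", "observed_view", "OBSERVED_COLUMNS"]

#: columns exported in the "observed" (human-equivalent) view
OBSERVED_COLUMNS = [
    "subject", "trial", "s1_choice", "transition", "s2_state",
    "s2_choice", "reward", "rt1", "rt2",
]


@dataclass(frozen=True)
class RtModel:
    """Additive Stage-2 reaction-time generator (milliseconds).

    rt2 = base2 - seq_speedup * 1(open loop) + switch_cost * 1(Stage-2
    action differs from previous trial) + noise, truncated at ``min_rt``
    so latencies stay positive.  rt1 is baseline plus noise.
    """

    base1: float = 900.0
    base2: float = 700.0
    seq_speedup: float = 80.0
    switch_cost: float = 50.0
    noise_sd: float = 200.0
    min_rt: float = 100.0

    def __post_init__(self) -> None:
        if self.base2 <= 0 or self.base1 <= 0:
            raise ValueError("RT baselines must be positive")
        if self.min_rt <= 0:
            raise ValueError("min_rt must be positive")


DEFAULT_RT_MODEL = RtModel()


def generate_dataset(
    experiment: int,
    model: ModelSpec,
    n_subjects: int = 96,
    n_trials: int = 125,
    rt_model: RtModel = DEFAULT_RT_MODEL,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full dataset for Experiment 1 or 2, with reaction times.

    Returns the *hidden-truth* table: it includes the latent
    ``option_latent`` column marking open-loop sequence execution, which
    real data never contain.  Use :func:`observed_view` (or the observed
    export in :mod:`seqhabit.io`) for the human-equivalent schema.
    """
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    task = make_task("graded_expt1" if experiment == 1 else "redstate_expt2", "path_based")
    cohort = CohortConfig(model=model, task=task, n_agents=n_subjects,
                          n_trials=n_trials, seed=seed)
    df = simulate_cohort(cohort)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(n_subjects + 1)[-1])
    open_loop = (df["option_latent"] != "").to_numpy()
    prev_a2 = df.groupby("subject")["s2_choice"].shift(1)
    switched = (df["s2_choice"] != prev_a2) & prev_a2.notna()
    n = len(df)
    rt2 = (
        rt_model.base2
        - rt_model.seq_speedup * open_loop
        + rt_model.switch_cost * switched.to_numpy()
        + rng.normal(0.0, rt_model.noise_sd, size=n)
    )
    rt1 = rt_model.base1 + rng.normal(0.0, rt_model.noise_sd, size=n)
    df["rt1"] = np.maximum(rt1, rt_model.min_rt)
    df["rt2"] = np.maximum(rt2, rt_model.min_rt)
    return df


def observed_view(table: pd.DataFrame) -> pd.DataFrame:
    """Drop latent columns, yielding the schema observable in real data."""
    cols = [c for c in OBSERVED_COLUMNS if c in table.columns]
    return table[cols].copy()
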