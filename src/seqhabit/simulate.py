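"""Cohort simulation: draw agents from the population priors and play sessions.

Agent parameters are sampled from the population priors used throughout
the study: alpha ~ Beta(1.1, 1.1), beta1 and beta2 ~ Gamma(shape 1.2,
scale 5) independently, nu ~ Normal(0, 1), and, where a model uses them,
omega ~ Uniform(0, 1) and lambda ~ Uniform(0, 1) (omega is pinned at 1
for purely model-based controllers).

Cohorts default to 1,000 agents playing 125 trials each.  Every agent
receives its own child seed (spawned from the cohort seed by a
counter-based scheme), so a cohort is reproducible regardless of any
agent-level parallelism or iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import Agent, AgentConfig, AgentParams, DEFAULT_CONFIG, ModelSpec, run_trial
from .task import TaskSpec, advance_walk, init_walk, STAGE1_ACTIONS, STAGE2_ACTIONS, STAGE2_STATES

__all__ = ["CohortConfig", "sample_params", "run_session", "simulate_cohort"]


@dataclass
class CohortConfig:
    """One simulated cohort: a model, a task, sizes, and a seed."""

    model: ModelSpec
    task: TaskSpec
    n_agents: int = 1000
    n_trials: int = 125
    seed: int = 0
    agent_config: AgentConfig = field(default_factory=AgentConfig)

    def __post_init__(self) -> None:
        if self.n_agents < 1 or self.n_trials < 1:
            raise ValueError("n_agents and n_trials must be at least 1")


def sample_params(model: ModelSpec, rng: np.random.Generator) -> AgentParams:
    """Draw one agent's parameters from the population priors."""
    alpha = float(rng.beta(1.1, 1.1))
    beta1 = float(rng.gamma(1.2, 5.0))
    beta2 = float(rng.gamma(1.2, 5.0))
    nu = float(rng.normal(0.0, 1.0))
    omega = float(rng.uniform()) if model.uses_omega else 1.0
    lam = float(rng.uniform()) if model.uses_lambda else 0.0
    return AgentParams(alpha=alpha, beta1=beta1, beta2=beta2, nu=nu, omega=omega, lam=lam)


def run_session(
    model: ModelSpec,
    params: AgentParams,
    spec: TaskSpec,
    rng: np.random.Generator,
    n_trials: int | None = None,
    agent_config: AgentConfig = DEFAULT_CONFIG,
) -> list:
    """Simulate one agent's session; returns a list of TrialRecords.

    The reward walk starts from uniform draws over its bounds and takes
    one reflecting step after every trial.
    """
    n = spec.n_trials if n_trials is None else n_trials
    agent = Agent(model, params, spec, agent_config)
    walk = init_walk(spec, rng)
    records = []
    for t in range(1, n + 1):
        records.append(run_trial(agent, walk, rng, trial=t))
        walk = advance_walk(walk, spec, rng)
    return records


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort and return the long-format trial table.

    Columns: subject, trial (1-based), s1_choice, transition, s2_state,
    s2_choice, reward, and the latent (unobservable in real data)
    ``option_latent`` column naming the sequence executed open-loop, or
    "" for a deliberate trial.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_agents)
    rows: dict[str, list] = {
        "subject": [], "trial": [], "s1_choice": [], "transition": [],
        "s2_state": [], "s2_choice": [], "reward": [], "option_latent": [],
    }
    for i, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        params = sample_params(config.model, rng)
        records = run_session(
            config.model, params, config.task, rng,
            n_trials=config.n_trials, agent_config=config.agent_config,
        )
        for rec in records:
            rows["subject"].append(i)
            rows["trial"].append(rec.trial)
            rows["s1_choice"].append(STAGE1_ACTIONS[rec.s1_choice])
            rows["transition"].append(rec.transition)
            rows["s2_state"].append(STAGE2_STATES[rec.s2_state])
            rows["s2_choice"].append(STAGE2_ACTIONS[rec.s2_choice])
            rows["reward"].append(rec.reward)
            rows["option_latent"].append(rec.option_latent)
    return pd.DataFrame(rows)
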