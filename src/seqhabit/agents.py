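"""Value computation and choice rules for the candidate decision models.

Five named models span the space of controllers compared in the study:

===============================  ==============  ====================  =====================
name                             uses sequences  single-step control   sequence control
===============================  ==============  ====================  =====================
No sequences                     no              mixture of MF and MB  --
Pure MB                          yes             MB                    MB
Mixture-actions/MB-sequences     yes             mixture of MF and MB  MB
MB-actions/Mixture-sequences     yes             MB                    mixture of MF and MB
Mixture-actions/Mixture-sequences yes            mixture of MF and MB  mixture of MF and MB
===============================  ==============  ====================  =====================

Model-based values follow the Bellman recursion over a known transition
model T' and a learned reward model R' (delta rule, shared learning rate);
model-free values follow Q-learning with an eligibility trace that passes
the Stage-2 reward prediction error back to the Stage-1 action, discounted
by lambda.  MB and MF values are blended with a mixture weight omega
(omega=1 pure MB, omega=0 pure MF) and fed through a softmax with inverse
temperature beta and an additive stay bonus nu for options repeating the
previous trial's action.

Agents that use sequences choose, at Stage 1, among six options: the two
single-step actions and the four precompiled sequences (L1-L2, L1-R2,
R1-L2, R1-R2).  A chosen sequence is executed *open-loop*: the Stage-2
action is emitted regardless of which Stage-2 state is actually reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, NamedTuple

import numpy as np

from .task import TaskSpec, WalkState, sample_transition, emit_reward

__all__ = [
    "AgentParams",
    "ModelSpec",
    "AgentConfig",
    "Agent",
    "TrialRecord",
    "MODELS",
    "MODEL_NAMES",
    "get_model",
    "choice_probs",
    "combine_q",
    "mb_values",
    "mf_update",
    "run_trial",
]

# Stage-1 option order used throughout: two singles, then the four
# sequences indexed by 2*a1 + a2.
OPTION_LABELS = ("L1", "R1", "L1-L2", "L1-R2", "R1-L2", "R1-R2")


@dataclass
class AgentParams:
    """One parameter point.

    alpha   learning rate in (0, 1), shared by all delta-rule updates
    beta1   Stage-1 inverse temperature (>= 0)
    beta2   Stage-2 inverse temperature (>= 0)
    nu      stay bonus, in log-odds units (any real)
    omega   MB/MF mixture weight in [0, 1]
    lam     eligibility-trace decay in [0, 1]
    """

    alpha: float
    beta1: float
    beta2: float
    nu: float
    omega: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta1", "beta2", "nu", "omega", "lam"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("inverse temperatures must be non-negative")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one candidate model.

    ``single_step_control`` is "MB" or "mixture"; ``sequence_control`` is
    "MB", "mixture", "MF", or "none" (the last only when
    ``uses_sequences`` is false).  "MF" sequence control is not one of the
    five named models but supports ablation simulations in which sequence
    values are purely cached.
    """

    name: str
    uses_sequences: bool
    single_step_control: str
    sequence_control: str
    update_sequences_from_components: bool = True

    def __post_init__(self) -> None:
        if self.single_step_control not in ("MB", "mixture"):
            raise ValueError(f"bad single_step_control {self.single_step_control!r}")
        if self.sequence_control not in ("MB", "mixture", "MF", "none"):
            raise ValueError(f"bad sequence_control {self.sequence_control!r}")
        if not self.uses_sequences and self.sequence_control != "none":
            raise ValueError("sequence_control must be 'none' when uses_sequences is false")
        if self.uses_sequences and self.sequence_control == "none":
            raise ValueError("a sequence-using model needs a sequence controller")

    @property
    def uses_omega(self) -> bool:
        return "mixture" in (self.single_step_control, self.sequence_control)

    @property
    def uses_lambda(self) -> bool:
        # The trace only exists for flat MF values; a sequence receives a
        # single chunked update, so lambda never applies to it.
        return self.single_step_control == "mixture"


def _table1() -> dict[str, ModelSpec]:
    rows = [
        ("No sequences", False, "mixture", "none"),
        ("Pure MB", True, "MB", "MB"),
        ("Mixture-actions/MB-sequences", True, "mixture", "MB"),
        ("MB-actions/Mixture-sequences", True, "MB", "mixture"),
        ("Mixture-actions/Mixture-sequences", True, "mixture", "mixture"),
    ]
    return {
        name: ModelSpec(name, uses_seq, single, seq)
        for name, uses_seq, single, seq in rows
    }


#: The five models entering the model comparison, keyed by name.
MODELS: dict[str, ModelSpec] = _table1()
MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_NAMES)}"
        ) from None


@dataclass(frozen=True)
class AgentConfig:
    """Structural switches that are held fixed across the study.

    stay_bonus_stage2: whether the stay bonus also applies to the Stage-2
        softmax (keyed on the previous trial's Stage-2 action label).
    q_init: initial flat MF values.
    r_init: initial learned reward-model values for graded channels.
    p_init: initial learned reward probabilities (binary representation).
    """

    stay_bonus_stage2: bool = True
    q_init: float = 0.0
    r_init: float = 0.0
    p_init: float = 0.5


DEFAULT_CONFIG = AgentConfig()


class TrialRecord(NamedTuple):
    trial: int
    s1_choice: int
    transition: str
    s2_state: int
    s2_choice: int
    reward: float
    option_latent: str  # "" for a deliberate (closed-loop) trial, else the sequence label


def _stable_softmax(logits: list[float]) -> list[float]:
    m = max(logits)
    exps = [math.exp(x - m) for x in logits]
    z = sum(exps)
    return [e / z for e in exps]


def choice_probs(
    q: Mapping[str, float],
    beta: float,
    nu: float,
    prev_first_action: str | None = None,
) -> dict[str, float]:
    """Softmax with stay bonus over an arbitrary option set.

    Every option whose first-stage component matches ``prev_first_action``
    (e.g. "L1" matches both the single action "L1" and the sequence
    "L1-R2") receives the additive bonus ``nu``.  Numerically stable for
    large ``beta * Q`` via max-subtraction.
    """
    if not q:
        raise ValueError("empty option set")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    keys = list(q)
    logits = []
    for k in keys:
        v = beta * q[k]
        if prev_first_action is not None and k.split("-")[0] == prev_first_action:
            v += nu
        logits.append(v)
    probs = _stable_softmax(logits)
    return dict(zip(keys, probs))


def combine_q(
    q_mb: Mapping[str, float], q_mf: Mapping[str, float], omega: float
) -> dict[str, float]:
    """Elementwise convex combination omega*Q_MB + (1-omega)*Q_MF."""
    if set(q_mb) != set(q_mf):
        raise ValueError("q_mb and q_mf must share an identical key set")
    return {k: omega * q_mb[k] + (1.0 - omega) * q_mf[k] for k in q_mb}


class Agent:
    """Mutable value stores plus the choice rules of one model.

    The same object drives both forward simulation (sampling choices) and
    likelihood evaluation of observed choices, so the two paths cannot
    drift apart.

    Internal encoding: Stage-1 actions 0=L1, 1=R1; Stage-2 actions 0=L2,
    1=R2; Stage-2 states 0=green, 1=yellow, 2=red; sequences indexed by
    ``2*a1 + a2``.
    """

    __slots__ = (
        "model", "params", "spec", "config",
        "q1", "q2", "q_seq", "r_chan", "p_seq",
        "prev_a1", "prev_a2",
    )

    def __init__(
        self,
        model: ModelSpec,
        params: AgentParams,
        spec: TaskSpec,
        config: AgentConfig = DEFAULT_CONFIG,
    ) -> None:
        if model.uses_sequences and spec.representation == "reward_based" and spec.graded:
            raise ValueError("reward_based representation requires the binary variant")
        self.model = model
        self.params = params
        self.spec = spec
        self.config = config
        # Flat MF values.
        self.q1 = [config.q_init, config.q_init]
        self.q2 = [[config.q_init, config.q_init] for _ in range(3)]
        # Cached MF sequence values (one chunked value per sequence).
        self.q_seq = [config.q_init] * 4
        # Learned reward model R'.  Path-based: one entry per terminal
        # channel.  Reward-based: entries 0..3 are P(reward | s2, a2) and
        # p_seq holds P(reward | sequence), learned open-loop.
        if spec.representation == "path_based":
            self.r_chan = [config.r_init] * spec.n_channels
            self.p_seq = None
        else:
            self.r_chan = [config.p_init] * 4
            self.p_seq = [config.p_init] * 4
        self.prev_a1: int | None = None
        self.prev_a2: int | None = None

    # -- model-based values ----------------------------------------------------

    def mb_stage2(self, s2: int) -> list[float]:
        """MB values of L2/R2 in state ``s2``: the learned terminal reward."""
        spec = self.spec
        return [self.r_chan[spec.channel_index(s2, 0)], self.r_chan[spec.channel_index(s2, 1)]]

    def mb_stage1_single(self, a1: int) -> float:
        """Bellman value of a single Stage-1 action: the transition-weighted
        expectation of the best Stage-2 value in each reachable state."""
        spec = self.spec
        p = spec.common_prob
        v_des = max(self.mb_stage2(spec.designated_state(a1)))
        v_rare = max(self.mb_stage2(spec.rare_state(a1)))
        return p * v_des + (1.0 - p) * v_rare

    def mb_sequence(self, a1: int, a2: int) -> float:
        """MB value of the open-loop sequence a1 -> a2.

        Path-based: expectation of the terminal channel reached by fixing
        ``a2`` across the sequence's Stage-2 outcome distribution.
        Reward-based: the learned reward probability of the sequence.
        """
        spec = self.spec
        if spec.representation == "reward_based":
            return self.p_seq[2 * a1 + a2]
        p = spec.common_prob
        v_des = self.r_chan[spec.channel_index(spec.designated_state(a1), a2)]
        v_rare = self.r_chan[spec.channel_index(spec.rare_state(a1), a2)]
        return p * v_des + (1.0 - p) * v_rare

    # -- choice ----------------------------------------------------------------

    def _mix(self, control: str, mb: float, mf: float) -> float:
        if control == "MB":
            return mb
        if control == "MF":
            return mf
        w = self.params.omega
        return w * mb + (1.0 - w) * mf

    def stage1_values(self) -> list[float]:
        """Combined values in option order (2 singles, then 4 sequences if used)."""
        model = self.model
        sctrl = model.single_step_control
        vals = [
            self._mix(sctrl, self.mb_stage1_single(0), self.q1[0]),
            self._mix(sctrl, self.mb_stage1_single(1), self.q1[1]),
        ]
        if model.uses_sequences:
            qctrl = model.sequence_control
            for seq in range(4):
                a1, a2 = seq >> 1, seq & 1
                vals.append(self._mix(qctrl, self.mb_sequence(a1, a2), self.q_seq[seq]))
        return vals

    def stage1_probs(self) -> list[float]:
        """Stage-1 softmax over the full option set, with the stay bonus
        applied to every option whose first action repeats last trial's."""
        p = self.params
        vals = self.stage1_values()
        logits = [p.beta1 * v for v in vals]
        if self.prev_a1 is not None and p.nu != 0.0:
            for i, label_first in enumerate((0, 1, 0, 0, 1, 1)[: len(vals)]):
                if label_first == self.prev_a1:
                    logits[i] += p.nu
        return _stable_softmax(logits)

    def stage2_probs(self, s2: int) -> list[float]:
        """Stage-2 softmax over L2/R2 for a deliberate (closed-loop) choice."""
        p = self.params
        mb = self.mb_stage2(s2)
        mf = self.q2[s2]
        sctrl = self.model.single_step_control
        vals = [self._mix(sctrl, mb[0], mf[0]), self._mix(sctrl, mb[1], mf[1])]
        logits = [p.beta2 * v for v in vals]
        if self.config.stay_bonus_stage2 and self.prev_a2 is not None and p.nu != 0.0:
            logits[self.prev_a2] += p.nu
        return _stable_softmax(logits)

    # -- learning --------------------------------------------------------------

    def update(
        self,
        a1: int,
        s2: int,
        a2: int,
        r: float,
        open_loop: bool,
        seq_weight: float | None = None,
    ) -> None:
        """Apply all post-trial learning updates.

        ``open_loop`` marks whether the Stage-2 action was executed as
        part of a chunked sequence.  Under the path-based representation
        the terminal state reveals the path taken, so learning is
        identical either way; under the reward-based representation an
        open-loop trial teaches only the sequence's reward probability
        (the agent never registers which Stage-2 state it passed
        through).

        ``seq_weight`` optionally scales the cached-sequence update; it is
        used by the likelihood when sequence use is latent and
        ``update_sequences_from_components`` is off.
        """
        p = self.params
        alpha = p.alpha
        model = self.model
        spec = self.spec
        update_seq_cache = open_loop or model.update_sequences_from_components
        if seq_weight is None:
            seq_weight = 1.0 if update_seq_cache else 0.0

        if spec.representation == "reward_based":
            if open_loop:
                seq = 2 * a1 + a2
                self.p_seq[seq] += alpha * (r - self.p_seq[seq])
            else:
                ch = 2 * s2 + a2
                self.r_chan[ch] += alpha * (r - self.r_chan[ch])
                if seq_weight > 0.0:
                    seq = 2 * a1 + a2
                    self.p_seq[seq] += seq_weight * alpha * (r - self.p_seq[seq])
                self._mf_flat_update(a1, s2, a2, r)
        else:
            # Path-based: the differentiated terminal state is observed on
            # every trial, so the reward model, the flat MF values and (per
            # the component-updating assumption) the sequence cache all learn.
            ch = spec.channel_index(s2, a2)
            self.r_chan[ch] += alpha * (r - self.r_chan[ch])
            self._mf_flat_update(a1, s2, a2, r)
            if seq_weight > 0.0:
                seq = 2 * a1 + a2
                self.q_seq[seq] += seq_weight * alpha * (r - self.q_seq[seq])

        self.prev_a1 = a1
        self.prev_a2 = a2

    def _mf_flat_update(self, a1: int, s2: int, a2: int, r: float) -> None:
        """Q-learning with a within-trial eligibility trace.

        Stage-1 first backs up the best Stage-2 value (no immediate
        reward), then the Stage-2 prediction error is passed back to the
        Stage-1 action discounted by lambda.
        """
        p = self.params
        alpha = p.alpha
        q2s = self.q2[s2]
        self.q1[a1] += alpha * (max(q2s) - self.q1[a1])
        delta2 = r - q2s[a2]
        q2s[a2] += alpha * delta2
        self.q1[a1] += alpha * p.lam * delta2


def mb_values(agent: Agent, stage: int, s2: int | None = None) -> dict[str, float]:
    """Pure model-based values as a labelled map.

    ``stage=1`` returns the Stage-1 option set (singles, plus sequences if
    the model uses them); ``stage=2`` requires ``s2`` and returns the two
    Stage-2 actions.
    """
    if stage == 2:
        if s2 is None:
            raise ValueError("stage 2 values need the Stage-2 state")
        v = agent.mb_stage2(s2)
        return {"L2": v[0], "R2": v[1]}
    out = {"L1": agent.mb_stage1_single(0), "R1": agent.mb_stage1_single(1)}
    if agent.model.uses_sequences:
        for seq in range(4):
            out[OPTION_LABELS[2 + seq]] = agent.mb_sequence(seq >> 1, seq & 1)
    return out


def mf_update(agent: Agent, record: tuple[int, int, int, float]) -> Agent:
    """Apply the flat MF update for one (a1, s2, a2, r) transition record."""
    agent._mf_flat_update(*record)
    return agent


def run_trial(
    agent: Agent,
    walk: WalkState,
    rng: np.random.Generator,
    trial: int = 1,
) -> TrialRecord:
    """Play one trial: choose, transition, (possibly open-loop) act, learn.

    The walk itself is *not* advanced here; the session loop steps it
    between trials.
    """
    spec = agent.spec
    probs1 = agent.stage1_probs()
    opt = _sample_index(probs1, rng)
    if opt < 2:
        a1 = opt
        s2, transition = sample_transition(spec, a1, rng)
        probs2 = agent.stage2_probs(s2)
        a2 = _sample_index(probs2, rng)
        open_loop = False
        latent = ""
    else:
        seq = opt - 2
        a1, a2 = seq >> 1, seq & 1
        s2, transition = sample_transition(spec, a1, rng)
        open_loop = True
        latent = OPTION_LABELS[opt]
    r = emit_reward(spec, walk, s2, a2, rng)
    agent.update(a1, s2, a2, r, open_loop)
    return TrialRecord(trial, a1, transition, s2, a2, r, latent)


def _sample_index(probs: list[float], rng: np.random.Generator) -> int:
    u = rng.random()
    acc = 0.0
    for i, p in enumerate(probs):
        acc += p
        if u < acc:
            return i
    return len(probs) - 1
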