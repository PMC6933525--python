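"""Two-step task variants and their stochastic dynamics.

Three variants of the two-step task are supported:

``original_binary``
    The classic task: binary (0/1) rewards whose per-pair reward
    *probabilities* drift via a reflecting Gaussian walk.
``graded_expt1``
    Graded point rewards on [-5, 5]; the point value of each Stage-2
    state-action pair drifts via a reflecting Gaussian walk (sd 1.75).
``redstate_expt2``
    Like ``graded_expt1``, but every rare transition (20%) leads to a
    shared red state whose two actions yield one common drifting outcome.

A :class:`TaskSpec` additionally records the *terminal-state
representation* an agent is assumed to use: ``reward_based`` (terminal
states defined by reward identity; only coherent for binary rewards) or
``path_based`` (one terminal state per Stage-2 state-action path).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "TaskSpec",
    "WalkState",
    "make_task",
    "init_walk",
    "advance_walk",
    "sample_transition",
    "emit_reward",
    "STAGE1_ACTIONS",
    "STAGE2_ACTIONS",
    "STAGE2_STATES",
    "VARIANTS",
    "REPRESENTATIONS",
]

VARIANTS = ("original_binary", "graded_expt1", "redstate_expt2")
REPRESENTATIONS = ("reward_based", "path_based")

STAGE1_ACTIONS = ("L1", "R1")
STAGE2_ACTIONS = ("L2", "R2")
# State indices: 0=green, 1=yellow, 2=red (red exists only in redstate_expt2).
STAGE2_STATES = ("green", "yellow", "red")

#: channel index of the shared red-state outcome
RED_CHANNEL = 4


@dataclass(frozen=True)
class TaskSpec:
    """Immutable definition of one task variant.

    All constants are overridable for sensitivity analyses; the defaults
    are the study conditions (80/20 transitions, 125 trials, graded-walk
    sd 1.75 on [-5, 5]).  ``prob_walk_*`` govern the drifting reward
    probabilities of the binary variant and follow the standard two-step
    convention (reflecting walk with sd 0.025 on [0.25, 0.75]).
    """

    variant: str
    representation: str = "path_based"
    common_prob: float = 0.8
    n_trials: int = 125
    walk_sigma: float = 1.75
    walk_bounds: tuple[float, float] = (-5.0, 5.0)
    prob_walk_sigma: float = 0.025
    prob_walk_bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.representation!r}; expected one of {REPRESENTATIONS}"
            )
        if self.representation == "reward_based" and self.variant != "original_binary":
            # With graded rewards a reward-based encoding would need one
            # terminal state per point value (11 states, 44 transition
            # probabilities) -- implausible by construction, so we reject it.
            raise ValueError(
                "reward_based terminal states are only coherent for the "
                "original_binary variant: a graded task would require one "
                "terminal state per point value (11 states / 44 transition "
                "probabilities), which is not a plausible representation"
            )
        if not 0.0 < self.common_prob < 1.0:
            raise ValueError("common_prob must lie in (0, 1)")

    # -- structural properties -------------------------------------------------

    @property
    def rare_prob(self) -> float:
        return 1.0 - self.common_prob

    @property
    def graded(self) -> bool:
        """Whether rewards are graded point values (vs. Bernoulli 0/1)."""
        return self.variant != "original_binary"

    @property
    def has_red_state(self) -> bool:
        return self.variant == "redstate_expt2"

    @property
    def n_stage2_states(self) -> int:
        return 3 if self.has_red_state else 2

    @property
    def stage2_states(self) -> tuple[str, ...]:
        return STAGE2_STATES[: self.n_stage2_states]

    @property
    def n_channels(self) -> int:
        """Number of drifting reward channels.

        Four per-pair channels (green/yellow x L2/R2) plus, in the
        red-state variant, one shared channel for the red outcome.
        """
        return 5 if self.has_red_state else 4

    @property
    def channel_labels(self) -> tuple[str, ...]:
        labels = tuple(
            f"{STAGE2_STATES[s]}-{a}" for s in range(2) for a in STAGE2_ACTIONS
        )
        return labels + ("red",) if self.has_red_state else labels

    def designated_state(self, a1: int) -> int:
        """Common-transition target of Stage-1 action ``a1`` (L1->green, R1->yellow)."""
        return a1

    def rare_state(self, a1: int) -> int:
        """Rare-transition target: the other canonical state, or red in expt 2."""
        return 2 if self.has_red_state else 1 - a1

    def channel_index(self, s2: int, a2: int) -> int:
        """Reward-channel index of the (Stage-2 state, action) pair.

        In the red state both actions map onto the single shared channel.
        """
        if s2 == 2:
            if not self.has_red_state:
                raise ValueError("red state does not exist in this variant")
            return RED_CHANNEL
        return 2 * s2 + a2

    # -- (de)serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        d = dict(d)
        for key in ("walk_bounds", "prob_walk_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def make_task(variant: str, representation: str | None = None, **overrides) -> TaskSpec:
    """Construct the :class:`TaskSpec` for a named variant.

    When ``representation`` is omitted, the variant's natural encoding is
    used: reward-based for the original binary task, path-based otherwise.
    """
    if representation is None:
        representation = "reward_based" if variant == "original_binary" else "path_based"
    return TaskSpec(variant=variant, representation=representation, **overrides)


@dataclass
class WalkState:
    """Current values of the drifting reward channels.

    For graded variants ``values[c]`` is the point value of channel ``c``;
    for the binary variant it is the pair's reward *probability*.
    """

    values: np.ndarray
    lo: float
    hi: float
    sigma: float

    def copy(self) -> "WalkState":
        return WalkState(self.values.copy(), self.lo, self.hi, self.sigma)


def init_walk(spec: TaskSpec, rng: np.random.Generator) -> WalkState:
    """Independent uniform starting values over the walk bounds."""
    if spec.graded:
        lo, hi = spec.walk_bounds
        sigma = spec.walk_sigma
    else:
        lo, hi = spec.prob_walk_bounds
        sigma = spec.prob_walk_sigma
    values = rng.uniform(lo, hi, size=spec.n_channels)
    return WalkState(values=values, lo=lo, hi=hi, sigma=sigma)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold ``x`` back into [lo, hi] by reflection at the bounds."""
    if lo >= hi:
        raise ValueError("empty interval")
    width = hi - lo
    # Reflection is periodic with period 2*width; one modulo then a fold.
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def advance_walk(walk: WalkState, spec: TaskSpec, rng: np.random.Generator) -> WalkState:
    """One step of the reflecting Gaussian random walk on every channel.

    Each channel receives an independent N(0, sigma) perturbation and is
    reflected at the bounds, so the output always lies within them.
    """
    steps = rng.normal(0.0, walk.sigma, size=walk.values.shape) if walk.sigma > 0 else 0.0
    new = walk.values + steps
    out = np.array([_reflect(v, walk.lo, walk.hi) for v in np.atleast_1d(new)])
    return WalkState(values=out, lo=walk.lo, hi=walk.hi, sigma=walk.sigma)


def sample_transition(
    spec: TaskSpec, a1: int, rng: np.random.Generator
) -> tuple[int, str]:
    """Draw the Stage-2 state reached by Stage-1 action ``a1``.

    Returns ``(s2, transition_type)`` where ``transition_type`` labels
    which branch fired ("common" or "rare").
    """
    if a1 not in (0, 1):
        raise ValueError(f"invalid Stage-1 action index {a1!r}")
    if rng.random() < spec.common_prob:
        return spec.designated_state(a1), "common"
    return spec.rare_state(a1), "rare"


def emit_reward(
    spec: TaskSpec, walk: WalkState, s2: int, a2: int, rng: np.random.Generator
) -> float:
    """Reward delivered for choosing ``a2`` in Stage-2 state ``s2``.

    Binary variant: Bernoulli draw with the pair's current probability.
    Graded variants: the channel's current point value (the red state
    pays the shared channel regardless of the action taken).
    """
    ch = spec.channel_index(s2, a2)
    v = float(walk.values[ch])
    if spec.graded:
        return v
    return 1.0 if rng.random() < v else 0.0
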