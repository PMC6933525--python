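# Methods

`seqhabit` implements a complete simulation-and-analysis pipeline for a
family of two-step sequential decision tasks used to dissociate two
accounts of habitual behavior: model-free reinforcement learning over
single actions, and model-based selection of precompiled action
sequences executed open-loop. This note documents the models, the task
environments, the statistical estimators, the numerical choices, and
the limitations a user should know before trusting a result.

## Task environments

All variants share the two-step skeleton: a Stage-1 choice between L1
and R1 gates a probabilistic transition (80% to the action's designated
color state, L1→green / R1→yellow) followed by a Stage-2 choice between
L2 and R2 that yields reward.

- **`original_binary`** — rewards are 0/1; each Stage-2 state–action
  pair carries a drifting reward *probability*. The drift is a
  reflecting Gaussian walk on [0.25, 0.75] with step sd 0.025. These
  two constants are not part of the study definition; they follow the
  long-standing convention for this task and are exposed in `TaskSpec`
  for sensitivity analyses.
- **`graded_expt1`** — rewards are graded point values on [−5, 5]; the
  point value of each pair drifts by a reflecting Gaussian walk with
  μ = 0, σ = 1.75. Values are kept continuous (no display rounding) and
  enter all analyses raw.
- **`redstate_expt2`** — as the graded task, but every rare transition
  (20%, identical for both Stage-1 actions) leads to one shared red
  state whose two actions pay a single common outcome channel. The red
  channel drifts by the same walk as the other four; a static red value
  would leave no within-red reward variance and hence no model-free
  signal to detect on red trials.

Walk channels are initialized by independent uniform draws over their
bounds, and one walk step is taken between trials. Reflection is total
(values can never leave the bounds), implemented by folding the
proposal into the reflective period, which is exact for arbitrarily
large steps.

A `TaskSpec` also fixes the assumed *terminal-state representation*:
`reward_based` (terminal states defined by reward identity) is only
accepted for the binary task — a graded task would need one terminal
state per point value, which is not a plausible encoding and is
rejected with an explanatory error — while `path_based` gives each
Stage-2 state–action path its own terminal state.

## Agents

Five named models cover the comparison space (flat hybrid; pure-MB
sequences; and the three mixtures over single-step actions and/or
sequences). All share the same building blocks:

- **Model-based values.** The transition model T′ is fixed at the true
  probabilities — participants in these tasks are told the transition
  structure explicitly, so nothing forces transition learning — and
  only the reward model R′ is learned, by a delta rule with the shared
  learning rate α. Stage-1 single-action values follow the Bellman
  recursion with a `max` over Stage-2 actions, exactly as the standard
  formulation prints it (not a softmax expectation). A sequence's
  model-based value is the expectation of its open-loop outcome
  distribution: the fixed Stage-2 action evaluated across the Stage-1
  action's transition probabilities (path-based), or a directly learned
  reward probability per sequence (reward-based).
- **Model-free values.** Q-learning with a within-trial eligibility
  trace: Stage 1 first backs up the best Stage-2 value, then receives
  the Stage-2 reward prediction error discounted by λ. Cached sequence
  values are updated toward the trial's terminal reward with the same
  α in a single chunked update — a sequence is one temporally extended
  action, so it gets one prediction error and λ does not apply to it.
- **Choice.** Values are blended as ωQ_MB + (1−ω)Q_MF per controller
  setting and passed through a softmax (β1 at Stage 1 over 2 or 6
  options, β2 at Stage 2) with an additive stay bonus ν. The bonus
  applies to every Stage-1 option whose *first* action repeats the
  previous trial's first action — the minimal reading of the stay
  indicator over a mixed option set — and, by default, to the Stage-2
  action matching the previous trial's Stage-2 action
  (`AgentConfig.stay_bonus_stage2`, configurable, since the printed
  choice rule is stated once generically).
- **Open-loop execution.** A chosen sequence emits its Stage-2 action
  regardless of the realized state. Under the path-based representation
  the differentiated terminal state is observed at the end of every
  trial, so all learning systems update identically on open- and
  closed-loop trials. Under the reward-based representation an
  open-loop trial teaches only the sequence's reward probability — the
  agent never registers which color state it passed through — which is
  precisely the property that lets a purely model-based sequence agent
  mimic model-free behavior on the binary task.
- **Component updating.** By default, choosing single actions that
  happen to spell out a sequence also updates that sequence's cached
  value (`update_sequences_from_components=True`); the alternative is
  retained behind the flag.

Initial values: Q_MF and R′ start at 0 (graded) and probability
channels at 0.5; all exposed in `AgentConfig`.

Population priors for simulation and for MAP fitting are
α ~ Beta(1.1, 1.1), β1, β2 ~ Gamma(shape 1.2, scale 5) independently,
ν ~ Normal(0, 1), and ω, λ ~ Uniform(0, 1) where the model uses them
(ω ≡ 1 for purely model-based controllers). The Gamma is
shape–scale (mean 6): under the shape–rate reading (mean 0.24) choices
are nearly value-blind and none of the task's signature effects is
detectable at cohort scale, so that reading is excluded empirically.

Cohorts default to 1,000 agents × 125 trials. Each agent receives its
own `SeedSequence` child of the cohort seed, so results are independent
of iteration order or parallelism. No practice trials are simulated.

## Signature analyses

All analyses are one-trial-back regressions on the long-format trial
table. Coding conventions (coefficients depend on them, and the source
analyses do not state theirs): continuous reward is mean-centered over
the analyzed rows; binary predictors are ±0.5 (transition: common
= +0.5; repeats: repeat = +0.5). Reward is never binned for inference;
the sign-binning helper (zero → negative, a fixed documented tie rule)
exists for display only.

- `stay1_signature`: Stage-1 repeat ~ previous reward × previous
  transition. Reward main effect = model-free signature; interaction =
  model-based signature.
- `expt2_stay1_after_rare`: Stage-1 repeat ~ previous reward on trials
  following a red-state transition, where model-based control is blind
  to the shared outcome.
- `filter_sequence_trials` + `stage2_choice_signature`: Stage-2 repeat
  ~ Stage-1 repeat × previous reward on trials whose Stage-2 state
  differs from the previous trial's (optionally conditioned on, or
  interacting with, the previous transition type). The restriction
  removes attention-style confounds: a closed-loop agent carries no
  relevant value information into a different Stage-2 state, whereas an
  open-loop agent is insensitive to the state by construction.
- `stage2_rt_signature`: the reaction-time analogue. The factorial
  parameterization is the default, with the Stage-2 repeat coded as a
  *speed gain* (repeat = −0.5) so that the signature coefficient is
  positive when repeating Stage 2 is fastest after a reward with a
  repeated Stage-1 choice. A difference-score parameterization
  (per-subject repeat-vs-switch RT gains per cell, interaction contrast
  t-tested across subjects) is available for comparison.
- `graded_vs_binned`: AIC comparison of predicting Stage-1 repeats from
  the continuous previous reward versus its sign, restricted to trials
  following common transitions. Pooled logistic models with a single
  intercept are used on an identical row set, so the AIC difference
  isolates the reward coding; with only two reward levels the codings
  are collinear and the result is flagged.

### Estimators

The reference analyses for these tasks are random-slopes logistic
GLMMs. The package does not reimplement a full GLMM; it provides two
estimators whose domains of validity are complementary, plus an
approximate mixed backend:

- **`two_stage`** (default for the Stage-1 analyses): one GLM per
  subject, then an equal-weight one-sample t-test of the coefficient
  vectors across subjects. Its estimand is the population mean of
  subject-level effects — the quantity the GLMM's fixed effect targets.
  Equal weighting matters: precision weights are strongly correlated
  with subject effect sizes here (both scale with the softmax inverse
  temperature), and precision-weighted variants measurably shift the
  estimand toward high-β subjects. Subjects whose fits separate or
  whose regressors are degenerate are dropped and counted in
  `flags`; with fewer than two usable subjects the result carries the
  raw coefficient direction and no inferential statistics.
- **`pooled`** (default for the Stage-2 sequence signatures): one GLM
  over all rows with cluster-robust (by subject) standard errors, a
  GEE-style population-averaged estimator. The sequence-trial
  restriction leaves roughly 15–25 rows per subject, too few for stable
  per-subject maximum likelihood; pooling restores the power that the
  GLMM obtains from partial pooling.
- **`mixed`**: a random-intercept mixed model (variational Bayes for
  logistic outcomes) for sensitivity checks. It is not a random-slopes
  GLMM and is not used by default.

Every analysis accepts any backend. Reproducing the *human-data*
coefficients of the original analyses to the printed digit would
require the full random-slopes GLMM with the original (unstated)
contrast coding; the package reproduces the qualitative and
sign/significance structure of the simulation results.

A known sensitivity, documented rather than hidden: for purely
model-based sequence cohorts on the graded task, precision-weighted
estimators (including a GLMM) detect a small positive reward main
effect (≈ +0.05 log-odds per point) concentrated on trials following
open-loop execution, where max-based single-action planning transmits
common-transition rewards into staying slightly more strongly than
rare-transition rewards into switching. The subject-mean estimand is
null, as the default backend reports. The dissociation claim (hybrid
cohorts show a reward main effect an order of magnitude larger under
both representations; pure-MB sequence cohorts show none under the
subject-mean estimand on the graded task) is robust across backends.

## Trial-level fitting and model comparison

Likelihoods replay the agent's learning rules trial by trial. Sequence
use is unobservable, so sequence models marginalize the latent
chunking per trial: P(a1, a2 | s2) = P(sequence a1→a2) + P(single a1) ·
P(a2 | s2). Under the default component-updating assumption, learning
does not depend on the latent flag and the marginalization is exact;
with component updating off, the cached sequence value is updated in
proportion to the posterior probability of sequence use (an approximate
filter, flagged in the docstring). Likelihood evaluation for sequence
models requires the path-based representation — under the reward-based
one, learning differs between the latent branches and the likelihood
would not be well defined without a latent-state filter over histories.

MAP estimation maximizes log-likelihood plus log prior in an
unconstrained space (logit for α, ω, λ; log for β1, β2; identity for
ν), with the priors transformed by the change of variables. This
removes the boundary pathologies that a constrained optimizer induces
in the Hessian used by the Laplace approximation; the original fits
used a constrained optimizer, so parameter point estimates can differ
at the reparameterization level even when fits are equivalent.
Optimization is L-BFGS-B from `n_restarts` prior-drawn start points
(10 by default; the validation suites use 2–5), deterministic given
the seed. The Hessian of the negative log posterior is computed by
central finite differences (step 1e−4 in transformed units).

The Laplace log evidence is log p(D|θ̂) + log p(θ̂) + (d/2) ln 2π −
½ ln det H, with the Jacobian included in the prior term. A
non-positive-definite Hessian is ridge-regularized (shift by the most
negative eigenvalue plus 1e−6) and the fit is flagged.

Group-level comparison uses the random-effects hierarchy over model
frequencies: variational updates to a Dirichlet posterior over
frequencies, exceedance probabilities by Monte-Carlo Dirichlet sampling
(10⁶ draws by default, seeded), the Bayes omnibus risk from the
variational free-energy comparison against the equal-frequency null,
and PXP = EP·(1−BOR) + BOR/K. Because the variational free energy is a
bound, the BOR (and hence PXP in weak-evidence regimes) can deviate
from an exact Monte-Carlo evaluation of the same hierarchy by a few
hundredths; the test suite pins this agreement at 0.06 absolute. The
BIC-based Bayes factor helper counts *trials* as n (not button
presses), a choice the source analyses leave unstated.

`model_recovery` closes the loop: cohorts simulated from each
generating model, all candidates fitted per subject, PXP per cohort,
confusion table out.

## Synthetic datasets and reaction times

The agent models produce no latencies, so `seqhabit.synthetic` attaches
them: rt2 = base2 − seq_speedup·1(open loop) + switch_cost·1(Stage-2
switch) + Gaussian noise, truncated at a positive floor; rt1 is
baseline plus noise. Defaults (base2 = 700 ms, speedup = 80 ms, switch
cost = 50 ms, noise sd = 200 ms) produce interaction t-statistics of
the same order as human data at comparable cohort sizes, but the model
is deliberately minimal: it makes the RT signature analyses testable
end to end and nothing more. Generated datasets carry the latent
open-loop column; the observed export drops it, since real data never
contain it.

What passing tests on generated data do and do not show: they show the
pipeline detects the signatures its generators inject at realistic
sizes, with correct nulls under ablation; they do not show that human
RT distributions, lapses, response deadlines, or practice effects are
captured — none of those are modeled.

## Problem sizes used in validation

The behavioral signature suites run at the study's own scale (1,000
agents × 125 trials per cell). The fitting suites are scaled-down
analogues chosen to keep a full validation run on one CPU comfortably
inside a coffee break: parameter recovery uses 50 subjects × 250 trials
with 2 optimizer restarts; model recovery uses five cohorts of 20
subjects × 250 trials. At these sizes mixture-weight recovery
correlates at r ≈ 0.84 and model recovery is 5/5 exact.

## Known limitations

- No arbitration/meta-control model: ω is a free mixture weight, not a
  resource-rational controller.
- The mixed-model backend is random-intercept only; none of the
  backends is a random-slopes GLMM.
- The reward-based representation's fitting path is intentionally
  unsupported for sequence models (see above).
- No MCMC posterior sampling and no hierarchical group-level priors on
  agent parameters; the only hierarchy is over model frequencies.
- Reaction-time generation is additive and stationary; quantitative RT
  matching is out of scope.
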