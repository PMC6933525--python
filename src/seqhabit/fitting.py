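"""Trial-level likelihoods, MAP fitting, and Bayesian model selection.

For each candidate model the likelihood of a subject's choices is
evaluated sequentially, replaying the agent's learning rules trial by
trial.  Because sequence use is unobservable in choice data, sequence
models marginalize the latent chunking on every trial:

    P(a1, a2 | s2) = P(choose sequence a1->a2) + P(choose single a1) * P(a2 | s2)

Subject-level parameters are estimated by maximum a posteriori (MAP)
optimization under the same priors used for simulation, with random
restarts.  Optimization runs in an unconstrained transformed space
(logit for alpha/omega/lambda, log for the inverse temperatures,
identity for the stay bonus); the priors carry the change-of-variables
Jacobian, which removes boundary pathologies from the Hessian used by
the Laplace approximation.

Group-level comparison uses the random-effects hierarchy over model
frequencies: a variational Dirichlet-multinomial fit yields exceedance
probabilities, the Bayes omnibus risk (BOR) compares the random-effects
model against the equal-frequency null, and protected exceedance
probabilities follow as PXP = EP * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .agents import Agent, AgentConfig, AgentParams, DEFAULT_CONFIG, ModelSpec
from .task import TaskSpec

__all__ = [
    "SessionArrays",
    "session_arrays",
    "trial_loglik",
    "log_prior_transformed",
    "free_param_names",
    "fit_map",
    "SubjectFit",
    "laplace_evidence",
    "laplace_log_evidence",
    "hessian_fd",
    "evidence_matrix",
    "bms_pxp",
    "BMSResult",
    "bic_bayes_factor",
    "model_recovery",
]

PARAM_ORDER = ("alpha", "beta1", "beta2", "nu", "omega", "lam")

# natural <- transformed maps
_SIGMOID = {"alpha", "omega", "lam"}
_EXP = {"beta1", "beta2"}

_LN_2PI = math.log(2.0 * math.pi)
# normalizing constants of the priors
_LOG_BETA_CONST = math.lgamma(2.2) - 2.0 * math.lgamma(1.1)  # Beta(1.1, 1.1)
_GAMMA_SHAPE, _GAMMA_SCALE = 1.2, 5.0
_LOG_GAMMA_CONST = -math.lgamma(_GAMMA_SHAPE) - _GAMMA_SHAPE * math.log(_GAMMA_SCALE)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _log_sigmoid(x: float) -> float:
    """log(sigmoid(x)), stable for any x."""
    if x >= 0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


def to_natural(x: np.ndarray, names: tuple[str, ...]) -> dict[str, float]:
    """Map a transformed-space vector onto natural parameter values."""
    out = {}
    for v, name in zip(x, names):
        if name in _SIGMOID:
            out[name] = _sigmoid(float(v))
        elif name in _EXP:
            out[name] = math.exp(float(v))
        else:
            out[name] = float(v)
    return out


def to_transformed(values: dict[str, float], names: tuple[str, ...]) -> np.ndarray:
    out = np.empty(len(names))
    for i, name in enumerate(names):
        v = values[name]
        if name in _SIGMOID:
            v = min(max(v, 1e-12), 1 - 1e-12)
            out[i] = math.log(v / (1.0 - v))
        elif name in _EXP:
            out[i] = math.log(max(v, 1e-12))
        else:
            out[i] = v
    return out


def log_prior_transformed(x: np.ndarray, names: tuple[str, ...]) -> float:
    """Log prior density in the unconstrained space (Jacobian included).

    Priors on the natural scale: alpha ~ Beta(1.1, 1.1); beta1, beta2 ~
    Gamma(1.2, scale 5); nu ~ Normal(0, 1); omega, lambda ~ Uniform(0, 1).
    """
    lp = 0.0
    for v, name in zip(x, names):
        v = float(v)
        if name == "alpha":
            # Beta(1.1, 1.1) logpdf plus logit Jacobian log(a(1-a)):
            # exponents combine to 1.1 on each log-sigmoid term
            lp += 1.1 * _log_sigmoid(v) + 1.1 * _log_sigmoid(-v) + _LOG_BETA_CONST
        elif name in _EXP:
            b = math.exp(v)
            lp += (_GAMMA_SHAPE - 1.0) * v - b / _GAMMA_SCALE + _LOG_GAMMA_CONST
            lp += v  # Jacobian of exp
        elif name == "nu":
            lp += -0.5 * v * v - 0.5 * _LN_2PI
        else:  # omega, lam: Uniform(0,1) through a logit
            lp += _log_sigmoid(v) + _log_sigmoid(-v)
    return lp


def free_param_names(model: ModelSpec, fixed: dict | None = None) -> tuple[str, ...]:
    """The free parameters of a model, in canonical order."""
    fixed = fixed or {}
    names = ["alpha", "beta1", "beta2", "nu"]
    if model.uses_omega:
        names.append("omega")
    if model.uses_lambda:
        names.append("lam")
    return tuple(n for n in names if n not in fixed)


def _build_params(model: ModelSpec, values: dict[str, float], fixed: dict | None) -> AgentParams:
    merged = {"omega": 1.0 if not model.uses_omega else 0.5, "lam": 0.0}
    merged.update(fixed or {})
    merged.update(values)
    return AgentParams(**{k: merged.get(k, 0.0) for k in PARAM_ORDER})


# ---------------------------------------------------------------------------
# likelihood


@dataclass(frozen=True)
class SessionArrays:
    """One subject's trials in the fast internal encoding."""

    a1: tuple[int, ...]
    s2: tuple[int, ...]
    a2: tuple[int, ...]
    r: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.a1)


_S1_IDX = {"L1": 0, "R1": 1}
_S2_IDX = {"L2": 0, "R2": 1}
_STATE_IDX = {"green": 0, "yellow": 1, "red": 2}


def session_arrays(trials: pd.DataFrame) -> SessionArrays:
    """Convert one subject's trial table (sorted by trial) to arrays."""
    df = trials.sort_values("trial")
    return SessionArrays(
        a1=tuple(_S1_IDX[v] for v in df["s1_choice"]),
        s2=tuple(_STATE_IDX[v] for v in df["s2_state"]),
        a2=tuple(_S2_IDX[v] for v in df["s2_choice"]),
        r=tuple(float(v) for v in df["reward"]),
    )


def trial_loglik(
    model: ModelSpec,
    params: AgentParams,
    trials: SessionArrays | pd.DataFrame,
    spec: TaskSpec,
    config: AgentConfig = DEFAULT_CONFIG,
) -> float:
    """Log-likelihood of one subject's choice sequence under a model.

    Sequence models marginalize the latent open-loop flag per trial.
    Learning updates replay exactly the rules in :mod:`seqhabit.agents`;
    under the (default) component-updating assumption they do not depend
    on the latent flag, so the marginalization is exact.  With component
    updating disabled, the cached sequence value is updated in proportion
    to the posterior probability that a sequence was used (an
    approximate filter).
    """
    if isinstance(trials, pd.DataFrame):
        trials = session_arrays(trials)
    if model.uses_sequences and spec.representation == "reward_based":
        raise ValueError(
            "likelihoods for sequence models are defined for the path_based "
            "representation, where learning does not depend on the latent "
            "open-loop flag"
        )
    agent = Agent(model, params, spec, config)
    uses_seq = model.uses_sequences
    components = model.update_sequences_from_components
    log = math.log
    ll = 0.0
    for i in range(len(trials)):
        a1, s2, a2, r = trials.a1[i], trials.s2[i], trials.a2[i], trials.r[i]
        p1 = agent.stage1_probs()
        p2 = agent.stage2_probs(s2)[a2]
        if uses_seq:
            p_seq = p1[2 + 2 * a1 + a2]
            p = p_seq + p1[a1] * p2
            w = None if components else (p_seq / p if p > 0 else 0.0)
        else:
            p = p1[a1] * p2
            w = None
        if not (p > 0.0) or not math.isfinite(p):
            raise FloatingPointError(f"non-finite choice probability at trial {i + 1}")
        ll += log(p)
        agent.update(a1, s2, a2, r, open_loop=False, seq_weight=w)
    return ll


# ---------------------------------------------------------------------------
# MAP estimation


@dataclass
class SubjectFit:
    """MAP fit of one model to one subject."""

    model: ModelSpec
    spec: TaskSpec
    free_names: tuple[str, ...]
    fixed: dict
    x_map: np.ndarray
    params: AgentParams
    log_posterior: float
    log_likelihood: float
    hessian: np.ndarray
    n_trials: int
    converged: bool
    n_restarts_used: int
    notes: list = field(default_factory=list)


def _sample_start(names: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    natural = {
        "alpha": float(rng.beta(1.1, 1.1)),
        "beta1": float(rng.gamma(1.2, 5.0)) + 1e-3,
        "beta2": float(rng.gamma(1.2, 5.0)) + 1e-3,
        "nu": float(rng.normal(0.0, 1.0)),
        "omega": float(rng.uniform(0.02, 0.98)),
        "lam": float(rng.uniform(0.02, 0.98)),
    }
    return to_transformed({k: natural[k] for k in names}, names)


def fit_map(
    model: ModelSpec,
    trials: SessionArrays | pd.DataFrame,
    spec: TaskSpec,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    fixed: dict | None = None,
    config: AgentConfig = DEFAULT_CONFIG,
    min_trials: int = 20,
) -> SubjectFit:
    """Maximize log-likelihood + log prior over the model's free parameters.

    Runs ``n_restarts`` L-BFGS-B starts from prior draws in the
    transformed space and keeps the best optimum; deterministic given the
    rng/seed.  The returned fit carries the Hessian of the negative log
    posterior at the MAP (central finite differences, step 1e-4), ready
    for :func:`laplace_evidence`.
    """
    if isinstance(trials, pd.DataFrame):
        trials = session_arrays(trials)
    if len(trials) < min_trials:
        raise ValueError(f"need at least {min_trials} trials to fit, got {len(trials)}")
    rng = np.random.default_rng(rng)
    names = free_param_names(model, fixed)
    if not names:
        raise ValueError("model has no free parameters after fixing")

    def neg_log_post(x: np.ndarray) -> float:
        values = to_natural(x, names)
        try:
            params = _build_params(model, values, fixed)
            ll = trial_loglik(model, params, trials, spec, config)
        except (FloatingPointError, OverflowError, ValueError):
            return 1e10
        lp = log_prior_transformed(x, names)
        total = ll + lp
        return -total if math.isfinite(total) else 1e10

    best = None
    any_success = False
    for _ in range(n_restarts):
        x0 = _sample_start(names, rng)
        res = optimize.minimize(
            neg_log_post, x0, method="L-BFGS-B",
            options={"maxiter": 300, "ftol": 1e-9},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x_map = np.asarray(best.x, dtype=float)
    values = to_natural(x_map, names)
    params = _build_params(model, values, fixed)
    ll = trial_loglik(model, params, trials, spec, config)
    lp = log_prior_transformed(x_map, names)
    hess = hessian_fd(neg_log_post, x_map, h=1e-4)
    return SubjectFit(
        model=model, spec=spec, free_names=names, fixed=dict(fixed or {}),
        x_map=x_map, params=params, log_posterior=ll + lp, log_likelihood=ll,
        hessian=hess, n_trials=len(trials), converged=any_success,
        n_restarts_used=n_restarts,
    )


def hessian_fd(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Symmetric Hessian of ``f`` at ``x`` by central finite differences."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def laplace_log_evidence(log_posterior_at_map: float, hessian: np.ndarray) -> tuple[float, bool]:
    """Gaussian (Laplace) approximation of the log marginal likelihood.

    ``hessian`` is the curvature of the *negative* log posterior at the
    MAP.  Returns ``(log_evidence, regularized)``; a non-positive-definite
    Hessian is ridge-regularized, with the flag set.
    """
    H = np.asarray(hessian, dtype=float)
    d = H.shape[0]
    regularized = False
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 0:
        H = H + (abs(eigvals.min()) + 1e-6) * np.eye(d)
        regularized = True
    sign, logdet = np.linalg.slogdet(H)
    return log_posterior_at_map + 0.5 * d * _LN_2PI - 0.5 * logdet, regularized


def laplace_evidence(fit: SubjectFit) -> float:
    """Log marginal likelihood of one subject fit via the Laplace approximation."""
    value, regularized = laplace_log_evidence(fit.log_posterior, fit.hessian)
    if regularized and "hessian_regularized" not in fit.notes:
        fit.notes.append("hessian_regularized")
    return value


def evidence_matrix(
    models: list[ModelSpec],
    table: pd.DataFrame,
    spec: TaskSpec,
    n_restarts: int = 10,
    seed: int | None = 0,
    config: AgentConfig = DEFAULT_CONFIG,
    return_fits: bool = False,
):
    """Per-subject log marginal likelihoods for every candidate model.

    Returns a subjects x models DataFrame (exportable with ``to_csv``);
    with ``return_fits`` also a ``{(subject, model name): SubjectFit}`` map.
    """
    subjects = pd.unique(table["subject"])
    streams = np.random.SeedSequence(seed).spawn(len(subjects) * len(models))
    out = pd.DataFrame(index=subjects, columns=[m.name for m in models], dtype=float)
    fits = {}
    k = 0
    for s in subjects:
        arrays = session_arrays(table[table["subject"] == s])
        for m in models:
            fit = fit_map(
                m, arrays, spec, n_restarts=n_restarts,
                rng=np.random.default_rng(streams[k]), config=config,
            )
            out.loc[s, m.name] = laplace_evidence(fit)
            if return_fits:
                fits[(s, m.name)] = fit
            k += 1
    return (out, fits) if return_fits else out


# ---------------------------------------------------------------------------
# group-level model selection


@dataclass
class BMSResult:
    """Random-effects Bayesian model selection summary."""

    model_names: tuple[str, ...]
    alpha: np.ndarray  # Dirichlet posterior counts
    expected_freq: np.ndarray
    exceedance: np.ndarray
    bor: float
    pxp: np.ndarray
    attributions: np.ndarray  # subjects x models posterior model assignments

    def best(self) -> str:
        return self.model_names[int(np.argmax(self.pxp))]

    def as_series(self, which: str = "pxp") -> pd.Series:
        return pd.Series(getattr(self, which), index=list(self.model_names))


def _dirichlet_kl(a: np.ndarray, a0: np.ndarray) -> float:
    asum, a0sum = a.sum(), a0.sum()
    return float(
        special.gammaln(asum) - special.gammaln(a0sum)
        - np.sum(special.gammaln(a) - special.gammaln(a0))
        + np.sum((a - a0) * (special.digamma(a) - special.digamma(asum)))
    )


def bms_pxp(
    evidence,
    rng: np.random.Generator | int | None = None,
    n_samples: int = 1_000_000,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> BMSResult:
    """Protected exceedance probabilities from a log-evidence matrix.

    Fits the hierarchical Dirichlet-multinomial model of population model
    frequencies by variational updates, estimates exceedance
    probabilities by Monte-Carlo sampling of the Dirichlet posterior,
    computes the Bayes omnibus risk (BOR) from the free-energy comparison
    with the equal-frequency null, and protects the exceedance
    probabilities as PXP = EP * (1 - BOR) + BOR / K.
    """
    if isinstance(evidence, pd.DataFrame):
        names = tuple(str(c) for c in evidence.columns)
        lme = evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(evidence, dtype=float)
        names = tuple(f"model_{k}" for k in range(lme.shape[1]))
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("evidence must be a subjects x models matrix with at least 2 of each")
    if not np.all(np.isfinite(lme)):
        raise ValueError("evidence matrix contains non-finite entries")
    rng = np.random.default_rng(rng)
    n, K = lme.shape
    a0 = np.ones(K)
    a = a0.copy()
    u = np.full((n, K), 1.0 / K)
    for _ in range(max_iter):
        logu = lme + (special.digamma(a) - special.digamma(a.sum()))
        logu -= logu.max(axis=1, keepdims=True)
        u = np.exp(logu)
        u /= u.sum(axis=1, keepdims=True)
        a_new = a0 + u.sum(axis=0)
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            break
        a = a_new
    # exceedance probabilities by Dirichlet Monte Carlo
    draws = rng.dirichlet(a, size=n_samples)
    winners = np.argmax(draws, axis=1)
    ep = np.bincount(winners, minlength=K) / n_samples
    # free energy of the random-effects model vs the equal-frequency null
    dig = special.digamma(a) - special.digamma(a.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(u > 0, u * np.log(u), 0.0))
    f1 = float(np.sum(u * lme) + np.sum(u * dig) + ent - _dirichlet_kl(a, a0))
    f0 = float(np.sum(special.logsumexp(lme, axis=1) - math.log(K)))
    bor = 1.0 / (1.0 + math.exp(min(max(f1 - f0, -700), 700)))
    pxp = ep * (1.0 - bor) + bor / K
    return BMSResult(
        model_names=names, alpha=a, expected_freq=a / a.sum(),
        exceedance=ep, bor=bor, pxp=pxp, attributions=u,
    )


def bic_bayes_factor(ll_null: float, k_null: int, ll_alt: float, k_alt: int, n_obs: int) -> float:
    """Bayes factor in favor of the null via the BIC approximation.

    BIC_m = k_m * ln(n_obs) - 2 * ll_m;  BF_null = exp((BIC_alt - BIC_null) / 2).
    """
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    bic_null = k_null * math.log(n_obs) - 2.0 * ll_null
    bic_alt = k_alt * math.log(n_obs) - 2.0 * ll_alt
    return math.exp((bic_alt - bic_null) / 2.0)


def model_recovery(
    models: list[ModelSpec],
    spec: TaskSpec,
    n_subjects: int = 20,
    n_trials: int = 250,
    seed: int = 0,
    n_restarts: int = 2,
    generating_models: list[ModelSpec] | None = None,
    config: AgentConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Generate-and-refit confusion summary.

    Simulates one cohort from each generating model (parameters drawn
    from the population priors), fits every candidate model to every
    simulated subject, and runs the group-level selection per cohort.
    Returns a DataFrame of PXPs indexed by generating model.
    """
    from .simulate import CohortConfig, simulate_cohort

    generating = generating_models if generating_models is not None else models
    root = np.random.SeedSequence(seed)
    rows = []
    for i, gen in enumerate(generating):
        sim_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31)) + i
        cohort = simulate_cohort(
            CohortConfig(model=gen, task=spec, n_agents=n_subjects,
                         n_trials=n_trials, seed=sim_seed, agent_config=config)
        )
        ev = evidence_matrix(models, cohort, spec, n_restarts=n_restarts,
                             seed=sim_seed + 1, config=config)
        bms = bms_pxp(ev, rng=sim_seed + 2, n_samples=200_000)
        rows.append(pd.Series(bms.pxp, index=list(bms.model_names), name=gen.name))
    return pd.DataFrame(rows)
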