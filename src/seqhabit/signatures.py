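"""One-trial-back behavioral signature analyses.

The analyses regress trial-t behavior on trial t-1 events:

* ``stay1_signature`` -- repeat of the Stage-1 choice on previous reward
  x previous transition type.  A main effect of previous reward is the
  classic signature of model-free control; the reward x transition
  interaction is the signature of model-based control.
* ``expt2_stay1_after_rare`` -- in the red-state task, Stage-1 repeats
  regressed on previous reward among trials following a rare (red)
  transition; model-based controllers integrate the shared red outcome
  out, so only model-free control predicts a positive effect.
* ``stage2_choice_signature`` / ``stage2_rt_signature`` -- the
  action-sequence signatures: after a reward, repeats of the Stage-1 and
  Stage-2 actions become *more correlated* (and jointly faster), because
  the agent is re-running a chunked sequence.  To rule out attention-like
  confounds, the analysis is restricted to trials whose Stage-2 state
  differs from the previous trial's (``filter_sequence_trials``).
* ``graded_vs_binned`` -- AIC comparison of predicting Stage-1 repeats
  from the continuous previous reward vs. its sign, a check that
  subjects treat the rewards as graded.

Statistical backends
--------------------
Three backends are available for every analysis:

``two_stage``
    Summary-statistics estimator: a logistic (or linear) GLM per
    subject, then an equal-weight one-sample t-test of the coefficients
    across subjects.  Its estimand is the population mean of the
    subject-level effects -- the quantity a random-slopes GLMM targets.
    Default for the Stage-1 stay analyses, where every subject
    contributes ~n_trials rows and the per-subject fits are
    well-conditioned.
``pooled``
    One GLM over all rows with cluster-robust (by subject) standard
    errors -- a GEE-style population-averaged estimator.  Default for
    the Stage-2 sequence signatures, whose trial restriction leaves too
    few rows per subject for stable per-subject maximum likelihood.
``mixed``
    Random-intercept mixed model (variational Bayes for logistic
    outcomes); an approximation offered for sensitivity checks.

Exactly reproducing the human-data coefficients of the original
analyses requires a full random-slopes GLMM, which none of these are.

Coding conventions (coefficients depend on them): the continuous reward
is mean-centered over the analyzed rows; binary predictors are coded
+/-0.5 (transition: common = +0.5, rare = -0.5; repeats: repeat = +0.5).
In the reaction-time model the Stage-2 repeat is coded as a *speed gain*
(repeat = -0.5), so positive coefficients mean repeating is faster.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DegenerateDataError",
    "RegressionResult",
    "derive_lagged",
    "filter_sequence_trials",
    "bin_reward",
    "stay1_signature",
    "expt2_stay1_after_rare",
    "stage2_choice_signature",
    "stage2_rt_signature",
    "graded_vs_binned",
    "GradedVsBinned",
]

#: per-subject standard errors above this are treated as separation artifacts
SE_CAP = 50.0


class DegenerateDataError(ValueError):
    """A regressor or outcome carries no usable variance."""


@dataclass
class RegressionResult:
    """Fixed-effect estimates of one signature analysis.

    ``table`` is indexed by term name with columns ``b`` (log-odds or the
    outcome's units), ``se``, ``z`` and ``p`` (two-sided Wald).
    """

    table: pd.DataFrame
    n_obs: int
    n_subjects: int
    n_used: int
    backend: str
    outcome: str
    aic: float | None = None
    flags: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "b"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def z(self, term: str) -> float:
        return float(self.table.loc[term, "z"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        half = stats.norm.ppf(0.5 + level / 2) * self.se(term)
        return self.coef(term) - half, self.coef(term) + half

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "backend": self.backend,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_used": self.n_used,
            "aic": self.aic,
            "flags": self.flags,
            "terms": {
                t: {c: (None if pd.isna(v) else float(v)) for c, v in row.items()}
                for t, row in self.table.to_dict("index").items()
            },
        }


# ---------------------------------------------------------------------------
# table preparation


def derive_lagged(table: pd.DataFrame) -> pd.DataFrame:
    """Add one-trial-back columns per subject.

    Adds ``prev_reward``, ``prev_transition``, ``prev_s1_choice``,
    ``prev_s2_state``, ``prev_s2_choice``, and the repeat indicators
    ``stay1`` / ``stay2`` (floats; NaN on each subject's first trial).
    Rows are returned sorted by (subject, trial).
    """
    required = {"subject", "trial", "s1_choice", "transition", "s2_state", "s2_choice", "reward"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    if table.duplicated(["subject", "trial"]).any():
        dupes = table[table.duplicated(["subject", "trial"])][["subject", "trial"]]
        raise ValueError(f"duplicate (subject, trial) keys, e.g. {dupes.iloc[0].tolist()}")
    df = table.sort_values(["subject", "trial"], kind="mergesort").reset_index(drop=True)
    g = df.groupby("subject", sort=False)
    df["prev_reward"] = g["reward"].shift(1)
    df["prev_transition"] = g["transition"].shift(1)
    df["prev_s1_choice"] = g["s1_choice"].shift(1)
    df["prev_s2_state"] = g["s2_state"].shift(1)
    df["prev_s2_choice"] = g["s2_choice"].shift(1)
    df["stay1"] = (df["s1_choice"] == df["prev_s1_choice"]).astype(float)
    df["stay2"] = (df["s2_choice"] == df["prev_s2_choice"]).astype(float)
    first = df["prev_s1_choice"].isna()
    df.loc[first, ["stay1", "stay2"]] = np.nan
    return df


def _ensure_lagged(table: pd.DataFrame) -> pd.DataFrame:
    return table if "prev_reward" in table.columns else derive_lagged(table)


def filter_sequence_trials(
    table: pd.DataFrame,
    prev_transition: str | None = "common",
    require_state_change: bool = True,
) -> pd.DataFrame:
    """Trial restriction for the action-sequence signatures.

    Keeps rows with a usable lag, optionally conditioned on the previous
    trial's transition type, and (by default) only where the current
    Stage-2 state differs from the previous one -- the restriction that
    removes attention-style confounds, since a closed-loop agent carries
    no relevant value information into a different Stage-2 state.
    """
    df = _ensure_lagged(table)
    mask = df["prev_transition"].notna()
    if prev_transition is not None:
        if prev_transition not in ("common", "rare"):
            raise ValueError("prev_transition must be 'common', 'rare', or None")
        mask &= df["prev_transition"] == prev_transition
    if require_state_change:
        mask &= df["s2_state"] != df["prev_s2_state"]
    return df[mask].reset_index(drop=True)


def bin_reward(reward: float) -> str:
    """Sign-based display binning; zero counts as negative (fixed convention)."""
    return "positive" if reward > 0 else "negative"


# ---------------------------------------------------------------------------
# two-stage estimation machinery


def _design(df: pd.DataFrame, terms: list[tuple[str, ...]]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in terms:
        x = np.ones(len(df))
        for c in term:
            x = x * df[c].to_numpy(dtype=float)
        cols.append(x)
        names.append(":".join(term))
    return np.column_stack(cols), names


def _check_variance(df: pd.DataFrame, columns: list[str]) -> None:
    for c in columns:
        vals = df[c].to_numpy(dtype=float)
        if len(vals) == 0 or np.nanstd(vals) == 0:
            raise DegenerateDataError(f"column {c!r} has zero variance in the analyzed rows")


def _fit_subject(y, X, family: str):
    """One subject's GLM/OLS fit; returns (params, bse, ok_flag)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "binomial":
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            else:
                res = sm.OLS(y, X).fit()
        except Exception:
            return None, None, False
    b, se = np.asarray(res.params), np.asarray(res.bse)
    ok = bool(np.all(np.isfinite(b)) and np.all(np.isfinite(se)) and np.all(se < SE_CAP))
    return b, se, ok


def _two_stage(
    df: pd.DataFrame,
    outcome: str,
    terms: list[tuple[str, ...]],
    family: str,
) -> RegressionResult:
    """Per-subject GLM + equal-weight across-subject t-test.

    Every subject with a well-conditioned fit contributes one
    coefficient vector; the group test is a one-sample t-test of those
    vectors against zero.  Equal weighting keeps the estimand at the
    population mean of subject-level effects (precision weighting would
    tilt it toward high-inverse-temperature subjects, whose effects are
    systematically larger).  Subjects with separated or otherwise
    degenerate fits are excluded and counted in the flags.
    """
    X_all, names = _design(df, terms)
    y_all = df[outcome].to_numpy(dtype=float)
    subjects = df["subject"].to_numpy()
    uniq = pd.unique(subjects)
    est, raw = [], []
    n_sep = n_skipped = 0
    for s in uniq:
        m = subjects == s
        y, X = y_all[m], X_all[m]
        # a subject contributes only if the outcome and every regressor vary
        if len(y) <= X.shape[1] or np.std(y) == 0 or np.any(np.std(X[:, 1:], axis=0) == 0):
            n_skipped += 1
            continue
        b, se, ok = _fit_subject(y, X, family)
        if b is None:
            n_skipped += 1
            continue
        if not ok:
            n_sep += 1
            raw.append(b)
            continue
        est.append(b)
    flags: dict = {}
    if n_sep:
        flags["separation_subjects"] = n_sep
    if n_skipped:
        flags["skipped_subjects"] = n_skipped
    n_used = len(est)
    if n_used < 2:
        # e.g. a deterministic toy where every subject separates: report
        # the direction from the raw estimates but no inferential stats
        flags["all_subjects_degenerate"] = True
        raw_arr = np.array(raw) if raw else np.full((1, len(names)), np.nan)
        tab = pd.DataFrame(
            {"b": raw_arr.mean(axis=0), "se": np.nan, "z": np.nan, "p": np.nan},
            index=names,
        )
    else:
        est_arr = np.array(est)
        b_hat = est_arr.mean(axis=0)
        se_hat = est_arr.std(axis=0, ddof=1) / math.sqrt(n_used)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b_hat / se_hat
        p = 2.0 * stats.t.sf(np.abs(t), df=n_used - 1)
        tab = pd.DataFrame({"b": b_hat, "se": se_hat, "z": t, "p": p}, index=names)
    return RegressionResult(
        table=tab,
        n_obs=len(df),
        n_subjects=len(uniq),
        n_used=n_used,
        backend="two_stage",
        outcome=outcome,
        flags=flags,
    )


def _pooled(
    df: pd.DataFrame,
    outcome: str,
    terms: list[tuple[str, ...]],
    family: str,
) -> RegressionResult:
    """Pooled GLM with cluster-robust (by subject) standard errors."""
    X, names = _design(df, terms)
    y = df[outcome].to_numpy(dtype=float)
    groups = df["subject"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "binomial":
            model = sm.GLM(y, X, family=sm.families.Binomial())
        else:
            model = sm.OLS(y, X)
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    b, se = np.asarray(res.params), np.asarray(res.bse)
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    tab = pd.DataFrame({"b": b, "se": se, "z": z, "p": p}, index=names)
    n_subj = df["subject"].nunique()
    return RegressionResult(
        table=tab, n_obs=len(df), n_subjects=n_subj, n_used=n_subj,
        backend="pooled", outcome=outcome,
        aic=float(res.aic) if family == "binomial" else None,
    )


def _mixed(
    df: pd.DataFrame,
    outcome: str,
    terms: list[tuple[str, ...]],
    family: str,
) -> RegressionResult:
    """Random-intercept mixed model (variational Bayes for logistic outcomes).

    An approximation of the full random-slopes GLMM; provided for
    sensitivity checks rather than exact replication.
    """
    X, names = _design(df, terms)
    y = df[outcome].to_numpy(dtype=float)
    data = pd.DataFrame(X[:, 1:], columns=names[1:])
    data[outcome] = y
    data["subject"] = df["subject"].to_numpy()
    if family == "binomial":
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        exog_vc = pd.get_dummies(data["subject"], sparse=True).to_numpy(dtype=float)
        model = BinomialBayesMixedGLM(
            y, X, exog_vc=exog_vc, ident=np.zeros(exog_vc.shape[1], dtype=int)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit_vb()
        b = res.fe_mean
        se = res.fe_sd
    else:
        model = sm.MixedLM(y, X, groups=data["subject"].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        b = np.asarray(res.fe_params)
        se = np.asarray(res.bse[: len(names)])
    z = b / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    tab = pd.DataFrame({"b": b, "se": se, "z": z, "p": p}, index=names)
    return RegressionResult(
        table=tab, n_obs=len(df), n_subjects=df["subject"].nunique(),
        n_used=df["subject"].nunique(), backend="mixed", outcome=outcome,
    )


def _fit(df, outcome, terms, family, backend):
    if backend == "two_stage":
        return _two_stage(df, outcome, terms, family)
    if backend == "pooled":
        return _pooled(df, outcome, terms, family)
    if backend == "mixed":
        return _mixed(df, outcome, terms, family)
    raise ValueError(f"unknown backend {backend!r}")


def _code_common(df: pd.DataFrame) -> pd.DataFrame:
    """Attach centered/coded regressor columns used by the signatures."""
    out = df.copy()
    out["prev_reward_c"] = out["prev_reward"] - out["prev_reward"].mean()
    out["prev_transition_c"] = np.where(out["prev_transition"] == "common", 0.5, -0.5)
    out["stay1_c"] = out["stay1"] - 0.5
    out["stay2_gain"] = 0.5 - out["stay2"]  # repeat = -0.5: positive b => repeats faster
    return out


# ---------------------------------------------------------------------------
# the signature analyses


def stay1_signature(table: pd.DataFrame, backend: str = "two_stage") -> RegressionResult:
    """Stage-1 stay ~ previous reward x previous transition type.

    The previous-reward main effect (term ``prev_reward_c``) is the
    model-free signature; the interaction is the model-based one.
    """
    df = _ensure_lagged(table)
    df = df[df["prev_reward"].notna()].reset_index(drop=True)
    if df["subject"].nunique() < 2:
        raise ValueError("stay1_signature needs at least 2 subjects with lagged trials")
    _check_variance(df, ["prev_reward"])
    df = _code_common(df)
    terms = [("prev_reward_c",), ("prev_transition_c",), ("prev_reward_c", "prev_transition_c")]
    return _fit(df, "stay1", terms, "binomial", backend)


def expt2_stay1_after_rare(table: pd.DataFrame, backend: str = "two_stage") -> RegressionResult:
    """Stage-1 stay ~ previous reward, among trials following a rare (red)
    transition.  Positive previous-reward effect = model-free signature."""
    df = _ensure_lagged(table)
    df = df[(df["prev_transition"] == "rare")].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no trials follow a rare transition")
    _check_variance(df, ["prev_reward"])
    df = _code_common(df)
    return _fit(df, "stay1", [("prev_reward_c",)], "binomial", backend)


def stage2_choice_signature(
    filtered: pd.DataFrame,
    split_by_prev_transition: bool = False,
    backend: str = "pooled",
) -> RegressionResult:
    """Stage-2 stay ~ Stage-1 stay x previous reward (x previous transition).

    Run on a table prepared by :func:`filter_sequence_trials`.  The
    ``stay1_c:prev_reward_c`` interaction is the action-sequence
    signature; with the split flag the three-way
    ``stay1_c:prev_reward_c:prev_transition_c`` term tests whether the
    signature is stronger after common than rare transitions (the mark of
    model-based sequence control).
    """
    df = filtered[filtered["prev_reward"].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty table after the sequence-trial restriction")
    _check_variance(df, ["prev_reward", "stay1"])
    df = _code_common(df)
    terms = [("stay1_c",), ("prev_reward_c",), ("stay1_c", "prev_reward_c")]
    if split_by_prev_transition:
        _check_variance(df, ["prev_transition_c"])
        terms += [
            ("prev_transition_c",),
            ("stay1_c", "prev_transition_c"),
            ("prev_reward_c", "prev_transition_c"),
            ("stay1_c", "prev_reward_c", "prev_transition_c"),
        ]
    return _fit(df, "stay2", terms, "binomial", backend)


def stage2_rt_signature(
    filtered: pd.DataFrame,
    split_by_prev_transition: bool = False,
    backend: str = "pooled",
    parameterization: str = "factorial",
) -> RegressionResult:
    """Stage-2 reaction time version of the sequence signature.

    Factorial default: rt2 ~ speed-gain coding of the Stage-2 repeat
    crossed with Stage-1 stay and previous reward.  The term
    ``stay2_gain:stay1_c:prev_reward_c`` is the signature (positive:
    repeating Stage 2 is fastest after a reward with a repeated Stage-1
    choice).  ``parameterization="difference"`` instead computes each
    subject's repeat-vs-switch RT difference per (stay1 x binned reward)
    cell and t-tests the interaction contrast across subjects.
    """
    if "rt2" not in filtered.columns:
        raise ValueError("stage2_rt_signature requires an rt2 column")
    df = filtered[filtered["prev_reward"].notna() & filtered["rt2"].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("empty table after the sequence-trial restriction")
    if np.std(df["rt2"].to_numpy(float)) == 0:
        raise DegenerateDataError("rt2 has zero variance")
    _check_variance(df, ["prev_reward", "stay1", "stay2"])
    df = _code_common(df)
    if parameterization == "difference":
        return _rt_difference_contrast(df)
    if parameterization != "factorial":
        raise ValueError("parameterization must be 'factorial' or 'difference'")
    terms = [
        ("stay2_gain",), ("stay1_c",), ("prev_reward_c",),
        ("stay2_gain", "stay1_c"), ("stay2_gain", "prev_reward_c"),
        ("stay1_c", "prev_reward_c"),
        ("stay2_gain", "stay1_c", "prev_reward_c"),
    ]
    if split_by_prev_transition:
        _check_variance(df, ["prev_transition_c"])
        terms += [
            ("prev_transition_c",),
            ("stay2_gain", "prev_transition_c"),
            ("stay1_c", "prev_transition_c"),
            ("prev_reward_c", "prev_transition_c"),
            ("stay2_gain", "stay1_c", "prev_transition_c"),
            ("stay2_gain", "prev_reward_c", "prev_transition_c"),
            ("stay1_c", "prev_reward_c", "prev_transition_c"),
            ("stay2_gain", "stay1_c", "prev_reward_c", "prev_transition_c"),
        ]
    return _fit(df, "rt2", terms, "gaussian", backend)


def _rt_difference_contrast(df: pd.DataFrame) -> RegressionResult:
    """Per-subject repeat-vs-switch RT gains, interaction contrast t-test."""
    df = df.copy()
    df["rew_bin"] = (df["prev_reward"] > 0).astype(int)
    contrasts = []
    for _, sub in df.groupby("subject"):
        gains = {}
        for (s1, rb), cell in sub.groupby(["stay1", "rew_bin"]):
            rep = cell.loc[cell["stay2"] == 1, "rt2"]
            swi = cell.loc[cell["stay2"] == 0, "rt2"]
            if len(rep) and len(swi):
                gains[(s1, rb)] = swi.mean() - rep.mean()
        if len(gains) == 4:
            contrasts.append(
                (gains[(1, 1)] - gains[(1, 0)]) - (gains[(0, 1)] - gains[(0, 0)])
            )
    if len(contrasts) < 2:
        raise DegenerateDataError("too few subjects with all four cells populated")
    arr = np.asarray(contrasts)
    t, p = stats.ttest_1samp(arr, 0.0)
    se = arr.std(ddof=1) / np.sqrt(len(arr))
    tab = pd.DataFrame(
        {"b": [arr.mean()], "se": [se], "z": [t], "p": [p]}, index=["gain_interaction"]
    )
    return RegressionResult(
        table=tab, n_obs=len(df), n_subjects=df["subject"].nunique(),
        n_used=len(arr), backend="difference", outcome="rt2_gain",
    )


class GradedVsBinned(NamedTuple):
    aic_graded: float
    aic_binned: float
    delta: float  # aic_binned - aic_graded; positive favors the graded model
    flags: dict


def graded_vs_binned(table: pd.DataFrame) -> GradedVsBinned:
    """AIC comparison: Stage-1 stay from continuous vs. sign-binned reward.

    Restricted to trials following common transitions.  Pooled logistic
    models (one intercept; the comparison is between reward codings on an
    identical row set), so the AIC difference isolates the reward term.
    """
    df = _ensure_lagged(table)
    df = df[(df["prev_transition"] == "common") & df["prev_reward"].notna()].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no trials follow a common transition")
    _check_variance(df, ["prev_reward"])
    flags: dict = {}
    rewards = df["prev_reward"].to_numpy(float)
    if len(np.unique(rewards)) <= 2:
        # with two reward levels the graded and binned codings are collinear
        flags["binary_rewards"] = True
    y = df["stay1"].to_numpy(float)
    x_graded = rewards - rewards.mean()
    x_binned = np.where(rewards > 0, 0.5, -0.5)
    aics = []
    for x in (x_graded, x_binned):
        X = np.column_stack([np.ones(len(y)), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        aics.append(float(res.aic))
    return GradedVsBinned(aics[0], aics[1], aics[1] - aics[0], flags)
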