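import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from seqhabit.agents import MODELS, AgentParams
from seqhabit.fitting import (
    bic_bayes_factor, bms_pxp, fit_map, free_param_names, hessian_fd,
    laplace_evidence, laplace_log_evidence, log_prior_transformed,
    session_arrays, to_natural, to_transformed, trial_loglik,
)
from seqhabit.simulate import CohortConfig, simulate_cohort
from seqhabit.task import make_task


@pytest.fixture(scope="module")
def one_session(graded_task):
    cfg = CohortConfig(model=MODELS["Mixture-actions/Mixture-sequences"],
                       task=graded_task, n_agents=1, n_trials=125, seed=5)
    return session_arrays(simulate_cohort(cfg))


class TestLikelihood:
    def test_alpha_irrelevant_when_choice_is_value_blind(self, one_session, graded_task):
        m = MODELS["No sequences"]
        lls = {trial_loglik(m, AgentParams(a, 0.0, 0.0, 0.0, 0.5, 0.5),
                            one_session, graded_task) for a in (0.1, 0.5, 0.9)}
        assert len(lls) == 1

    def test_loglik_nonpositive_and_monotone_in_trials(self, one_session, graded_task):
        m = MODELS["Mixture-actions/Mixture-sequences"]
        p = AgentParams(0.5, 2.0, 2.0, 0.2, 0.4, 0.6)
        from seqhabit.fitting import SessionArrays
        prev = 0.0
        for n in (10, 50, 125):
            sub = SessionArrays(one_session.a1[:n], one_session.s2[:n],
                                one_session.a2[:n], one_session.r[:n])
            ll = trial_loglik(m, p, sub, graded_task)
            assert ll <= 0.0
            assert ll <= prev
            prev = ll

    def test_sequence_models_need_path_based_representation(self, orig_task):
        tab = simulate_cohort(CohortConfig(model=MODELS["Pure MB"], task=orig_task,
                                           n_agents=1, n_trials=30, seed=0))
        with pytest.raises(ValueError, match="path_based"):
            trial_loglik(MODELS["Pure MB"], AgentParams(0.5, 1, 1, 0),
                         session_arrays(tab), orig_task)


class TestTransforms:
    def test_roundtrip(self):
        names = ("alpha", "beta1", "beta2", "nu", "omega", "lam")
        vals = {"alpha": 0.3, "beta1": 4.2, "beta2": 0.7, "nu": -1.1,
                "omega": 0.9, "lam": 0.05}
        back = to_natural(to_transformed(vals, names), names)
        for k in names:
            assert back[k] == pytest.approx(vals[k], rel=1e-9)

    def test_prior_density_finite_at_extremes(self):
        names = ("alpha", "beta1", "omega")
        for x in ([-40.0, -40.0, -40.0], [40.0, 5.0, 40.0]):
            assert math.isfinite(log_prior_transformed(np.array(x), names))

    def test_free_params_by_model(self):
        assert free_param_names(MODELS["Pure MB"]) == ("alpha", "beta1", "beta2", "nu")
        assert free_param_names(MODELS["No sequences"]) == (
            "alpha", "beta1", "beta2", "nu", "omega", "lam")
        assert free_param_names(MODELS["MB-actions/Mixture-sequences"]) == (
            "alpha", "beta1", "beta2", "nu", "omega")
        assert free_param_names(MODELS["No sequences"], fixed={"nu": 0.0}) == (
            "alpha", "beta1", "beta2", "omega", "lam")


class TestMapFit:
    def test_deterministic_given_seed(self, one_session, graded_task):
        m = MODELS["No sequences"]
        a = fit_map(m, one_session, graded_task, n_restarts=2, rng=7)
        b = fit_map(m, one_session, graded_task, n_restarts=2, rng=7)
        assert np.array_equal(a.x_map, b.x_map)
        assert a.log_posterior == b.log_posterior

    def test_too_few_trials_rejected(self, graded_task):
        from seqhabit.fitting import SessionArrays
        tiny = SessionArrays((0,) * 5, (0,) * 5, (0,) * 5, (1.0,) * 5)
        with pytest.raises(ValueError, match="trials"):
            fit_map(MODELS["No sequences"], tiny, graded_task, rng=0)

    def test_recovers_strong_known_parameters(self, graded_task):
        """High-beta agent, 1,000 trials: alpha and omega recovered near
        the generating values."""
        from seqhabit.simulate import run_session
        import seqhabit.simulate  # noqa: F401
        model = MODELS["No sequences"]
        true = AgentParams(alpha=0.4, beta1=8.0, beta2=8.0, nu=0.2, omega=0.3, lam=0.6)
        recs = run_session(model, true, graded_task, np.random.default_rng(17), n_trials=1000)
        df = pd.DataFrame(
            [(1, r.trial, ("L1", "R1")[r.s1_choice], r.transition,
              ("green", "yellow", "red")[r.s2_state], ("L2", "R2")[r.s2_choice], r.reward)
             for r in recs],
            columns=["subject", "trial", "s1_choice", "transition",
                     "s2_state", "s2_choice", "reward"])
        fit = fit_map(model, df, graded_task, n_restarts=4, rng=1)
        assert fit.converged
        # posterior curvature gives the parameter scale in transformed space
        sds = np.sqrt(np.diag(np.linalg.inv(fit.hessian)))
        x_true = to_transformed(true.to_dict(), fit.free_names)
        for i, name in enumerate(fit.free_names):
            if name in ("alpha", "omega"):
                assert abs(fit.x_map[i] - x_true[i]) < 3 * sds[i] + 0.3


class TestLaplace:
    def test_exact_for_gaussian_posterior(self):
        # prior N(0,1), likelihood N(y | x, 1), y = 0.8:
        # exact evidence = N(y | 0, 2)
        y = 0.8

        def neg_log_post(x):
            return 0.5 * x[0] ** 2 + 0.5 * (y - x[0]) ** 2 + math.log(2 * math.pi)

        res = optimize.minimize(neg_log_post, [0.0], method="BFGS")
        H = hessian_fd(neg_log_post, res.x, 1e-5)
        lev, reg = laplace_log_evidence(-res.fun, H)
        exact = -0.5 * math.log(2 * math.pi * 2.0) - y**2 / 4.0
        assert not reg
        assert lev == pytest.approx(exact, abs=1e-6)

    def test_invariant_to_parameter_transform_on_conjugate_toy(self):
        """Beta-Bernoulli marginal: Laplace through the logit transform and
        through the natural space agree with the exact value within 0.05."""
        a, b, n, k = 2.0, 3.0, 100, 37
        exact = special.betaln(a + k, b + n - k) - special.betaln(a, b)

        def neg_logit_post(x):
            th = 1.0 / (1.0 + math.exp(-x[0]))
            return -(k * math.log(th) + (n - k) * math.log(1 - th)
                     + (a - 1) * math.log(th) + (b - 1) * math.log(1 - th)
                     - special.betaln(a, b) + math.log(th * (1 - th)))

        def neg_nat_post(x):
            th = x[0]
            return -(k * math.log(th) + (n - k) * math.log(1 - th)
                     + (a - 1) * math.log(th) + (b - 1) * math.log(1 - th)
                     - special.betaln(a, b))

        for f, x0 in ((neg_logit_post, [0.0]), (neg_nat_post, [0.4])):
            res = optimize.minimize(f, x0, method="Nelder-Mead", options={"xatol": 1e-10})
            H = hessian_fd(f, np.asarray(res.x), 1e-5)
            lev, _ = laplace_log_evidence(-res.fun, H)
            assert lev == pytest.approx(exact, abs=0.05)

    def test_nonpd_hessian_is_regularized_not_fatal(self):
        lev, reg = laplace_log_evidence(-10.0, np.array([[1.0, 0.0], [0.0, -0.5]]))
        assert reg and math.isfinite(lev)


def brute_force_pxp(lme, n_draws=400_000, seed=0):
    """Monte-Carlo evaluation of the same random-effects hierarchy:
    r ~ Dirichlet(1), m_n | r ~ Categorical(r), evidence p(y_n | m) given.
    Importance sampling over the prior gives exceedance probabilities and
    the exact Bayes omnibus risk."""
    rng = np.random.default_rng(seed)
    lme = np.asarray(lme, dtype=float)
    n, K = lme.shape
    draws = rng.dirichlet(np.ones(K), size=n_draws)
    M = np.exp(lme - lme.max(axis=1, keepdims=True))
    lw = np.zeros(n_draws)
    for i in range(n):
        lw += np.log(draws @ M[i]) + lme[i].max()
    w = np.exp(lw - lw.max())
    w /= w.sum()
    winners = np.argmax(draws, axis=1)
    ep = np.array([w[winners == k].sum() for k in range(K)])
    log_y1 = special.logsumexp(lw) - math.log(n_draws)
    log_y0 = sum(special.logsumexp(lme[i]) - math.log(K) for i in range(n))
    bor = 1.0 / (1.0 + math.exp(log_y1 - log_y0))
    return ep * (1 - bor) + bor / K


class TestModelSelection:
    def test_identical_evidence_gives_uniform_pxp(self):
        res = bms_pxp(np.zeros((10, 4)), rng=0, n_samples=100_000)
        assert np.allclose(res.pxp, 0.25, atol=0.01)

    def test_dominant_model_wins_decisively(self):
        lme = np.zeros((20, 2))
        lme[:, 0] = 10.0
        res = bms_pxp(lme, rng=0, n_samples=100_000)
        assert res.pxp[0] > 0.99
        assert res.best() == "model_0"

    def test_small_samples_shrink_toward_uniform(self):
        """With a dominant model, fewer subjects leave more omnibus risk,
        pulling PXP toward 1/K."""
        lme_big = np.zeros((20, 2)); lme_big[:, 0] = 3.0
        lme_small = lme_big[:2]
        big = bms_pxp(lme_big, rng=0, n_samples=100_000)
        small = bms_pxp(lme_small, rng=0, n_samples=100_000)
        assert small.pxp[0] < big.pxp[0]
        assert small.bor > big.bor

    def test_nan_evidence_rejected(self):
        lme = np.zeros((5, 2))
        lme[0, 0] = np.nan
        with pytest.raises(ValueError):
            bms_pxp(lme, rng=0)

    def test_matches_brute_force_hierarchy(self):
        rng = np.random.default_rng(42)
        lme = rng.normal(0, 1, (12, 3))
        lme[:, 1] += 1.0
        res = bms_pxp(lme, rng=1, n_samples=400_000)
        brute = brute_force_pxp(lme)
        assert np.allclose(res.pxp, brute, atol=0.06)


class TestBicBayesFactor:
    def test_equal_fits_give_unity(self):
        assert bic_bayes_factor(-100, 3, -100, 3, 125) == pytest.approx(1.0)

    def test_closed_form_ten(self):
        # BIC difference of 2 ln 10 corresponds to a Bayes factor of 10
        delta = 2 * math.log(10)
        assert bic_bayes_factor(-50, 2, -50 - delta / 2, 2, 100) == pytest.approx(10.0)

    def test_reciprocity(self):
        bf = bic_bayes_factor(-80, 2, -75, 4, 125)
        assert bic_bayes_factor(-75, 4, -80, 2, 125) == pytest.approx(1 / bf)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bic_bayes_factor(-1, 1, -1, 1, 0)


class TestEvidenceOrdering:
    def test_mf_generated_subjects_favor_mf_bearing_model(self, graded_task):
        """Strongly model-free agents (omega near 0, crisp choices) must be
        assigned higher evidence by the flat hybrid model than by the pure
        MB sequence model for nearly all subjects."""
        from seqhabit.simulate import run_session
        model = MODELS["No sequences"]
        wins = 0
        n_subj = 8
        for i in range(n_subj):
            p = AgentParams(alpha=0.5, beta1=8.0, beta2=8.0, nu=0.0, omega=0.1, lam=0.8)
            recs = run_session(model, p, graded_task,
                               np.random.default_rng(100 + i), n_trials=250)
            df = pd.DataFrame(
                [(1, r.trial, ("L1", "R1")[r.s1_choice], r.transition,
                  ("green", "yellow", "red")[r.s2_state], ("L2", "R2")[r.s2_choice], r.reward)
                 for r in recs],
                columns=["subject", "trial", "s1_choice", "transition",
                         "s2_state", "s2_choice", "reward"])
            arrays = session_arrays(df)
            ev_mf = laplace_evidence(fit_map(model, arrays, graded_task, n_restarts=2, rng=i))
            ev_mb = laplace_evidence(fit_map(MODELS["Pure MB"], arrays, graded_task,
                                             n_restarts=2, rng=i))
            wins += ev_mf > ev_mb
        assert wins >= int(0.9 * n_subj)
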