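import numpy as np
import pytest
from scipy.stats import truncnorm

from ternmix.gibbs import (
    ChainConfig,
    ChainState,
    init_chain,
    mcmc_sweep,
    posterior_summaries,
    run_mcmc,
    update_labels,
    update_mu,
    update_pi,
    update_sigma,
)
from ternmix.labelgraph import CandidateSet
from ternmix.model import (
    AssociationVector,
    ConstrainedClassParams,
    validate_constraints,
)
from ternmix.simulate import SimulationSpec, build_classes, sample_from_mixture
from ternmix.weights import Hyperparameters


def make_hyper(vectors, mu_scale=2.0, strength=50.0):
    vecs = [AssociationVector(v) for v in vectors]
    D = vecs[0].D
    M = len(vecs)
    mu0 = np.zeros((M, D))
    psi0 = np.zeros((M, D, D))
    nu = np.full(M, max(strength, D + 2))
    for m, h in enumerate(vecs):
        mu0[m] = [mu_scale * a for a in h]
        S = np.eye(D)
        for r in range(D):
            for t in range(r + 1, D):
                if h[r] != 0 and h[t] != 0:
                    S[r, t] = S[t, r] = 0.5 * h[r] * h[t]
        psi0[m] = S * (nu[m] - D - 1)
    return Hyperparameters(
        vectors=vecs,
        mu0=mu0,
        psi0=psi0,
        kappa=nu.copy(),
        nu=nu,
        dirichlet=np.full(M, strength),
    )


def two_class_setup(n=400, seed=0):
    classes = build_classes([(0, 0), (1, 1)], mean_scale=4.0, corr=0.5)
    spec = SimulationSpec(classes=classes, weights=[0.5, 0.5], n=n, seed=seed)
    sim = sample_from_mixture(spec)
    hyper = make_hyper([(0, 0), (1, 1)], mu_scale=4.0)
    cands = CandidateSet(list(hyper.vectors), pruned=True)
    return sim, cands, hyper


class TestInitChain:
    def test_null_only_model_is_fully_determined(self):
        hyper = make_hyper([(0, 0)])
        cands = CandidateSet(list(hyper.vectors), pruned=True)
        X = np.random.default_rng(0).standard_normal((50, 2))
        state = init_chain(X, cands, hyper, ChainConfig(n_iter=10, burn_in=1))
        np.testing.assert_array_equal(state.mus, 0.0)
        np.testing.assert_array_equal(state.sigmas[0], np.eye(2))
        assert np.all(state.labels == 0)

    def test_state_valid_for_any_input(self):
        sim, cands, hyper = two_class_setup()
        state = init_chain(sim.scores, cands, hyper, ChainConfig(n_iter=10, burn_in=1))
        state.validate()  # raises on violation


class TestUpdateLabels:
    def test_single_class_unchanged(self):
        hyper = make_hyper([(0, 0)])
        X = np.random.default_rng(1).standard_normal((30, 2))
        state = ChainState(
            list(hyper.vectors), np.zeros((1, 2)), np.eye(2)[None], np.ones(1),
            np.zeros(30, int),
        )
        out = update_labels(state, X, np.random.default_rng(2))
        np.testing.assert_array_equal(out, 0)

    def test_point_near_mean_goes_to_that_class(self):
        hyper = make_hyper([(0, 0), (1, 1)], mu_scale=4.0)
        state = ChainState(
            list(hyper.vectors),
            np.array([[0.0, 0.0], [4.0, 4.0]]),
            np.stack([np.eye(2), np.eye(2)]),
            np.array([0.5, 0.5]),
            np.zeros(1, int),
        )
        X = np.array([[4.0, 4.0]])
        rng = np.random.default_rng(3)
        draws = np.array([update_labels(state, X, rng)[0] for _ in range(2000)])
        assert np.mean(draws == 1) > 0.999

    def test_frequencies_match_analytic_responsibilities(self):
        from scipy.stats import multivariate_normal

        state = ChainState(
            [AssociationVector((0, 0)), AssociationVector((1, 1))],
            np.array([[0.0, 0.0], [1.5, 1.5]]),
            np.stack([np.eye(2), np.eye(2)]),
            np.array([0.7, 0.3]),
            np.zeros(1, int),
        )
        x = np.array([[1.0, 1.0]])
        p0 = 0.7 * multivariate_normal([0, 0], np.eye(2)).pdf(x[0])
        p1 = 0.3 * multivariate_normal([1.5, 1.5], np.eye(2)).pdf(x[0])
        expect = p1 / (p0 + p1)
        rng = np.random.default_rng(4)
        draws = np.array([update_labels(state, x, rng)[0] for _ in range(10_000)])
        assert np.mean(draws == 1) == pytest.approx(expect, abs=0.02)


class TestUpdatePi:
    def _state(self, labels, M=2):
        return ChainState(
            [AssociationVector((0, 0)), AssociationVector((1, 1))][:M],
            np.zeros((M, 2)),
            np.tile(np.eye(2), (M, 1, 1)),
            np.full(M, 1.0 / M),
            np.asarray(labels, int),
        )

    def test_prior_domination(self):
        state = self._state([0] * 10)
        rng = np.random.default_rng(5)
        draws = np.array([update_pi(state, np.array([5e5, 5e5]), rng) for _ in range(200)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.5, 0.5], atol=0.01)

    def test_data_domination(self):
        state = self._state([0] * 900 + [1] * 100)
        rng = np.random.default_rng(6)
        draws = np.array([update_pi(state, np.array([1.0, 1.0]), rng) for _ in range(500)])
        np.testing.assert_allclose(draws.mean(axis=0), [0.9, 0.1], atol=0.02)

    def test_moments_match_dirichlet_closed_form(self):
        state = self._state([0] * 30 + [1] * 10)
        alpha = np.array([2.0, 3.0])
        post = alpha + np.array([30, 10])
        a0 = post.sum()
        rng = np.random.default_rng(7)
        draws = np.array([update_pi(state, alpha, rng) for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), post / a0, atol=0.005)
        var = post * (a0 - post) / (a0**2 * (a0 + 1))
        np.testing.assert_allclose(draws.var(axis=0), var, atol=0.002)


class TestUpdateMu:
    def test_fully_null_class_untouched(self):
        hyper = make_hyper([(0, 0)])
        X = np.random.default_rng(8).standard_normal((40, 2))
        state = ChainState(
            list(hyper.vectors), np.zeros((1, 2)), np.eye(2)[None], np.ones(1),
            np.zeros(40, int),
        )
        out = update_mu(state, X, hyper, ChainConfig(n_iter=2, burn_in=0), np.random.default_rng(9))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_signed_coordinate_matches_truncnorm(self):
        """One non-null coordinate: draws follow the univariate truncated
        normal with the conjugate posterior location/scale."""
        rng_data = np.random.default_rng(10)
        X = np.column_stack([rng_data.normal(0.4, 1.0, 25), rng_data.normal(0, 1, 25)])
        hyper = make_hyper([(1, 0)], mu_scale=0.5, strength=10.0)
        state = ChainState(
            list(hyper.vectors),
            np.array([[0.5, 0.0]]),
            np.eye(2)[None].copy(),
            np.ones(1),
            np.zeros(25, int),
        )
        n_h, kap = 25, 10.0
        loc = (kap * 0.5 + n_h * X[:, 0].mean()) / (kap + n_h)
        sd = np.sqrt(1.0 / (kap + n_h))
        ref = truncnorm(a=(0 - loc) / sd, b=np.inf, loc=loc, scale=sd)
        rng = np.random.default_rng(11)
        cfg = ChainConfig(n_iter=2, burn_in=0)
        draws = np.array(
            [update_mu(state, X, hyper, cfg, rng)[0, 0] for _ in range(10_000)]
        )
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(ref.mean(), abs=4 * ref.std() / 100)
        assert draws.std() == pytest.approx(ref.std(), rel=0.05)

    def test_inactive_truncation_matches_conjugate_normal(self):
        """Data deep inside the orthant: truncation never binds and the
        draws match the untruncated conjugate posterior moments."""
        rng_data = np.random.default_rng(12)
        X = rng_data.multivariate_normal([5.0, 5.0], np.eye(2), size=200)
        hyper = make_hyper([(1, 1)], mu_scale=5.0, strength=20.0)
        state = ChainState(
            list(hyper.vectors),
            np.array([[5.0, 5.0]]),
            np.eye(2)[None].copy(),
            np.ones(1),
            np.zeros(200, int),
        )
        kap, n_h = 20.0, 200
        loc = (kap * 5.0 + n_h * X.mean(axis=0)) / (kap + n_h)
        sd = np.sqrt(1.0 / (kap + n_h))
        rng = np.random.default_rng(13)
        cfg = ChainConfig(n_iter=2, burn_in=0)
        draws = np.array([update_mu(state, X, hyper, cfg, rng)[0] for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), loc, atol=5 * sd / 100 * 4)
        np.testing.assert_allclose(draws.std(axis=0), sd, rtol=0.05)


class TestUpdateSigma:
    def test_null_class_keeps_identity(self):
        hyper = make_hyper([(0, 0)])
        X = np.random.default_rng(14).standard_normal((40, 2))
        state = ChainState(
            list(hyper.vectors), np.zeros((1, 2)), np.eye(2)[None], np.ones(1),
            np.zeros(40, int),
        )
        out, acc = update_sigma(state, X, hyper, ChainConfig(n_iter=2, burn_in=0), np.random.default_rng(15))
        np.testing.assert_array_equal(out[0], np.eye(2))
        assert acc[0]

    def test_concordant_class_draws_stay_positive(self):
        sim, cands, hyper = two_class_setup(n=300, seed=16)
        cfg = ChainConfig(n_iter=2, burn_in=0)
        state = init_chain(sim.scores, cands, hyper, cfg)
        rng = np.random.default_rng(17)
        for _ in range(50):
            state.sigmas, _ = update_sigma(state, sim.scores.values, hyper, cfg, rng)
            assert state.sigmas[1][0, 1] > 0

    def test_unconstrained_limit_matches_iw_mean(self):
        """All-positive label with strongly positively correlated data: the
        sign indicator never rejects and draw moments match the conjugate
        inverse-Wishart posterior mean."""
        rng_data = np.random.default_rng(18)
        S_true = np.array([[1.0, 0.6], [0.6, 1.0]])
        X = rng_data.multivariate_normal([3.0, 3.0], S_true, size=300)
        hyper = make_hyper([(1, 1)], mu_scale=3.0, strength=10.0)
        mu = np.array([[3.0, 3.0]])
        state = ChainState(
            list(hyper.vectors), mu, np.eye(2)[None].copy(), np.ones(1),
            np.zeros(300, int),
        )
        diff = X - mu[0]
        psi_n = hyper.psi0[0] + diff.T @ diff  # mu = mu0, so the kappa term is 0
        df_n = hyper.nu[0] + 300 + 1
        expect = psi_n / (df_n - 2 - 1)
        cfg = ChainConfig(n_iter=2, burn_in=0)
        rng = np.random.default_rng(19)
        draws = np.stack(
            [update_sigma(state, X, hyper, cfg, rng)[0][0] for _ in range(10_000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), expect, rtol=0.02)


class TestRunMcmc:
    def test_single_null_candidate_states_identical(self):
        hyper = make_hyper([(0, 0)])
        cands = CandidateSet(list(hyper.vectors), pruned=True)
        X = np.random.default_rng(20).standard_normal((40, 2))
        cfg = ChainConfig(n_iter=20, burn_in=5, seed=21)
        draws = run_mcmc(X, cands, hyper, cfg)
        assert np.all(draws.mu == 0.0)
        assert np.all(draws.sigma == np.eye(2))
        np.testing.assert_allclose(draws.pi, 1.0, rtol=1e-12)

    def test_seed_determinism(self):
        sim, cands, hyper = two_class_setup(n=200)
        cfg = ChainConfig(n_iter=30, burn_in=10, seed=5)
        a = run_mcmc(sim.scores, cands, hyper, cfg)
        b = run_mcmc(sim.scores, cands, hyper, cfg)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_checkpoint_resume_reproduces_uninterrupted_chain(self):
        sim, cands, hyper = two_class_setup(n=150)
        X = sim.scores.values
        cfg = ChainConfig(n_iter=40, burn_in=0, seed=6)
        full = run_mcmc(X, cands, hyper, cfg)
        # interrupted: 15 sweeps, checkpoint, then 25 more with the same rng
        rng = np.random.default_rng(cfg.seed)
        state = init_chain(X, cands, hyper, cfg, rng)
        for _ in range(15):
            state, _ = mcmc_sweep(state, X, hyper, cfg, rng)
        resumed = run_mcmc(
            X, cands, hyper,
            ChainConfig(n_iter=25, burn_in=0, seed=999),
            start_state=state, rng=rng,
        )
        np.testing.assert_array_equal(full.mu[15:], resumed.mu)
        np.testing.assert_array_equal(full.labels[15:], resumed.labels)

    def test_all_retained_draws_satisfy_constraints(self):
        sim, cands, hyper = two_class_setup(n=200)
        cfg = ChainConfig(n_iter=30, burn_in=10, seed=7)
        draws = run_mcmc(sim.scores, cands, hyper, cfg)
        for t in range(draws.T):
            for m, h in enumerate(draws.vectors):
                p = ConstrainedClassParams(h, draws.mu[t, m], draws.sigma[t, m])
                assert validate_constraints(p) == []

    def test_burnin_thinning_bookkeeping(self):
        sim, cands, hyper = two_class_setup(n=100)
        cfg = ChainConfig(n_iter=23, burn_in=5, thin=3, seed=8)
        draws = run_mcmc(sim.scores, cands, hyper, cfg)
        assert draws.T == (23 - 5) // 3 == cfg.n_retained


class TestPosteriorSummaries:
    def test_t1_equals_single_state(self):
        sim, cands, hyper = two_class_setup(n=100)
        cfg = ChainConfig(n_iter=6, burn_in=5, seed=9)
        draws = run_mcmc(sim.scores, cands, hyper, cfg)
        assert draws.T == 1
        model, membership = posterior_summaries(draws)
        np.testing.assert_allclose(model.classes[1].mu, draws.mu[0, 1])
        np.testing.assert_array_equal(membership.sum(axis=1), 1.0)

    def test_modal_class_matches_planted_truth(self):
        sim, cands, hyper = two_class_setup(n=400, seed=23)
        cfg = ChainConfig(n_iter=200, burn_in=100, seed=10)
        draws = run_mcmc(sim.scores, cands, hyper, cfg)
        _, membership = posterior_summaries(draws)
        acc = np.mean(membership.argmax(axis=1) == sim.labels)
        assert acc >= 0.95
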