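"""Step 4 — Metropolis–Hastings-within-Gibbs for the D-dimensional model.

The retained candidate classes and their empirical-Bayes hyperparameters
define a hierarchical constrained normal mixture:

    x_i | mu_h, Sigma_h, H_i = h  ~  N_D(mu_h, Sigma_h), constrained by h
    mu_h | Sigma_h                ~  N_D(mu0_h, Sigma_h / kappa_h), truncated
    Sigma_h                       ~  constrained IW_D(Psi0_h, nu_h)
    H_i | pi                      ~  Categorical(pi)
    pi                            ~  Dirichlet(alpha)

Null dimensions of each class are fixed (mean 0, unit variance, zero
covariance), so only the non-null block of each class is sampled.  The
mean update is a draw from the conjugate normal posterior truncated to
the orthant sgn(mu_d) = h_d (coordinate-wise Gibbs with inverse-CDF
sampling); the covariance update proposes from the unconstrained
conjugate inverse-Wishart posterior and rejects proposals whose
off-diagonal signs violate sgn(Sigma_rt) = h_r * h_t — an independence
proposal whose only difference from the target is the sign indicator, so
valid proposals are accepted with probability 1 and the constrained-IW
normalizing constant cancels.  Because the constraints pin each class's
identity, label switching cannot occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp, ndtr, ndtri
from scipy.stats import invwishart

from .labelgraph import CandidateSet
from .model import (
    AssociationVector,
    ConstrainedClassParams,
    MixtureModel,
    ScoreMatrix,
    mvn_logpdf,
    project_to_constraints,
    validate_constraints,
)
from .weights import Hyperparameters

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "ChainState",
    "PosteriorDraws",
    "init_chain",
    "update_labels",
    "update_pi",
    "update_mu",
    "update_sigma",
    "mcmc_sweep",
    "run_mcmc",
    "posterior_summaries",
]


@dataclass
class ChainConfig:
    """MCMC run settings."""

    n_iter: int = 5000
    burn_in: int = 2500
    thin: int = 1
    seed: int = 0
    mh_max_attempts: int = 100
    tnorm_sweeps: int = 5  # inner Gibbs sweeps for the truncated-normal draw

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ChainState:
    """Current parameters and label assignment of the chain."""

    vectors: list[AssociationVector]
    mus: np.ndarray  # (M, D)
    sigmas: np.ndarray  # (M, D, D)
    pi: np.ndarray  # (M,)
    labels: np.ndarray  # (n,) int indices into vectors

    @property
    def M(self) -> int:
        return len(self.vectors)

    @property
    def D(self) -> int:
        return self.vectors[0].D

    def copy(self) -> "ChainState":
        return ChainState(
            list(self.vectors),
            self.mus.copy(),
            self.sigmas.copy(),
            self.pi.copy(),
            self.labels.copy(),
        )

    def validate(self) -> None:
        for m, h in enumerate(self.vectors):
            bad = validate_constraints(
                ConstrainedClassParams(h, self.mus[m], self.sigmas[m])
            )
            if bad:
                raise ValueError(f"chain state class {h} invalid: {bad}")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in, thinned states of the chain."""

    vectors: list[AssociationVector]
    mu: np.ndarray  # (T, M, D)
    sigma: np.ndarray  # (T, M, D, D)
    pi: np.ndarray  # (T, M)
    labels: np.ndarray  # (T, n) int32
    seed: int
    config: ChainConfig
    sigma_accept_rate: np.ndarray = field(default_factory=lambda: np.array([]))
    empty_fraction: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def T(self) -> int:
        return self.mu.shape[0]

    @property
    def M(self) -> int:
        return len(self.vectors)

    @property
    def D(self) -> int:
        return self.vectors[0].D

    @property
    def n(self) -> int:
        return self.labels.shape[1]

    def membership(self) -> np.ndarray:
        """(n, M) fraction of retained iterations assigning each class."""
        out = np.zeros((self.n, self.M))
        for t in range(self.T):
            np.add.at(out, (np.arange(self.n), self.labels[t]), 1.0)
        return out / self.T


# ---------------------------------------------------------------------------
# updates


def init_chain(
    data: ScoreMatrix | np.ndarray,
    candidates: CandidateSet,
    hyper: Hyperparameters,
    config: ChainConfig,
    rng: Optional[np.random.Generator] = None,
) -> ChainState:
    """Deterministic parameter start at the prior means, labels sampled."""
    if list(candidates.vectors) != list(hyper.vectors):
        raise ValueError("candidates and hyperparameters disagree on the class list")
    X = data.values if isinstance(data, ScoreMatrix) else np.asarray(data, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    M, D = hyper.M, hyper.D
    mus = np.zeros((M, D))
    sigmas = np.zeros((M, D, D))
    for m, h in enumerate(hyper.vectors):
        sigma = hyper.psi0[m] / (hyper.nu[m] - D - 1)
        mus[m], sigmas[m] = project_to_constraints(hyper.mu0[m], sigma, h)
    pi = hyper.dirichlet / hyper.dirichlet.sum()
    state = ChainState(list(hyper.vectors), mus, sigmas, pi, np.zeros(X.shape[0], int))
    state.labels = update_labels(state, X, rng)
    state.validate()
    return state


def update_labels(
    state: ChainState, X: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Redraw every H_i from its full conditional (log-sum-exp stable)."""
    n = X.shape[0]
    logp = np.empty((n, state.M))
    for m in range(state.M):
        logp[:, m] = mvn_logpdf(X, state.mus[m], state.sigmas[m])
    with np.errstate(divide="ignore"):
        logp += np.log(state.pi)
    bad = ~np.isfinite(logp.max(axis=1))
    if np.any(bad):  # total underflow: fall back to max log-density
        logger.warning("label update: %d observations underflowed", bad.sum())
        logp[bad] = np.where(
            logp[bad] == logp[bad].max(axis=1, keepdims=True), 0.0, -np.inf
        )
    logp -= logsumexp(logp, axis=1, keepdims=True)
    probs = np.exp(logp)
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n)
    return (u[:, None] > cum).sum(axis=1).astype(int)


def update_pi(
    state: ChainState, dirichlet: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate Dirichlet draw from Dir(alpha + class counts)."""
    counts = np.bincount(state.labels, minlength=state.M)
    return rng.dirichlet(np.asarray(dirichlet, dtype=float) + counts)


def _sample_truncated_mvn(
    mean: np.ndarray,
    cov: np.ndarray,
    signs: np.ndarray,
    start: np.ndarray,
    rng: np.random.Generator,
    sweeps: int,
) -> np.ndarray:
    """Orthant-truncated multivariate normal via coordinate-wise Gibbs.

    ``signs[j]`` (+1/-1) pins coordinate j to the open half-line of that
    sign.  One-dimensional blocks are exact single draws.
    """
    k = mean.shape[0]
    prec = np.linalg.inv(cov)
    x = start.copy()
    n_sweeps = 1 if k == 1 else sweeps
    for _ in range(n_sweeps):
        for j in range(k):
            cond_var = 1.0 / prec[j, j]
            others = np.delete(np.arange(k), j)
            cond_mean = mean[j] - cond_var * prec[j, others] @ (x[others] - mean[others])
            sd = np.sqrt(cond_var)
            # CDF bounds of the admissible half-line
            a = ndtr((0.0 - cond_mean) / sd)
            if signs[j] > 0:
                lo, hi = a, 1.0
            else:
                lo, hi = 0.0, a
            if hi - lo < 1e-300:  # numerically degenerate tail
                x[j] = signs[j] * max(abs(cond_mean), 1e-8) if cond_mean * signs[j] > 0 else signs[j] * 1e-8
                continue
            u = lo + (hi - lo) * rng.random()
            u = min(max(u, 1e-16), 1.0 - 1e-16)
            x[j] = cond_mean + sd * ndtri(u)
            if x[j] * signs[j] <= 0:  # guard against rounding across 0
                x[j] = signs[j] * 1e-10
    return x


def update_mu(
    state: ChainState,
    X: np.ndarray,
    hyper: Hyperparameters,
    config: ChainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw each class mean from its truncated conjugate normal posterior.

    Null coordinates stay exactly 0; the non-null block is drawn from
    N((kappa*mu0 + n_h*xbar)/(kappa + n_h), Sigma_BB/(kappa + n_h))
    restricted to the orthant sgn(mu_d) = h_d.  Classes without members
    draw from the (truncated) prior.
    """
    mus = state.mus.copy()
    for m, h in enumerate(state.vectors):
        nn = np.flatnonzero(h.nonnull)
        if nn.size == 0:
            continue
        members = state.labels == m
        n_h = int(members.sum())
        kap = hyper.kappa[m]
        mu0 = hyper.mu0[m][nn]
        sigma_bb = state.sigmas[m][np.ix_(nn, nn)]
        if n_h > 0:
            xbar = X[members][:, nn].mean(axis=0)
            post_mean = (kap * mu0 + n_h * xbar) / (kap + n_h)
        else:
            post_mean = mu0
        post_cov = sigma_bb / (kap + n_h)
        signs = np.array([h[d] for d in nn], dtype=float)
        draw = _sample_truncated_mvn(
            post_mean, post_cov, signs, mus[m][nn], rng, config.tnorm_sweeps
        )
        if np.any(draw * signs <= 0):  # pragma: no cover - guarded above
            raise RuntimeError(f"truncated mean draw failed for class {h}")
        mus[m][nn] = draw
    return mus


def update_sigma(
    state: ChainState,
    X: np.ndarray,
    hyper: Hyperparameters,
    config: ChainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """MH draw of each class covariance from the constrained-IW posterior.

    Proposes the non-null block from the unconstrained conjugate
    inverse-Wishart posterior and rejects proposals violating the sign
    indicator; valid proposals are accepted with probability 1.  Returns
    (new sigmas, per-class acceptance flags).
    """
    sigmas = state.sigmas.copy()
    accepted = np.ones(state.M, bool)
    for m, h in enumerate(state.vectors):
        nn = np.flatnonzero(h.nonnull)
        k = nn.size
        if k == 0:
            continue
        members = state.labels == m
        n_h = int(members.sum())
        mu_b = state.mus[m][nn]
        mu0_b = hyper.mu0[m][nn]
        psi = hyper.psi0[m][np.ix_(nn, nn)].copy()
        if n_h > 0:
            diff = X[members][:, nn] - mu_b
            psi += diff.T @ diff
        dmu = mu_b - mu0_b
        psi += hyper.kappa[m] * np.outer(dmu, dmu)
        df = hyper.nu[m] + n_h + 1
        psi = (psi + psi.T) / 2.0

        want = np.array([[h[r] * h[t] for t in nn] for r in nn], dtype=float)
        ok = False
        for _ in range(config.mh_max_attempts):
            prop = invwishart.rvs(df=df, scale=psi, random_state=rng)
            prop = np.atleast_2d(prop)
            off = ~np.eye(k, dtype=bool)
            if np.all(prop[off] * want[off] > 0):
                ok = True
                break
        if ok:
            block = np.zeros_like(sigmas[m])
            block[np.ix_(nn, nn)] = prop
            null = np.setdiff1d(np.arange(state.D), nn)
            block[null, null] = 1.0
            sigmas[m] = block
        else:
            accepted[m] = False
            logger.debug(
                "class %s: no sign-valid covariance proposal in %d attempts; keeping current",
                h,
                config.mh_max_attempts,
            )
    return sigmas, accepted


def mcmc_sweep(
    state: ChainState,
    X: np.ndarray,
    hyper: Hyperparameters,
    config: ChainConfig,
    rng: np.random.Generator,
) -> tuple[ChainState, np.ndarray]:
    """One full Gibbs sweep (labels, pi, mu, Sigma); returns accept flags."""
    state.labels = update_labels(state, X, rng)
    state.pi = update_pi(state, hyper.dirichlet, rng)
    state.mus = update_mu(state, X, hyper, config, rng)
    state.sigmas, accepted = update_sigma(state, X, hyper, config, rng)
    return state, accepted


def run_mcmc(
    data: ScoreMatrix | np.ndarray,
    candidates: CandidateSet,
    hyper: Hyperparameters,
    config: ChainConfig,
    start_state: Optional[ChainState] = None,
    rng: Optional[np.random.Generator] = None,
) -> PosteriorDraws:
    """Run the full chain and retain post-burn-in, thinned states.

    Identical seeds give identical draws.  A chain may be resumed by
    passing the ``start_state`` and the carried-over ``rng`` of a previous
    partial run; the resumed chain reproduces the uninterrupted one.
    """
    X = data.values if isinstance(data, ScoreMatrix) else np.asarray(data, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = (
        start_state.copy()
        if start_state is not None
        else init_chain(X, candidates, hyper, config, rng)
    )
    M, D, n = state.M, state.D, X.shape[0]
    T = config.n_retained
    mu_draws = np.empty((T, M, D))
    sigma_draws = np.empty((T, M, D, D))
    pi_draws = np.empty((T, M))
    label_draws = np.empty((T, n), dtype=np.int32)
    accept_counts = np.zeros(M)
    empty_counts = np.zeros(M)
    kept = 0
    for it in range(config.n_iter):
        try:
            state, accepted = mcmc_sweep(state, X, hyper, config, rng)
        except Exception as exc:
            raise RuntimeError(f"MCMC sweep failed at iteration {it}: {exc}") from exc
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            mu_draws[kept] = state.mus
            sigma_draws[kept] = state.sigmas
            pi_draws[kept] = state.pi
            label_draws[kept] = state.labels
            accept_counts += accepted
            empty_counts += np.bincount(state.labels, minlength=M) == 0
            kept += 1
    empty_frac = empty_counts / max(kept, 1)
    for m, h in enumerate(hyper.vectors):
        if empty_frac[m] > 0.5:
            logger.warning(
                "class %s was empty in %.0f%% of retained iterations", h, 100 * empty_frac[m]
            )
    return PosteriorDraws(
        vectors=list(hyper.vectors),
        mu=mu_draws[:kept],
        sigma=sigma_draws[:kept],
        pi=pi_draws[:kept],
        labels=label_draws[:kept],
        seed=config.seed,
        config=config,
        sigma_accept_rate=accept_counts / max(kept, 1),
        empty_fraction=empty_frac,
    )


def posterior_summaries(draws: PosteriorDraws) -> tuple[MixtureModel, np.ndarray]:
    """Posterior-mean model (projected to constraints) and memberships.

    The membership matrix row i gives, per class, the fraction of retained
    iterations in which observation i carried that class's label; rows sum
    to 1 exactly.
    """
    if draws.T < 1:
        raise ValueError("no retained draws")
    classes = []
    for m, h in enumerate(draws.vectors):
        mu = draws.mu[:, m].mean(axis=0)
        sigma = draws.sigma[:, m].mean(axis=0)
        mu, sigma = project_to_constraints(mu, sigma, h)
        classes.append(ConstrainedClassParams(h, mu, sigma))
    pi = draws.pi.mean(axis=0)
    model = MixtureModel(classes=classes, pi=pi / pi.sum(), n=draws.n)
    return model, draws.membership()
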