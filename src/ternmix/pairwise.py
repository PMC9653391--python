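"""Step 1 — penalized constrained bivariate mixtures for every condition pair.

Each unordered pair of conditions (r, t) is fit with a 9-class constrained
bivariate normal mixture, one class per two-dimensional association vector
in {-1,0,1}^2.  A log-type penalty on the mixing weights shrinks the
weights of unsupported classes; weights falling below an elimination
threshold are set to exactly zero and the class is dropped, so the fit
performs model selection over the pairwise class space.  The surviving
class sets drive the graph enumeration of D-dimensional candidates, and
the per-pair parameter estimates are recycled as empirical-Bayes prior
hyperparameters in the final step.

The EM here is a generalized EM: the constrained M-step projects each
class onto its feasible set (null dimensions hard-fixed, signed means
clipped to the open half-line, covariance signs enforced), and a
backtracking safeguard guarantees the penalized objective never decreases
along the recorded trace.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import (
    SIGN_MARGIN,
    AssociationVector,
    ConstrainedClassParams,
    ScoreMatrix,
    validate_constraints,
    implied_vector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PAIRWISE_VECTORS",
    "PairwiseClassSet",
    "PairwiseFit",
    "PenaltySettings",
    "enumerate_pairwise_classes",
    "fit_pairwise",
    "fit_all_pairs",
]

#: the 9 two-dimensional association vectors, lexicographic with -1 < 0 < 1
PAIRWISE_VECTORS: tuple[AssociationVector, ...] = tuple(
    AssociationVector((a, b)) for a, b in itertools.product((-1, 0, 1), repeat=2)
)


def enumerate_pairwise_classes() -> list[AssociationVector]:
    """All 9 possible pairwise association vectors, in deterministic order."""
    return list(PAIRWISE_VECTORS)


@dataclass
class PairwiseClassSet:
    """Retained two-dimensional vectors for one condition pair (r < t)."""

    pair: tuple[int, int]
    vectors: list[AssociationVector]

    def __post_init__(self) -> None:
        r, t = self.pair
        if not r < t:
            raise ValueError("pair must satisfy r < t")
        allowed = set(PAIRWISE_VECTORS)
        if any(v not in allowed for v in self.vectors):
            raise ValueError("vectors must be two-dimensional association vectors")

    def as_set(self) -> set[tuple[int, int]]:
        return {v.labels for v in self.vectors}


@dataclass
class PenaltySettings:
    """Tuning knobs for the penalized pairwise model selection.

    ``lambda_grid`` is on the scale of expected class member counts: a
    class supported by fewer than roughly lambda observations is shrunk
    away.  ``epsilon`` smooths the log penalty near zero.  The elimination
    threshold defaults to 1e-3 times the initial class count (9).
    ``var_floor`` bounds fitted non-null variances below, preventing
    signed components from collapsing into spikes sharper than the fixed
    standard-normal null.
    """

    lambda_grid: tuple[float, ...] = (5.0, 20.0, 80.0)
    epsilon: float = 1e-3
    elimination_threshold: Optional[float] = None  # default 1e-3 * 9
    max_iter: int = 300
    tol: float = 1e-7
    restarts: int = 1
    seed: int = 0
    sign_margin: float = SIGN_MARGIN
    var_floor: float = 1.0
    mean_zero_tol: float = 0.1  # collapse-to-null relabelling tolerance

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lambda_grid):
            raise ValueError("lambda grid entries must be positive")
        if self.epsilon <= 0 or self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("epsilon, tol, max_iter must be positive")
        thr = self.threshold
        if not (0.0 < thr < 1.0):
            raise ValueError("elimination threshold must lie in (0, 1)")

    @property
    def threshold(self) -> float:
        return (
            self.elimination_threshold
            if self.elimination_threshold is not None
            else 1e-3 * len(PAIRWISE_VECTORS)
        )


@dataclass
class PairwiseFit:
    """Selected classes, parameters and responsibilities for one pair."""

    class_set: PairwiseClassSet
    params: list[ConstrainedClassParams]
    weights: np.ndarray
    responsibilities: np.ndarray
    loglik_trace: list[float]
    converged: bool
    loglik: float = 0.0  # unpenalized, at the final parameters
    lam: float = float("nan")
    bic: float = float("nan")

    @property
    def M(self) -> int:
        return len(self.params)

    @property
    def vectors(self) -> list[AssociationVector]:
        return self.class_set.vectors


# ---------------------------------------------------------------------------
# internal EM machinery (arrays of 2-D class parameters)


def _bivariate_logpdf(X: np.ndarray, mus: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Log density of each row of X under each 2-D class: returns (n, M)."""
    a = sigmas[:, 0, 0]
    b = sigmas[:, 0, 1]
    c = sigmas[:, 1, 1]
    det = a * c - b * b
    dx = X[:, 0:1] - mus[None, :, 0]
    dy = X[:, 1:2] - mus[None, :, 1]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def _penalty(pi: np.ndarray, lam: float, eps: float) -> float:
    pos = pi[pi > 0]
    return float(lam * np.sum(np.log((eps + pos) / eps)))


def _objective(
    X: np.ndarray, mus: np.ndarray, sigmas: np.ndarray, pi: np.ndarray,
    lam: float, eps: float,
) -> tuple[float, float, np.ndarray]:
    """(penalized objective, unpenalized loglik, responsibilities)."""
    logp = _bivariate_logpdf(X, mus, sigmas)
    with np.errstate(divide="ignore"):
        logw = logp + np.log(pi)
    mx = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - mx)
    tot = w.sum(axis=1, keepdims=True)
    ll = float((np.log(tot) + mx).sum())
    return ll - _penalty(pi, lam, eps), ll, w / tot


def _weight_update(
    nm: np.ndarray, pi_old: np.ndarray, lam: float, eps: float
) -> np.ndarray:
    """Exact maximizer of the MM surrogate for the penalized weight step."""
    c = lam / (eps + pi_old)
    n = nm.sum()
    lo = -c.min() + 1e-12

    def f(kappa: float) -> float:
        return float(np.sum(nm / (kappa + c)) - 1.0)

    hi = n + c.max() + 1.0
    if f(lo) < 0:  # all classes vanishing; keep proportions
        return nm / n
    kappa = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    pi = nm / (kappa + c)
    return pi / pi.sum()


def _project_class_2d(
    h: AssociationVector,
    mean: np.ndarray,
    cov: np.ndarray,
    margin: float,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Constrained M-step projection for one 2-D class."""
    mu = mean.copy()
    S = cov.copy()
    for d in range(2):
        if h[d] == 0:
            mu[d] = 0.0
            S[d, d] = 1.0
        else:
            if h[d] * mu[d] < margin:
                mu[d] = h[d] * margin
            S[d, d] = max(S[d, d], var_floor)
    if h[0] == 0 or h[1] == 0:
        S[0, 1] = S[1, 0] = 0.0
    else:
        want = h[0] * h[1]
        if S[0, 1] * want <= 0:
            S[0, 1] = S[1, 0] = want * margin
        cap = 0.995 * np.sqrt(S[0, 0] * S[1, 1])
        if abs(S[0, 1]) > cap:
            S[0, 1] = S[1, 0] = np.sign(S[0, 1]) * cap
    return mu, S


def _init_class_params(
    vectors: Sequence[AssociationVector],
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overfit start: one class per vector, means on the +-2 pattern."""
    M = len(vectors)
    mus = np.zeros((M, 2))
    sigmas = np.tile(np.eye(2), (M, 1, 1))
    for m, h in enumerate(vectors):
        for d in range(2):
            mus[m, d] = 2.0 * h[d]
        if h[0] != 0 and h[1] != 0:
            rho = 0.5 * h[0] * h[1]
            sigmas[m, 0, 1] = sigmas[m, 1, 0] = rho
    if rng is not None:
        jitter = rng.normal(0.0, 0.5, size=(M, 2))
        for m, h in enumerate(vectors):
            for d in range(2):
                if h[d] != 0:
                    mus[m, d] = h[d] * max(h[d] * (mus[m, d] + jitter[m, d]), 0.5)
    return mus, sigmas


def _run_em(
    X: np.ndarray,
    lam: float,
    settings: PenaltySettings,
    rng: Optional[np.random.Generator],
) -> tuple[list[AssociationVector], np.ndarray, np.ndarray, np.ndarray, list[float], bool, float]:
    """One penalized EM run; returns surviving classes and their fit."""
    eps = settings.epsilon
    margin = settings.sign_margin
    thr = settings.threshold
    vectors = list(PAIRWISE_VECTORS)
    mus, sigmas = _init_class_params(vectors, rng)
    pi = np.full(len(vectors), 1.0 / len(vectors))

    f_old, ll, resp = _objective(X, mus, sigmas, pi, lam, eps)
    trace = [f_old]
    converged = False
    for _ in range(settings.max_iter):
        nm = resp.sum(axis=0)
        # penalized weight update, with exact-zero thresholding
        pi_new = _weight_update(nm, pi, lam, eps)
        pi_new = np.where(pi_new < thr, 0.0, pi_new)
        if pi_new.sum() == 0.0:
            raise RuntimeError(
                "no pairwise class survives the elimination threshold; "
                "relax the threshold or shrink lambda"
            )
        pi_new = pi_new / pi_new.sum()
        # constrained Gaussian updates
        mus_new = mus.copy()
        sigmas_new = sigmas.copy()
        for m, h in enumerate(vectors):
            if pi_new[m] == 0.0 or nm[m] < 1e-9:
                continue
            w = resp[:, m]
            mean = w @ X / nm[m]
            diff = X - mean
            cov = (diff.T * w) @ diff / nm[m]
            mus_new[m], sigmas_new[m] = _project_class_2d(
                h, mean, cov, margin, settings.var_floor
            )

        f_new, ll, resp_new = _objective(X, mus_new, sigmas_new, pi_new, lam, eps)
        if f_new < f_old - 1e-10:
            # backtrack toward the previous iterate (class set unchanged)
            accepted = False
            for alpha in (0.5, 0.25, 0.125):
                pi_b = alpha * np.where(pi_new > 0, pi_new, 0.0) + (1 - alpha) * pi
                pi_b = pi_b / pi_b.sum()
                mus_b = alpha * mus_new + (1 - alpha) * mus
                sig_b = alpha * sigmas_new + (1 - alpha) * sigmas
                for m, h in enumerate(vectors):
                    mus_b[m], sig_b[m] = _project_class_2d(
                        h, mus_b[m], sig_b[m], margin, settings.var_floor
                    )
                f_b, ll_b, resp_b = _objective(X, mus_b, sig_b, pi_b, lam, eps)
                if f_b >= f_old - 1e-10:
                    pi_new, mus_new, sigmas_new = pi_b, mus_b, sig_b
                    f_new, ll, resp_new = f_b, ll_b, resp_b
                    accepted = True
                    break
            if not accepted:
                converged = True
                break

        # drop eliminated classes permanently
        if np.any(pi_new == 0.0):
            keep = pi_new > 0.0
            vectors = [v for v, k in zip(vectors, keep) if k]
            pi_new = pi_new[keep]
            mus_new = mus_new[keep]
            sigmas_new = sigmas_new[keep]
            resp_new = resp_new[:, keep]
            resp_new = resp_new / resp_new.sum(axis=1, keepdims=True)
        pi, mus, sigmas, resp = pi_new, mus_new, sigmas_new, resp_new
        trace.append(f_new)
        if abs(f_new - f_old) < settings.tol * (1.0 + abs(f_old)):
            converged = True
            f_old = f_new
            break
        f_old = f_new
    return vectors, mus, sigmas, pi, trace, converged, ll


def _merge_collapsed(
    vectors: list[AssociationVector],
    mus: np.ndarray,
    sigmas: np.ndarray,
    pi: np.ndarray,
    zero_tol: float,
) -> tuple[list[AssociationVector], np.ndarray, np.ndarray, np.ndarray]:
    """Resolve components that collapsed onto another label.

    A signed dimension whose fitted mean sits at ~0 supports the null
    label; such a class is merged into the class its parameters imply (or
    relabelled if that class is absent).  Genuinely identical duplicates
    merge into the lexicographically smaller vector.
    """
    order = list(range(len(vectors)))
    keep: dict[AssociationVector, int] = {}
    out_vec: list[AssociationVector] = []
    out_idx: list[int] = []
    weights: list[float] = []
    for m in order:
        h = vectors[m]
        implied = implied_vector(mus[m], h, zero_tol)
        if implied in keep:
            weights[keep[implied]] += pi[m]
            continue
        if implied != h:
            # relabel: project parameters onto the implied pattern
            from .model import project_to_constraints

            mus[m], sigmas[m] = project_to_constraints(mus[m], sigmas[m], implied)
        keep[implied] = len(out_vec)
        out_vec.append(implied)
        out_idx.append(m)
        weights.append(float(pi[m]))
    # sort lexicographically for deterministic output
    srt = sorted(range(len(out_vec)), key=lambda i: out_vec[i])
    vec_s = [out_vec[i] for i in srt]
    mus_s = mus[[out_idx[i] for i in srt]]
    sig_s = sigmas[[out_idx[i] for i in srt]]
    pi_s = np.array([weights[i] for i in srt])
    return vec_s, mus_s, sig_s, pi_s / pi_s.sum()


def _free_params(vectors: Sequence[AssociationVector]) -> int:
    k = max(len(vectors) - 1, 0)  # mixing weights
    for h in vectors:
        nn = sum(1 for a in h if a != 0)
        k += 2 * nn  # means + variances on non-null dims
        if nn == 2:
            k += 1  # covariance
    return k


def fit_pairwise(
    data2: np.ndarray, settings: Optional[PenaltySettings] = None,
    pair: tuple[int, int] = (0, 1),
) -> PairwiseFit:
    """Fit the penalized 9-class constrained mixture to an n x 2 matrix.

    The penalty strength is chosen by BIC over ``settings.lambda_grid``;
    within each strength the best of ``settings.restarts`` EM runs (the
    first from the canonical overfit start, the rest jittered) is kept.
    """
    settings = settings or PenaltySettings()
    X = np.asarray(data2, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("data2 must be an n x 2 matrix")
    if X.shape[0] <= 20:
        raise ValueError("pairwise fitting needs more than 20 observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("data2 must be finite")

    n = X.shape[0]
    best: Optional[tuple] = None
    for lam in settings.lambda_grid:
        for restart in range(max(settings.restarts, 1)):
            rng = (
                None
                if restart == 0
                else np.random.default_rng(
                    np.random.SeedSequence([settings.seed, restart]).generate_state(1)[0]
                )
            )
            try:
                vectors, mus, sigmas, pi, trace, converged, ll = _run_em(
                    X, lam, settings, rng
                )
            except RuntimeError:
                continue
            bic = -2.0 * ll + _free_params(vectors) * np.log(n)
            cand = (bic, lam, vectors, mus, sigmas, pi, trace, converged, ll)
            if best is None or bic < best[0] - 1e-9:
                best = cand
    if best is None:
        raise RuntimeError(
            "no pairwise class survived at any penalty strength; "
            "relax the elimination threshold"
        )
    bic, lam, vectors, mus, sigmas, pi, trace, converged, ll = best
    if not converged:
        logger.warning("pairwise EM for pair %s did not converge", pair)

    vectors, mus, sigmas, pi = _merge_collapsed(
        vectors, mus, sigmas, pi, settings.mean_zero_tol
    )
    # final E-step on the cleaned class set
    logp = _bivariate_logpdf(X, mus, sigmas)
    with np.errstate(divide="ignore"):
        logw = logp + np.log(pi)
    mx = logw.max(axis=1, keepdims=True)
    w = np.exp(logw - mx)
    resp = w / w.sum(axis=1, keepdims=True)
    ll_final = float((np.log(w.sum(axis=1)) + mx[:, 0]).sum())

    params = [
        ConstrainedClassParams(h, mus[m], sigmas[m]) for m, h in enumerate(vectors)
    ]
    for p in params:
        bad = validate_constraints(p)
        if bad:  # pragma: no cover - projection should prevent this
            raise RuntimeError(f"fitted class {p.h} violates constraints: {bad}")
    return PairwiseFit(
        class_set=PairwiseClassSet(pair, vectors),
        params=params,
        weights=pi,
        responsibilities=resp,
        loglik_trace=trace,
        converged=converged,
        loglik=ll_final,
        lam=lam,
        bic=bic,
    )


def pair_seed(master_seed: int, r: int, t: int) -> int:
    """Deterministic per-pair seed independent of processing order."""
    return int(np.random.SeedSequence([master_seed, r, t]).generate_state(1)[0] % (2**31))


def fit_all_pairs(
    data: ScoreMatrix, settings: Optional[PenaltySettings] = None
) -> dict[tuple[int, int], PairwiseFit]:
    """Fit every unordered condition pair; returns {(r, t): fit, r < t}."""
    settings = settings or PenaltySettings()
    if data.D < 2:
        raise ValueError("need at least 2 conditions")
    battery: dict[tuple[int, int], PairwiseFit] = {}
    for r in range(data.D - 1):
        for t in range(r + 1, data.D):
            s = replace(settings, seed=pair_seed(settings.seed, r, t))
            try:
                battery[(r, t)] = fit_pairwise(data.pair(r, t), s, pair=(r, t))
            except Exception as exc:
                raise RuntimeError(f"pairwise fit failed for pair ({r}, {t}): {exc}") from exc
            logger.info(
                "pair (%d, %d): %d classes retained", r, t, battery[(r, t)].M
            )
    return battery
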