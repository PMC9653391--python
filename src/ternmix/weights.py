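"""Step 3 — prior class weights by pairwise-label concordance.

For every observation and every condition pair, one pairwise class label
is sampled from the posterior responsibilities of the pairwise fit.  The
prior weight of a candidate D-dimensional class is then the normalized
proportion of observations whose sampled pairwise labels agree with the
candidate's label pairs for at least C(D,2) - delta of the pairs, where
the tolerance delta controls the permitted discordance.  Candidates with
n * alpha <= D are removed (such classes are unlikely to have members and
their inverse-Wishart prior would be singular), and the surviving
pairwise parameter estimates are aggregated into empirical-Bayes
hyperparameters for the final D-dimensional model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Optional

import numpy as np

from .labelgraph import CandidateSet
from .model import (
    AssociationVector,
    nearest_positive_definite,
    project_to_constraints,
)
from .pairwise import PairwiseFit

logger = logging.getLogger(__name__)

__all__ = [
    "SampledLabels",
    "AlphaEstimate",
    "Hyperparameters",
    "sample_pairwise_labels",
    "estimate_alpha",
    "select_delta",
    "delta_search_range",
    "prune_by_alpha",
    "assemble_hyperparameters",
]


def _code(a1: int, a2: int) -> int:
    """Encode a pairwise label in 0..8."""
    return 3 * (a1 + 1) + (a2 + 1)


@dataclass
class SampledLabels:
    """One sampled pairwise label per observation per pair.

    ``codes[(r, t)]`` is a length-n integer array of encoded labels
    (0..8, via 3*(a1+1) + (a2+1)).
    """

    n: int
    D: int
    codes: dict[tuple[int, int], np.ndarray]
    seed: Optional[int] = None
    n_draws: int = 1  # R repeated draws averaged into alpha, metadata only

    @property
    def n_pairs(self) -> int:
        return len(self.codes)


@dataclass
class AlphaEstimate:
    """Estimated prior class weights with their concordance counts."""

    vectors: list[AssociationVector]
    alpha: np.ndarray
    delta: int
    counts: np.ndarray  # per-candidate concordant-observation counts

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.alpha < 0):
            raise ValueError("alpha entries must be nonnegative")


@dataclass
class Hyperparameters:
    """Empirical-Bayes prior settings for the D-dimensional model.

    Per retained class h: prior mean mu0 (sign-compatible with h), prior
    scale Psi0 (symmetric PD, scaled so the implied inverse-Wishart mean
    matches the aggregated pairwise covariance), and kappa = nu =
    max(n * alpha_h, D + 2).  The Dirichlet weights are on the counts
    scale, alpha_dir = n * alpha_h.
    """

    vectors: list[AssociationVector]
    mu0: np.ndarray  # (M, D)
    psi0: np.ndarray  # (M, D, D)
    kappa: np.ndarray  # (M,)
    nu: np.ndarray  # (M,)
    dirichlet: np.ndarray  # (M,)

    def __post_init__(self) -> None:
        M = len(self.vectors)
        D = self.vectors[0].D if M else 0
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(M, D)
        self.psi0 = np.asarray(self.psi0, dtype=float).reshape(M, D, D)
        for arr_name in ("kappa", "nu", "dirichlet"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name), dtype=float).reshape(M))
        if np.any(self.nu <= D + 1):
            raise ValueError("nu must exceed D + 1 for every class")

    @property
    def M(self) -> int:
        return len(self.vectors)

    @property
    def D(self) -> int:
        return self.vectors[0].D


def sample_pairwise_labels(
    battery: Mapping[tuple[int, int], PairwiseFit], seed: int
) -> SampledLabels:
    """Draw one pairwise class label per observation per pair.

    Each observation's label for pair (r, t) is a categorical draw over
    that pair's retained classes with probabilities equal to the posterior
    responsibilities.  Reproducible given the seed.
    """
    if not battery:
        raise ValueError("empty pairwise battery")
    pairs = sorted(battery)
    n = battery[pairs[0]].responsibilities.shape[0]
    D = max(t for _, t in pairs) + 1
    codes: dict[tuple[int, int], np.ndarray] = {}
    for pair in pairs:
        fit = battery[pair]
        resp = fit.responsibilities
        if resp is None or resp.shape[0] != n:
            raise ValueError(f"pair {pair}: missing or misshaped responsibilities")
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, pair[0], pair[1]]).generate_state(1)[0]
        )
        cum = np.cumsum(resp, axis=1)
        cum[:, -1] = 1.0
        u = rng.random(n)
        idx = (u[:, None] > cum).sum(axis=1)
        vec_codes = np.array([_code(*v.labels) for v in fit.vectors])
        codes[pair] = vec_codes[idx]
    return SampledLabels(n=n, D=D, codes=codes, seed=seed)


def _concordance_counts(
    samples: SampledLabels, candidates: CandidateSet, delta: int
) -> np.ndarray:
    """Per-candidate count of observations concordant up to tolerance delta."""
    pairs = sorted(samples.codes)
    P = len(pairs)
    label_mat = np.stack([samples.codes[p] for p in pairs], axis=1)  # (n, P)
    counts = np.empty(len(candidates.vectors))
    for m, h in enumerate(candidates.vectors):
        want = np.array([_code(h[r], h[t]) for r, t in pairs])
        matches = (label_mat == want).sum(axis=1)
        counts[m] = int(np.count_nonzero(matches >= P - delta))
    return counts


def estimate_alpha(
    samples: SampledLabels, candidates: CandidateSet, delta: int
) -> AlphaEstimate:
    """Normalized concordant-observation proportions per candidate class."""
    n_pairs = comb(samples.D, 2)
    if not (0 <= delta <= n_pairs):
        raise ValueError(f"delta must lie in [0, C(D,2)] = [0, {n_pairs}]")
    if len(candidates.vectors) == 0:
        raise ValueError("candidate set is empty")
    counts = _concordance_counts(samples, candidates, delta)
    denom = counts.sum()
    if denom == 0:
        raise ValueError(
            "no observation is concordant with any candidate at this delta; "
            "increase delta"
        )
    return AlphaEstimate(
        vectors=list(candidates.vectors),
        alpha=counts / denom,
        delta=delta,
        counts=counts,
    )


def delta_search_range(n_pairs: int, separation_hint: str) -> tuple[int, int]:
    """Integer search range for the concordance tolerance.

    Well-separated data search delta in [0, 0.15 * C(D,2)); weakly
    separated data in [0.15 * C(D,2), 0.30 * C(D,2)] (both inclusive of
    the integers inside the stated real intervals).
    """
    if separation_hint == "well_separated":
        hi = int(np.floor(0.15 * n_pairs))
        if hi == 0.15 * n_pairs:  # open right endpoint
            hi -= 1
        return 0, max(hi, 0)
    if separation_hint == "weakly_separated":
        return int(np.ceil(0.15 * n_pairs)), int(np.floor(0.30 * n_pairs))
    raise ValueError("separation_hint must be well_separated or weakly_separated")


def select_delta(
    samples: SampledLabels,
    candidates: CandidateSet,
    separation_hint: str = "well_separated",
    c: int = 2,
) -> int:
    """Pick the concordance tolerance by the plateau heuristic.

    Within the hint's search range the smallest delta is returned for
    which the class count surviving the n*alpha > D rule stays constant
    over delta .. delta + c.  Without a plateau, the range endpoint is
    returned with a warning.
    """
    n_pairs = comb(samples.D, 2)
    lo, hi = delta_search_range(n_pairs, separation_hint)
    n, D = samples.n, samples.D

    def survivors(d: int) -> int:
        try:
            a = estimate_alpha(samples, candidates, d)
        except ValueError:
            return 0
        return int(np.count_nonzero(n * a.alpha > D))

    cache: dict[int, int] = {}

    def M(d: int) -> int:
        if d not in cache:
            cache[d] = survivors(min(d, n_pairs))
        return cache[d]

    for delta in range(lo, hi + 1):
        m0 = M(delta)
        if m0 > 0 and all(M(delta + j) == m0 for j in range(1, c + 1)):
            return delta
    warnings.warn(
        f"no stable plateau of surviving class counts in [{lo}, {hi}]; "
        f"returning the endpoint {hi}"
    )
    return hi


def prune_by_alpha(
    candidates: CandidateSet, alpha: AlphaEstimate, n: int, D: int
) -> tuple[CandidateSet, AlphaEstimate]:
    """Remove classes with n * alpha <= D; renormalize over survivors."""
    keep = n * alpha.alpha > D
    if not np.any(keep):
        raise ValueError(
            "every candidate has n * alpha <= D; nothing would remain "
            "(consider a larger delta or more data)"
        )
    vectors = [v for v, k in zip(alpha.vectors, keep) if k]
    a = alpha.alpha[keep]
    pruned = CandidateSet(vectors=vectors, pruned=True)
    est = AlphaEstimate(
        vectors=vectors, alpha=a / a.sum(), delta=alpha.delta, counts=alpha.counts[keep]
    )
    logger.info("mixing-weight pruning: %d -> %d classes", len(alpha.vectors), len(vectors))
    return pruned, est


def assemble_hyperparameters(
    battery: Mapping[tuple[int, int], PairwiseFit],
    candidates: CandidateSet,
    alpha: AlphaEstimate,
    n: int,
    fallback_mean: float = 2.0,
    fallback_corr: float = 0.5,
) -> Hyperparameters:
    """Aggregate pairwise estimates into per-class prior hyperparameters.

    Each dimension of a class's prior mean is the unweighted average, over
    the D-1 pairwise fits involving that dimension, of the matching
    pairwise class's mean component.  The prior scale is assembled from
    matching pairwise variances (averaged) and covariances (each
    off-diagonal is estimated by exactly one pair), repaired to the
    nearest symmetric PD matrix, and scaled so the implied inverse-Wishart
    mean Psi0 / (nu - D - 1) reproduces the assembled covariance.  Classes
    without a matching pairwise class in some pair fall back to
    constraint-respecting defaults with a logged warning.
    """
    if list(candidates.vectors) != list(alpha.vectors):
        raise ValueError("candidates and alpha must describe the same classes")
    D = candidates.D
    pairs = sorted(battery)
    M = len(candidates.vectors)
    mu0 = np.zeros((M, D))
    psi0 = np.zeros((M, D, D))
    kappa = np.zeros(M)
    nu = np.zeros(M)

    # index pairwise classes by label for fast matching
    by_pair: dict[tuple[int, int], dict[tuple[int, int], int]] = {
        p: {f.h.labels: i for i, f in enumerate(battery[p].params)} for p in pairs
    }

    for m, h in enumerate(candidates.vectors):
        mean_acc = np.zeros(D)
        mean_cnt = np.zeros(D)
        var_acc = np.zeros(D)
        var_cnt = np.zeros(D)
        cov = np.zeros((D, D))
        for (r, t) in pairs:
            sub = (h[r], h[t])
            idx = by_pair[(r, t)].get(sub)
            if idx is None:
                continue
            prm = battery[(r, t)].params[idx]
            mean_acc[r] += prm.mu[0]
            mean_acc[t] += prm.mu[1]
            mean_cnt[r] += 1
            mean_cnt[t] += 1
            var_acc[r] += prm.sigma[0, 0]
            var_acc[t] += prm.sigma[1, 1]
            var_cnt[r] += 1
            var_cnt[t] += 1
            cov[r, t] = cov[t, r] = prm.sigma[0, 1]

        missing = [d for d in range(D) if h[d] != 0 and mean_cnt[d] == 0]
        if missing:
            logger.warning(
                "class %s: no matching pairwise class covers dimensions %s; "
                "using constraint-respecting defaults",
                h,
                missing,
            )
        mean = np.where(mean_cnt > 0, mean_acc / np.maximum(mean_cnt, 1), 0.0)
        var = np.where(var_cnt > 0, var_acc / np.maximum(var_cnt, 1), 1.0)
        for d in missing:
            mean[d] = fallback_mean * h[d]
            var[d] = 1.0
        S = cov.copy()
        np.fill_diagonal(S, var)
        for r in range(D):
            for t in range(r + 1, D):
                if h[r] != 0 and h[t] != 0 and S[r, t] * h[r] * h[t] <= 0:
                    S[r, t] = S[t, r] = (
                        h[r] * h[t] * fallback_corr * np.sqrt(S[r, r] * S[t, t])
                        if (r in missing or t in missing or cov[r, t] == 0)
                        else h[r] * h[t] * 1e-6
                    )
        mean, S = project_to_constraints(mean, S, h)
        nn = np.flatnonzero(h.nonnull)
        if nn.size:
            S[np.ix_(nn, nn)] = nearest_positive_definite(S[np.ix_(nn, nn)])
            mean, S = project_to_constraints(mean, S, h)

        kappa[m] = nu[m] = max(n * alpha.alpha[m], D + 2)
        mu0[m] = mean
        psi0[m] = S * (nu[m] - D - 1)

    return Hyperparameters(
        vectors=list(candidates.vectors),
        mu0=mu0,
        psi0=psi0,
        kappa=kappa,
        nu=nu,
        dirichlet=n * alpha.alpha,
    )
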