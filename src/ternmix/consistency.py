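"""Sign-aware generalized partial-conjunction tests from posterior draws.

For each observation the retained MCMC label draws induce posterior class
membership probabilities.  The sign-aware statistic asks whether at least
``u`` of the ``D`` conditions carry the *same* label (+1, 0, or -1):

    P^{u/D+} = posterior mass of classes with >= u entries equal to +1
    P^{u/D0} = posterior mass of classes with >= u entries equal to  0
    P^{u/D-} = posterior mass of classes with >= u entries equal to -1
    P^{u/D}  = max of the three

An observation is declared consistent when P^{u/D} exceeds a confidence
threshold b >= 0.5.  The classical partial-conjunction hypothesis (at
least u of D effects non-null, signs ignored) is exposed separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .gibbs import PosteriorDraws

__all__ = [
    "ConsistencyResult",
    "consistency_stats",
    "sign_aware_test",
    "partial_conjunction_test",
    "call_consistent_vs_differential",
]

_DIRECTIONS = ("+", "0", "-")


@dataclass
class ConsistencyResult:
    """Per-observation sign-aware consistency statistics."""

    p_plus: np.ndarray
    p_zero: np.ndarray
    p_minus: np.ndarray
    u: int
    b: Optional[float] = None

    @property
    def p(self) -> np.ndarray:
        """P^{u/D}: the max over the three directional components."""
        return np.maximum(self.p_plus, np.maximum(self.p_zero, self.p_minus))

    @property
    def dominant(self) -> np.ndarray:
        """Dominant direction per observation; ties break +, 0, -."""
        stacked = np.stack([self.p_plus, self.p_zero, self.p_minus])
        return np.array(_DIRECTIONS)[stacked.argmax(axis=0)]

    def reject(self, b: float) -> np.ndarray:
        if b < 0.5:
            raise ValueError("confidence threshold b must be at least 0.5")
        return self.p > b


def _class_indicators(draws: PosteriorDraws, u: int) -> dict[str, np.ndarray]:
    counts = {lab: np.zeros(draws.M, bool) for lab in (-1, 0, 1)}
    for m, h in enumerate(draws.vectors):
        for lab in (-1, 0, 1):
            counts[lab][m] = h.count(lab) >= u
    return counts


def consistency_stats(draws: PosteriorDraws, u: int) -> ConsistencyResult:
    """The three directional components of the sign-aware statistic.

    Each is the fraction of retained iterations in which the observation's
    sampled class has at least ``u`` entries of the given label.
    """
    if draws.T < 1:
        raise ValueError("draws are empty")
    if not (1 <= u <= draws.D):
        raise ValueError(f"u must lie in [1, D] = [1, {draws.D}]")
    F = draws.membership()  # (n, M)
    ind = _class_indicators(draws, u)
    return ConsistencyResult(
        p_plus=F @ ind[1].astype(float),
        p_zero=F @ ind[0].astype(float),
        p_minus=F @ ind[-1].astype(float),
        u=u,
    )


def sign_aware_test(draws: PosteriorDraws, u: int, b: float) -> np.ndarray:
    """Reject (declare sign-consistent) iff P^{u/D} > b, b >= 0.5."""
    if b < 0.5:
        raise ValueError("confidence threshold b must be at least 0.5")
    return consistency_stats(draws, u).reject(b)


def partial_conjunction_test(draws: PosteriorDraws, u: int, b: float) -> np.ndarray:
    """Classical partial conjunction: >= u non-null entries, signs ignored."""
    if b < 0.5:
        raise ValueError("confidence threshold b must be at least 0.5")
    if not (1 <= u <= draws.D):
        raise ValueError(f"u must lie in [1, D] = [1, {draws.D}]")
    F = draws.membership()
    nonnull = np.array(
        [sum(1 for a in h if a != 0) >= u for h in draws.vectors], dtype=float
    )
    return (F @ nonnull) > b


def call_consistent_vs_differential(
    draws: PosteriorDraws, b: float = 0.5
) -> np.ndarray:
    """Lineage-style call: consistent iff P^{D/D} > b, else differential.

    A feature is consistently expressed when it almost surely belongs to a
    constant-label class (all +1, all 0, or all -1 across conditions);
    every other feature is called differential.
    """
    stats = consistency_stats(draws, u=draws.D)
    flags = stats.reject(b)
    return np.where(flags, "consistent", "differential")
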