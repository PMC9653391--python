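"""Seeded generators of multi-condition Z-score data from constrained mixtures.

Three study regimes are provided as templates, emulating common
multi-condition designs:

1. positive-only ChIP-seq-like signals (n = 15,000, D = 18) — labels in
   {0, 1} only, signal means positive;
2. signed differential-analysis Z-scores (n = 15,000, D = 11) — labels in
   {-1, 0, 1}, both directions present;
3. lineage RNA-seq-like signals (n = 21,303, D = 5) with two replicates
   per condition at within-condition correlation 0.96, and a rounded
   2**X pseudocount transform for count-based callers.

The class parameters of the templates are representative defaults
(signal means of magnitude 2-4, within-class correlations 0.3-0.7), not
estimates from any particular dataset; users can substitute their own
class tables.  The module also houses the sign-aware precision/recall
evaluator used to score consistency calls against a planted truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import (
    AssociationVector,
    ConstrainedClassParams,
    MixtureModel,
    ScoreMatrix,
    project_to_constraints,
    validate_constraints,
)

__all__ = [
    "SimulationSpec",
    "SimulatedData",
    "PRFResult",
    "sample_from_mixture",
    "make_replicates",
    "to_pseudocounts",
    "evaluate_sign_aware_prf",
    "preset_regimes",
    "build_classes",
    "well_separated_spec",
]


@dataclass
class SimulationSpec:
    """Generating mixture, sample size and regime flags for one simulation."""

    classes: list[ConstrainedClassParams]
    weights: np.ndarray
    n: int
    seed: int = 0
    replicate_rho: Optional[float] = None
    positive_only: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.classes) != self.weights.shape[0]:
            raise ValueError("one weight per class required")
        if abs(self.weights.sum() - 1.0) > 1e-10 or np.any(self.weights < 0):
            raise ValueError("weights must form a probability vector")
        for cls in self.classes:
            bad = validate_constraints(cls)
            if bad:
                raise ValueError(f"class {cls.h} violates constraints: {bad}")
        if self.positive_only and any(
            cls.h.count(-1) > 0 for cls in self.classes
        ):
            raise ValueError("positive-only regime forbids classes with -1 labels")
        if self.replicate_rho is not None and not (0.0 <= self.replicate_rho < 1.0):
            raise ValueError("replicate correlation must lie in [0, 1)")

    @property
    def D(self) -> int:
        return self.classes[0].D

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def vectors(self) -> list[AssociationVector]:
        return [c.h for c in self.classes]

    def model(self) -> MixtureModel:
        return MixtureModel(classes=self.classes, pi=self.weights)


@dataclass
class SimulatedData:
    """Simulated score matrix with its planted class labels."""

    scores: ScoreMatrix
    labels: np.ndarray  # (n,) index into spec.classes
    spec: SimulationSpec

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if np.any(self.labels < 0) or np.any(self.labels >= self.spec.M):
            raise ValueError("labels must index into spec classes")

    @property
    def true_vectors(self) -> list[AssociationVector]:
        return [self.spec.vectors[k] for k in self.labels]


def sample_from_mixture(spec: SimulationSpec) -> SimulatedData:
    """Draw n i.i.d. rows: class by weight, then the class's normal."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.M, size=spec.n, p=spec.weights)
    X = np.empty((spec.n, spec.D))
    for m, cls in enumerate(spec.classes):
        idx = np.flatnonzero(labels == m)
        if idx.size:
            X[idx] = rng.multivariate_normal(
                cls.mu, cls.sigma, size=idx.size, method="cholesky"
            )
    scores = ScoreMatrix(
        values=X,
        row_ids=[f"feat{i:06d}" for i in range(spec.n)],
        condition_names=[f"cond{d}" for d in range(spec.D)],
    )
    return SimulatedData(scores=scores, labels=labels, spec=spec)


def make_replicates(
    data: SimulatedData, rho: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two replicate matrices correlated rho within each condition.

    Shared latent signal plus independent Gaussian noise: each replicate
    is the source value plus noise with variance chosen per condition so
    that corr(rep1, rep2) = rho.  The per-entry expectation equals the
    source matrix.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    X = data.scores.values
    var = X.var(axis=0)
    if rho == 0.0:
        tau = np.full(X.shape[1], 1.0)  # arbitrary finite noise scale
    else:
        tau = np.sqrt(var * (1.0 - rho) / rho)
    rep1 = X + rng.normal(0.0, tau, size=X.shape)
    rep2 = X + rng.normal(0.0, tau, size=X.shape)
    return rep1, rep2


def to_pseudocounts(X: np.ndarray) -> np.ndarray:
    """Entrywise rounded 2**x, for count-based downstream callers."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("pseudocount transform requires finite input")
    if np.any(X > 62):
        bad = tuple(int(i) for i in np.argwhere(X > 62)[0])
        raise OverflowError(
            f"entry at {bad} (value {X[bad]:.3g}) would overflow 2**x"
        )
    return np.rint(np.exp2(X)).astype(np.int64)


@dataclass
class PRFResult:
    precision: Optional[float]
    recall: float
    f1: Optional[float]
    n_called: int
    n_true: int
    n_correct: int


def evaluate_sign_aware_prf(
    true_effect: np.ndarray,
    called: np.ndarray,
    true_sign: Optional[np.ndarray] = None,
    called_sign: Optional[np.ndarray] = None,
    require_sign: bool = True,
) -> PRFResult:
    """Sign-aware precision/recall/F1 of consistency calls.

    precision = |called & true & correctly signed| / |called|
    recall    = |called & true & correctly signed| / |true|

    A true effect called significant with the wrong sign counts as a
    false positive.  ``require_sign=False`` drops the sign requirement
    (as appropriate for direction-blind callers).
    """
    true_effect = np.asarray(true_effect, dtype=bool)
    called = np.asarray(called, dtype=bool)
    if called.shape != true_effect.shape:
        raise ValueError("calls must align with truth rows")
    correct = called & true_effect
    if require_sign:
        if true_sign is None or called_sign is None:
            raise ValueError("sign-aware evaluation needs true and called signs")
        correct = correct & (np.asarray(true_sign) == np.asarray(called_sign))
    n_called = int(called.sum())
    n_true = int(true_effect.sum())
    n_correct = int(correct.sum())
    if n_called == 0:
        warnings.warn("no significant calls; precision undefined")
        precision = None
    else:
        precision = n_correct / n_called
    recall = n_correct / n_true if n_true else 0.0
    if precision is None or precision + recall == 0:
        f1 = None if precision is None else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PRFResult(precision, recall, f1, n_called, n_true, n_correct)


# ---------------------------------------------------------------------------
# class-table builders and regime templates


def build_classes(
    vectors: Sequence[Sequence[int]],
    mean_scale: float = 3.0,
    corr: float = 0.5,
    var: float = 1.0,
) -> list[ConstrainedClassParams]:
    """Constraint-respecting class table from a list of label vectors.

    Non-null dimensions get mean ``mean_scale * label`` and variance
    ``var``; non-null pairs correlate with magnitude ``corr`` and the sign
    dictated by the label product.
    """
    out = []
    for vec in vectors:
        h = AssociationVector.from_iterable(vec)
        D = h.D
        mu = np.array([mean_scale * a for a in h], dtype=float)
        sigma = np.eye(D)
        for d in range(D):
            if h[d] != 0:
                sigma[d, d] = var
        for r in range(D):
            for t in range(r + 1, D):
                if h[r] != 0 and h[t] != 0:
                    sigma[r, t] = sigma[t, r] = h[r] * h[t] * corr * var
        mu, sigma = project_to_constraints(mu, sigma, h)
        out.append(ConstrainedClassParams(h, mu, sigma))
    return out


def well_separated_spec(
    D: int = 6,
    n: int = 5000,
    seed: int = 0,
    positive_only: bool = True,
    mean_scale: float = 4.0,
) -> SimulationSpec:
    """Desk-scale well-separated mixture used throughout the test study.

    Six classes: the null, the all-signal class, two complementary block
    patterns and two condition-specific singletons; signal means of
    magnitude ``mean_scale`` make the classes well separated.
    """
    half = D // 2
    vectors = [
        (0,) * D,
        (1,) * D,
        (1,) * half + (0,) * (D - half),
        (0,) * half + (1,) * (D - half),
        (1,) + (0,) * (D - 1),
        (0,) * (D - 1) + (1,),
    ]
    if not positive_only:
        vectors[3] = tuple(-a for a in vectors[3])
        vectors[5] = tuple(-a for a in vectors[5])
    classes = build_classes(vectors, mean_scale=mean_scale, corr=0.5)
    weights = np.array([0.25, 0.20, 0.15, 0.15, 0.15, 0.10])
    return SimulationSpec(
        classes=classes,
        weights=weights,
        n=n,
        seed=seed,
        positive_only=positive_only,
        name=f"well_separated_D{D}",
    )


def preset_regimes(seed: int = 0) -> dict[str, SimulationSpec]:
    """The three full-scale study regime templates.

    Shapes and flags follow the full-scale designs (n = 15,000 / 15,000 /
    21,303 observations over D = 18 / 11 / 5 conditions; regime 3 carries
    two replicates per condition at correlation 0.96).  Class tables are
    representative defaults and are meant to be replaced by user-supplied
    parameter tables for any specific study.
    """

    def blocks(D: int, signed: bool) -> list[tuple[int, ...]]:
        vecs: list[tuple[int, ...]] = [(0,) * D, (1,) * D]
        third = max(D // 3, 1)
        vecs.append((1,) * third + (0,) * (D - third))
        vecs.append((0,) * (D - third) + (1,) * third)
        vecs.append((1,) + (0,) * (D - 1))
        if signed:
            vecs.append((-1,) * D)
            vecs.append(tuple(-a for a in vecs[2]))
            vecs.append((0,) * (D - 1) + (-1,))
        return vecs

    def spec(D: int, n: int, signed: bool, rho: Optional[float], name: str) -> SimulationSpec:
        vecs = blocks(D, signed)
        classes = build_classes(vecs, mean_scale=3.0, corr=0.5)
        w = np.full(len(vecs), 0.5 / (len(vecs) - 1))
        w[0] = 0.5  # null class dominates, as in sparse genomic signals
        return SimulationSpec(
            classes=classes,
            weights=w,
            n=n,
            seed=seed,
            replicate_rho=rho,
            positive_only=not signed,
            name=name,
        )

    return {
        "chipseq_positive": spec(18, 15000, signed=False, rho=None, name="chipseq_positive"),
        "differential_signed": spec(11, 15000, signed=True, rho=None, name="differential_signed"),
        "lineage_rnaseq": spec(5, 21303, signed=True, rho=0.96, name="lineage_rnaseq"),
    }
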