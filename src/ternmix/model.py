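"""Constrained normal mixture model over ternary association vectors.

A feature measured across ``D`` conditions carries a latent *association
vector* ``h`` with one entry per condition: ``+1`` (significant positive
association), ``-1`` (significant negative association), or ``0`` (null).
Each vector indexes one class of a multivariate normal mixture whose
parameters are constrained so that the label is readable off the parameters:

* null dimensions are standard normal (mean 0, variance 1);
* non-null dimensions have a strictly signed mean matching the label;
* null dimensions are uncorrelated with every other dimension;
* two non-null dimensions correlate with sign equal to the product of
  their labels (concordant -> positive, discordant -> negative).

The density of each class is an ordinary multivariate normal density; the
constraints restrict the parameter space, not the support.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "AssociationVector",
    "ConstrainedClassParams",
    "MixtureModel",
    "ScoreMatrix",
    "SIGN_MARGIN",
    "SYMMETRY_TOL",
    "validate_constraints",
    "constrained_density",
    "constrained_logdensity",
    "mixture_loglik",
    "mvn_logpdf",
    "project_to_constraints",
    "nearest_positive_definite",
    "implied_vector",
]

#: default margin for "strictly signed" mean entries
SIGN_MARGIN = 1e-8
#: tolerance when checking covariance symmetry
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True, order=True)
class AssociationVector:
    """Ternary label vector, one entry in {-1, 0, 1} per condition.

    Frozen and ordered so vectors can live in sets/dicts and sort
    lexicographically with -1 < 0 < 1.
    """

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("association vector needs at least one dimension")
        if any(a not in (-1, 0, 1) for a in self.labels):
            raise ValueError(f"labels must be in {{-1, 0, 1}}, got {self.labels}")
        # normalize numpy ints etc. to builtin int
        object.__setattr__(self, "labels", tuple(int(a) for a in self.labels))

    @classmethod
    def from_iterable(cls, labels: Iterable[int]) -> "AssociationVector":
        return cls(tuple(int(a) for a in labels))

    @property
    def D(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.labels)

    def __getitem__(self, d: int) -> int:
        return self.labels[d]

    def count(self, value: int) -> int:
        return sum(1 for a in self.labels if a == value)

    @property
    def nonnull(self) -> np.ndarray:
        """Boolean mask of non-null dimensions."""
        return np.array([a != 0 for a in self.labels], dtype=bool)

    def subvector(self, dims: Sequence[int]) -> "AssociationVector":
        return AssociationVector(tuple(self.labels[d] for d in dims))

    def as_array(self) -> np.ndarray:
        return np.array(self.labels, dtype=int)

    def __str__(self) -> str:
        return "(" + ",".join(str(a) for a in self.labels) + ")"


@dataclass
class ConstrainedClassParams:
    """Mean and covariance of one mixture class, tied to its label ``h``."""

    h: AssociationVector
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(-1)
        self.sigma = np.asarray(self.sigma, dtype=float)
        D = self.h.D
        if self.mu.shape != (D,):
            raise ValueError(f"mu has shape {self.mu.shape}, expected ({D},)")
        if self.sigma.shape != (D, D):
            raise ValueError(f"sigma has shape {self.sigma.shape}, expected ({D}, {D})")

    @property
    def D(self) -> int:
        return self.h.D

    def copy(self) -> "ConstrainedClassParams":
        return ConstrainedClassParams(self.h, self.mu.copy(), self.sigma.copy())


@dataclass
class MixtureModel:
    """Finite constrained normal mixture with distinct class labels."""

    classes: list[ConstrainedClassParams]
    pi: np.ndarray
    n: Optional[int] = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float).reshape(-1)
        if len(self.classes) == 0:
            raise ValueError("mixture must contain at least one class")
        if self.pi.shape != (len(self.classes),):
            raise ValueError("pi length must equal number of classes")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be a probability vector (sum 1 within 1e-10)")
        vecs = [c.h for c in self.classes]
        if len(set(vecs)) != len(vecs):
            raise ValueError("class association vectors must be pairwise distinct")
        if self.n is not None and len(self.classes) > self.n:
            raise ValueError("number of classes exceeds sample size")

    @property
    def M(self) -> int:
        return len(self.classes)

    @property
    def D(self) -> int:
        return self.classes[0].D

    @property
    def vectors(self) -> list[AssociationVector]:
        return [c.h for c in self.classes]


@dataclass
class ScoreMatrix:
    """n x D matrix of per-feature Z-scores across conditions.

    Inputs are assumed to already be on the Z-score scale (the null class
    is fixed to the standard normal); no internal re-standardization.
    Optional BED-style coordinates are carried through untouched.
    """

    values: np.ndarray
    row_ids: list[str]
    condition_names: list[str]
    coordinates: Optional["object"] = None  # pandas.DataFrame with chrom/start/end

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, D = self.values.shape
        if len(self.row_ids) != n:
            raise ValueError("row_ids length must equal number of rows")
        if len(self.condition_names) != D:
            raise ValueError("condition_names length must equal number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix entries must all be finite")
        if len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]

    def pair(self, r: int, t: int) -> np.ndarray:
        """The n x 2 sub-matrix of columns (r, t)."""
        return self.values[:, [r, t]]


# ---------------------------------------------------------------------------
# constraint validation


def validate_constraints(
    params: ConstrainedClassParams, margin: float = SIGN_MARGIN
) -> list[str]:
    """Check a class's parameters against all sign/null constraint families.

    Returns one human-readable entry per violated rule; an empty list means
    the parameters are valid.  Sign strictness on non-null means uses a
    configurable ``margin`` so that sign tests are well defined at machine
    precision.
    """
    h, mu, sigma = params.h, params.mu, params.sigma
    D = h.D
    violations: list[str] = []

    if not np.allclose(sigma, sigma.T, atol=SYMMETRY_TOL, rtol=0.0):
        violations.append("sigma is not symmetric within tolerance")

    for d in range(D):
        a = h[d]
        if a == 0:
            if mu[d] != 0.0:
                violations.append(f"null dimension {d}: mu[{d}]={mu[d]!r} must be 0")
            if not np.isclose(sigma[d, d], 1.0, atol=1e-8):
                violations.append(
                    f"null dimension {d}: sigma[{d},{d}]={sigma[d, d]!r} must be 1"
                )
        elif a * mu[d] < margin:
            violations.append(
                f"dimension {d}: sgn(mu)={np.sign(mu[d])!r} must match label {a}"
            )
        if sigma[d, d] <= 0:
            violations.append(f"dimension {d}: variance must be positive")

    for r in range(D):
        for t in range(r + 1, D):
            if h[r] == 0 or h[t] == 0:
                if sigma[r, t] != 0.0:
                    violations.append(
                        f"pair ({r},{t}): null dimension must have zero covariance, "
                        f"got {sigma[r, t]!r}"
                    )
            else:
                want = h[r] * h[t]
                if sigma[r, t] * want <= 0:
                    violations.append(
                        f"pair ({r},{t}): sgn(sigma)={np.sign(sigma[r, t])!r} must be "
                        f"{want} (= h[{r}]*h[{t}])"
                    )

    # positive definiteness via symmetric (Cholesky) factorization
    try:
        np.linalg.cholesky((sigma + sigma.T) / 2.0)
    except np.linalg.LinAlgError:
        violations.append("sigma is not positive definite")
    return violations


class ConstraintViolationError(ValueError):
    """Raised when class parameters violate the label-driven constraints."""


def _require_valid(params: ConstrainedClassParams, margin: float = SIGN_MARGIN) -> None:
    violations = validate_constraints(params, margin=margin)
    if violations:
        raise ConstraintViolationError(
            f"class {params.h}: " + "; ".join(violations)
        )


# ---------------------------------------------------------------------------
# densities


def mvn_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Multivariate normal log-density, vectorized over rows of ``x``.

    Cholesky-based; raises ``numpy.linalg.LinAlgError`` for non-PD sigma.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu = np.asarray(mu, dtype=float).reshape(-1)
    D = mu.shape[0]
    chol, lower = cho_factor(sigma, lower=True)
    diff = x - mu
    solved = cho_solve((chol, lower), diff.T)
    quad = np.einsum("ij,ji->i", diff, solved)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (D * np.log(2.0 * np.pi) + logdet + quad)


def constrained_logdensity(
    x: np.ndarray, params: ConstrainedClassParams, validate: bool = True
) -> np.ndarray:
    """Log of :func:`constrained_density`; same validation semantics."""
    if validate:
        _require_valid(params)
    try:
        return mvn_logpdf(x, params.mu, params.sigma)
    except np.linalg.LinAlgError as exc:  # non-PD slipped past validate=False
        raise np.linalg.LinAlgError(
            f"covariance decomposition failed for class {params.h}: {exc}"
        ) from exc


def constrained_density(
    x: np.ndarray, params: ConstrainedClassParams, validate: bool = True
) -> np.ndarray | float:
    """Density of the constrained class at ``x`` (scalar or one per row).

    Identical to the unconstrained multivariate normal density: the
    constraints restrict the parameters, not the support.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    out = np.exp(constrained_logdensity(x, params, validate=validate))
    return float(out[0]) if scalar else out


def mixture_loglik(
    data: ScoreMatrix | np.ndarray, model: MixtureModel, validate: bool = True
) -> float:
    """Observed-data log-likelihood, computed with log-sum-exp stability."""
    X = data.values if isinstance(data, ScoreMatrix) else np.asarray(data, dtype=float)
    if model.M == 0:
        raise ValueError("empty mixture model")
    logp = np.empty((X.shape[0], model.M))
    for m, cls in enumerate(model.classes):
        logp[:, m] = constrained_logdensity(X, cls, validate=validate)
    with np.errstate(divide="ignore"):
        logp = logp + np.log(model.pi)
    from scipy.special import logsumexp

    return float(logsumexp(logp, axis=1).sum())


# ---------------------------------------------------------------------------
# projection utilities shared by the fitting and sampling code


def nearest_positive_definite(A: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Symmetrize and floor eigenvalues so the result is safely PD."""
    B = (A + A.T) / 2.0
    w, V = np.linalg.eigh(B)
    if w.min() > floor:
        return B
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def project_to_constraints(
    mu: np.ndarray,
    sigma: np.ndarray,
    h: AssociationVector,
    margin: float = SIGN_MARGIN,
    pd_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Project (mu, sigma) onto the feasible set of label ``h``.

    Null dimensions are hard-fixed (mean 0, variance 1, zero covariance);
    non-null means are clipped to the correct open half-line; off-diagonal
    entries with the wrong sign are clipped toward the correct side, and the
    non-null block is repaired to the nearest PD matrix if needed.
    """
    D = h.D
    mu = np.asarray(mu, dtype=float).copy()
    sigma = np.asarray(sigma, dtype=float).copy()
    sigma = (sigma + sigma.T) / 2.0
    for d in range(D):
        a = h[d]
        if a == 0:
            mu[d] = 0.0
            sigma[d, :] = 0.0
            sigma[:, d] = 0.0
            sigma[d, d] = 1.0
        elif a * mu[d] < margin:
            mu[d] = a * margin

    nn = np.flatnonzero(h.nonnull)
    if nn.size:
        block = sigma[np.ix_(nn, nn)]
        for i, r in enumerate(nn):
            for j in range(i + 1, nn.size):
                t = nn[j]
                want = h[r] * h[t]
                if block[i, j] * want <= 0:
                    block[i, j] = block[j, i] = want * margin
        try:
            np.linalg.cholesky(block)
        except np.linalg.LinAlgError:
            block = nearest_positive_definite(block, floor=pd_floor)
            # PD repair may flip tiny entries back across zero; re-clip
            for i, r in enumerate(nn):
                for j in range(i + 1, nn.size):
                    t = nn[j]
                    want = h[r] * h[t]
                    if block[i, j] * want <= 0:
                        block[i, j] = block[j, i] = want * margin
        sigma[np.ix_(nn, nn)] = block
    return mu, sigma


def implied_vector(
    mu: np.ndarray, h: AssociationVector, zero_tol: float
) -> AssociationVector:
    """The label the fitted mean actually supports.

    A non-null dimension whose fitted mean collapsed to within ``zero_tol``
    of 0 is, by the model's own semantics (mu_d = 0 iff h_d = 0), a null
    dimension; the implied vector re-labels such dimensions 0.
    """
    labels = []
    for d, a in enumerate(h):
        if a != 0 and abs(mu[d]) < zero_tol:
            labels.append(0)
        else:
            labels.append(a)
    return AssociationVector(tuple(labels))
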