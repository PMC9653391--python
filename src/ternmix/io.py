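"""Readers, writers and score transforms.

Score matrices travel as delimited text (TSV by default): first column
feature identifier, optional BED-style ``chrom``/``start``/``end``
columns (0-based half-open, carried through untouched), remaining
columns one per condition.  Intermediate pipeline artifacts use
versioned JSON (pairwise battery, hyperparameters), plain TSV (candidate
sets, summaries) and a columnar .npz archive (posterior draws).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .gibbs import ChainConfig, PosteriorDraws
from .labelgraph import CandidateSet
from .model import AssociationVector, ConstrainedClassParams, ScoreMatrix
from .pairwise import PairwiseClassSet, PairwiseFit
from .weights import Hyperparameters

logger = logging.getLogger(__name__)

__all__ = [
    "read_scores",
    "write_scores",
    "pvalues_to_z",
    "save_battery",
    "load_battery",
    "save_candidates",
    "load_candidates",
    "save_hyperparameters",
    "load_hyperparameters",
    "save_draws",
    "load_draws",
]

FORMAT_VERSION = 1
_COORD_COLS = ("chrom", "start", "end")


def read_scores(path: str | Path, sep: str = "\t") -> ScoreMatrix:
    """Read a delimited score file into a :class:`ScoreMatrix`.

    Header row names the columns; the first column holds unique feature
    identifiers; ``chrom``/``start``/``end`` columns, when present, are
    carried as coordinates.  Rows with any missing value are dropped with
    a logged count.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("score file needs an ID column plus condition columns")
    id_col = df.columns[0]
    coord_cols = [c for c in _COORD_COLS if c in df.columns]
    cond_cols = [c for c in df.columns[1:] if c not in coord_cols]
    if len(cond_cols) < 2:
        raise ValueError("need at least 2 condition columns")
    before = len(df)
    df = df.dropna(subset=cond_cols + [id_col])
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values", dropped)
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature identifiers in score file")
    try:
        values = df[cond_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric score cell: {exc}") from exc
    coords = df[coord_cols].reset_index(drop=True) if coord_cols else None
    return ScoreMatrix(
        values=values, row_ids=ids, condition_names=list(cond_cols), coordinates=coords
    )


def write_scores(data: ScoreMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(data.values, columns=data.condition_names)
    df.insert(0, "feature", data.row_ids)
    if data.coordinates is not None:
        for i, c in enumerate(data.coordinates.columns):
            df.insert(1 + i, c, data.coordinates[c].to_numpy())
    # default str() formatting is shortest-round-trip exact for float64
    df.to_csv(path, sep=sep, index=False)


def pvalues_to_z(
    p: np.ndarray,
    signs: Optional[np.ndarray] = None,
    floor: float = 1e-300,
) -> np.ndarray:
    """Convert p-values to Z-scores (larger = stronger signal).

    Unsigned mode: z = Phi^-1(1 - p), one-sided.  Signed mode (per-feature
    direction in {-1, +1} supplied): z = sign * Phi^-1(1 - p/2),
    two-sided.  p-values at 0 or 1 are clipped to a configurable floor
    with a warning.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        import warnings

        warnings.warn(f"p-values outside (0, 1) clipped to [{floor}, 1 - 1e-16]")
    p = np.clip(p, floor, 1.0 - 1e-16)
    if signs is None:
        return -ndtri(p)
    signs = np.asarray(signs)
    if not np.all(np.isin(signs, (-1, 1))):
        raise ValueError("signs must be -1 or +1")
    return signs * -ndtri(p / 2.0)


# ---------------------------------------------------------------------------
# artifact serialization


def _params_to_dict(p: ConstrainedClassParams) -> dict:
    return {"h": list(p.h.labels), "mu": p.mu.tolist(), "sigma": p.sigma.tolist()}


def _params_from_dict(d: dict) -> ConstrainedClassParams:
    return ConstrainedClassParams(
        AssociationVector(tuple(d["h"])), np.array(d["mu"]), np.array(d["sigma"])
    )


def save_battery(
    battery: Mapping[tuple[int, int], PairwiseFit], path: str | Path
) -> None:
    """Serialize per-pair class sets, parameters and weights (not the
    responsibilities, which are recomputable from the parameters)."""
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "pairwise_battery",
        "pairs": [
            {
                "pair": list(pair),
                "classes": [_params_to_dict(p) for p in fit.params],
                "weights": fit.weights.tolist(),
                "converged": bool(fit.converged),
                "loglik": fit.loglik,
                "lambda": fit.lam,
                "bic": fit.bic,
            }
            for pair, fit in sorted(battery.items())
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_battery(
    path: str | Path, data: Optional[ScoreMatrix] = None
) -> dict[tuple[int, int], PairwiseFit]:
    """Load a battery; responsibilities are recomputed when data is given."""
    from .pairwise import _bivariate_logpdf

    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "pairwise_battery":
        raise ValueError(f"{path} is not a pairwise battery archive")
    battery: dict[tuple[int, int], PairwiseFit] = {}
    for entry in payload["pairs"]:
        pair = tuple(entry["pair"])
        params = [_params_from_dict(d) for d in entry["classes"]]
        weights = np.array(entry["weights"])
        resp = np.zeros((0, len(params)))
        if data is not None:
            X = data.pair(*pair)
            mus = np.stack([p.mu for p in params])
            sigmas = np.stack([p.sigma for p in params])
            logp = _bivariate_logpdf(X, mus, sigmas) + np.log(weights)
            mx = logp.max(axis=1, keepdims=True)
            w = np.exp(logp - mx)
            resp = w / w.sum(axis=1, keepdims=True)
        battery[pair] = PairwiseFit(
            class_set=PairwiseClassSet(pair, [p.h for p in params]),
            params=params,
            weights=weights,
            responsibilities=resp,
            loglik_trace=[],
            converged=entry["converged"],
            loglik=entry["loglik"],
            lam=entry["lambda"],
            bic=entry["bic"],
        )
    return battery


def save_candidates(
    candidates: CandidateSet, path: str | Path, condition_names: Optional[list[str]] = None
) -> None:
    """One row per vector, D columns of {-1,0,1}, header of condition names."""
    D = candidates.D if len(candidates) else 0
    names = condition_names or [f"cond{d}" for d in range(D)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for v in candidates.vectors:
            fh.write("\t".join(str(a) for a in v.labels) + "\n")


def load_candidates(path: str | Path) -> CandidateSet:
    df = pd.read_csv(path, sep="\t")
    vectors = [AssociationVector(tuple(int(a) for a in row)) for row in df.to_numpy()]
    return CandidateSet(vectors=vectors, pruned=True)


def save_hyperparameters(hyper: Hyperparameters, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "hyperparameters",
        "classes": [
            {
                "h": list(h.labels),
                "mu0": hyper.mu0[m].tolist(),
                "psi0": hyper.psi0[m].tolist(),
                "kappa": float(hyper.kappa[m]),
                "nu": float(hyper.nu[m]),
                "dirichlet": float(hyper.dirichlet[m]),
            }
            for m, h in enumerate(hyper.vectors)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_hyperparameters(path: str | Path) -> Hyperparameters:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "hyperparameters":
        raise ValueError(f"{path} is not a hyperparameter archive")
    entries = payload["classes"]
    return Hyperparameters(
        vectors=[AssociationVector(tuple(e["h"])) for e in entries],
        mu0=np.array([e["mu0"] for e in entries]),
        psi0=np.array([e["psi0"] for e in entries]),
        kappa=np.array([e["kappa"] for e in entries]),
        nu=np.array([e["nu"] for e in entries]),
        dirichlet=np.array([e["dirichlet"] for e in entries]),
    )


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    np.savez_compressed(
        path,
        vectors=np.array([v.labels for v in draws.vectors], dtype=np.int8),
        mu=draws.mu,
        sigma=draws.sigma,
        pi=draws.pi,
        labels=draws.labels,
        seed=np.array([draws.seed]),
        config=np.array(
            [
                draws.config.n_iter,
                draws.config.burn_in,
                draws.config.thin,
                draws.config.seed,
                draws.config.mh_max_attempts,
                draws.config.tnorm_sweeps,
            ]
        ),
        sigma_accept_rate=draws.sigma_accept_rate,
        empty_fraction=draws.empty_fraction,
    )


def load_draws(path: str | Path) -> PosteriorDraws:
    with np.load(path) as z:
        cfg = z["config"]
        config = ChainConfig(
            n_iter=int(cfg[0]),
            burn_in=int(cfg[1]),
            thin=int(cfg[2]),
            seed=int(cfg[3]),
            mh_max_attempts=int(cfg[4]),
            tnorm_sweeps=int(cfg[5]),
        )
        return PosteriorDraws(
            vectors=[AssociationVector(tuple(int(a) for a in row)) for row in z["vectors"]],
            mu=z["mu"],
            sigma=z["sigma"],
            pi=z["pi"],
            labels=z["labels"],
            seed=int(z["seed"][0]),
            config=config,
            sigma_accept_rate=z["sigma_accept_rate"],
            empty_fraction=z["empty_fraction"],
        )
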