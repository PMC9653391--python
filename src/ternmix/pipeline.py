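"""End-to-end pipeline driver: pairwise fits -> enumeration -> weights -> MCMC.

Each step writes its artifact to the output directory, so a run can be
resumed from any completed stage; a manifest records the master seed,
configuration hash, package version and per-step timings.  All
randomness flows from the master seed through named child seeds, so a
rerun with the same seed is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .consistency import consistency_stats
from .gibbs import ChainConfig, PosteriorDraws, posterior_summaries, run_mcmc
from .labelgraph import CandidateSet, candidates_from_battery
from .model import MixtureModel, ScoreMatrix
from .pairwise import PenaltySettings, fit_all_pairs
from .weights import (
    assemble_hyperparameters,
    estimate_alpha,
    prune_by_alpha,
    sample_pairwise_labels,
    select_delta,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline settings in one place; YAML-loadable."""

    outdir: str = "ternmix_out"
    seed: int = 0
    input_path: Optional[str] = None
    sep: str = "\t"
    penalty: PenaltySettings = field(default_factory=PenaltySettings)
    delta: Optional[int] = None  # None -> plateau heuristic
    separation_hint: str = "well_separated"
    chain: ChainConfig = field(default_factory=ChainConfig)
    test_u: Optional[int] = None  # None -> u = D
    test_b: float = 0.5
    test_mode: str = "sign-aware"  # or "partial-conjunction"

    def child_seed(self, name: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Build a config from a YAML file; nested sections map to settings."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    penalty = PenaltySettings(**raw.pop("penalty", {}))
    chain = ChainConfig(**raw.pop("chain", {}))
    return PipelineConfig(penalty=penalty, chain=chain, **raw)


@dataclass
class PipelineResult:
    """Objects and artifact paths produced by one pipeline run."""

    battery: dict
    candidates_pre: CandidateSet
    candidates: CandidateSet
    delta: int
    alpha: np.ndarray
    hyper: "object"
    draws: PosteriorDraws
    model: MixtureModel
    membership: np.ndarray
    stats: "object"
    calls: np.ndarray
    outdir: Path


def _step(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("step %s: start", name)
            return self

        def __exit__(self, *exc):
            manifest["timings"][name] = round(time.perf_counter() - self.t0, 3)
            logger.info("step %s: done in %.1fs", name, manifest["timings"][name])

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    data: Optional[ScoreMatrix] = None,
    resume: bool = False,
) -> PipelineResult:
    """Execute the four estimation steps plus the consistency test.

    ``data`` may be passed directly or read from ``config.input_path``.
    With ``resume=True``, steps whose artifacts already exist in the
    output directory are loaded instead of recomputed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if data is None:
        if config.input_path is None:
            raise ValueError("either data or config.input_path is required")
        data = tio.read_scores(config.input_path, sep=config.sep)

    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n": data.n,
        "D": data.D,
        "timings": {},
        "class_counts": {},
    }
    from . import __version__

    manifest["version"] = __version__

    battery_path = outdir / "pairwise_battery.json"
    with _step(manifest, "pairwise"):
        if resume and battery_path.exists():
            battery = tio.load_battery(battery_path, data=data)
        else:
            penalty = dataclasses.replace(
                config.penalty, seed=config.child_seed("pairwise")
            )
            battery = fit_all_pairs(data, penalty)
            tio.save_battery(battery, battery_path)
    manifest["class_counts"]["pairwise_total"] = sum(f.M for f in battery.values())

    pre_path = outdir / "candidates_pre.tsv"
    post_path = outdir / "candidates_graph.tsv"
    with _step(manifest, "enumeration"):
        candidates_pre, candidates_graph = candidates_from_battery(battery)
        tio.save_candidates(candidates_pre, pre_path, data.condition_names)
        tio.save_candidates(candidates_graph, post_path, data.condition_names)
    manifest["class_counts"]["candidates_pre_pruning"] = len(candidates_pre)
    manifest["class_counts"]["candidates_post_pruning"] = len(candidates_graph)

    with _step(manifest, "weights"):
        samples = sample_pairwise_labels(battery, seed=config.child_seed("labels"))
        delta = (
            config.delta
            if config.delta is not None
            else select_delta(samples, candidates_graph, config.separation_hint)
        )
        alpha0 = estimate_alpha(samples, candidates_graph, delta)
        candidates, alpha = prune_by_alpha(candidates_graph, alpha0, data.n, data.D)
        hyper = assemble_hyperparameters(battery, candidates, alpha, data.n)
        tio.save_candidates(candidates, outdir / "candidates_final.tsv", data.condition_names)
        (outdir / "alpha.json").write_text(
            json.dumps(
                {
                    "delta": int(delta),
                    "alpha": {
                        str(v): float(a) for v, a in zip(alpha.vectors, alpha.alpha)
                    },
                }
            )
        )
        tio.save_hyperparameters(hyper, outdir / "hyperparameters.json")
    manifest["class_counts"]["candidates_final"] = len(candidates)
    manifest["delta"] = int(delta)

    draws_path = outdir / "draws.npz"
    with _step(manifest, "mcmc"):
        if resume and draws_path.exists():
            draws = tio.load_draws(draws_path)
        else:
            chain = dataclasses.replace(config.chain, seed=config.child_seed("mcmc"))
            draws = run_mcmc(data, candidates, hyper, chain)
            tio.save_draws(draws, draws_path)

    with _step(manifest, "summaries"):
        model, membership = posterior_summaries(draws)
        summary = pd.DataFrame(
            {
                "vector": [str(h) for h in model.vectors],
                "pi": model.pi,
            }
        )
        for d, name in enumerate(data.condition_names):
            summary[f"mu_{name}"] = [c.mu[d] for c in model.classes]
        summary.to_csv(outdir / "class_summary.tsv", sep="\t", index=False)

        u = config.test_u if config.test_u is not None else data.D
        stats = consistency_stats(draws, u)
        if config.test_mode == "partial-conjunction":
            from .consistency import partial_conjunction_test

            decision = partial_conjunction_test(draws, u, config.test_b)
            calls = np.where(decision, "consistent", "differential")
        else:
            calls = np.where(stats.reject(config.test_b), "consistent", "differential")
        results = pd.DataFrame(
            {
                "feature": data.row_ids,
                "p_plus": stats.p_plus,
                "p_zero": stats.p_zero,
                "p_minus": stats.p_minus,
                "p_max": stats.p,
                "dominant": stats.dominant,
                "decision": calls,
            }
        )
        if data.coordinates is not None:
            for i, c in enumerate(data.coordinates.columns):
                results.insert(1 + i, c, data.coordinates[c].to_numpy())
        results.to_csv(outdir / "consistency.tsv", sep="\t", index=False)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        battery=battery,
        candidates_pre=candidates_pre,
        candidates=candidates,
        delta=delta,
        alpha=alpha.alpha,
        hyper=hyper,
        draws=draws,
        model=model,
        membership=membership,
        stats=stats,
        calls=calls,
        outdir=outdir,
    )
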