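"""Post-fit analyses: condition dendrograms, class merging, group profiles.

The fitted class covariances induce a similarity between conditions: each
class covariance is converted to a correlation matrix and the mixing-
weight-weighted average correlation across classes is used as similarity
(distance = 1 - correlation, average linkage).  Fitted classes may be
merged into a small number of parent groups by hierarchical clustering of
their mean vectors, and each group summarized by the weight-averaged mean
signal profile.  Baker's Gamma compares two dendrograms by rank-
correlating, over all leaf pairs, the depth of the pair's lowest common
ancestor in each tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .model import MixtureModel

__all__ = [
    "ConditionTree",
    "ClassGrouping",
    "condition_dendrogram",
    "merge_classes",
    "group_signal",
    "bakers_gamma",
]


@dataclass
class ConditionTree:
    """Rooted dendrogram over the D conditions (scipy linkage encoding)."""

    linkage: np.ndarray  # (D-1, 4) scipy linkage matrix
    leaves: list[str]

    def __post_init__(self) -> None:
        if len(set(self.leaves)) != len(self.leaves):
            raise ValueError("leaf names must be distinct")
        if self.linkage.shape != (len(self.leaves) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")

    @property
    def D(self) -> int:
        return len(self.leaves)

    def merge_step_matrix(self) -> np.ndarray:
        """(D, D) step index (1-based) at which each leaf pair first joins."""
        D = self.D
        members: dict[int, set[int]] = {i: {i} for i in range(D)}
        step = np.zeros((D, D), dtype=int)
        for s, (a, b, _h, _c) in enumerate(self.linkage, start=1):
            left, right = members.pop(int(a)), members.pop(int(b))
            for i in left:
                for j in right:
                    step[i, j] = step[j, i] = s
            members[D - 1 + s] = left | right
        return step

    def to_newick(self) -> str:
        """Newick string with branch lengths from the linkage heights."""
        D = self.D
        heights = {i: 0.0 for i in range(D)}
        reps = {i: self.leaves[i] for i in range(D)}
        for s, (a, b, h, _c) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            node = D + s
            reps[node] = f"({reps[a]}:{la:.6g},{reps[b]}:{lb:.6g})"
            heights[node] = h
        return reps[2 * D - 2] + ";"


@dataclass
class ClassGrouping:
    """Partition of the fitted classes into G parent groups (labels 1..G)."""

    assignments: np.ndarray  # (M,) group index per class, 1-based
    G: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        present = set(self.assignments.tolist())
        if present != set(range(1, self.G + 1)):
            raise ValueError("group labels must be exactly 1..G")

    def members(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == g)


def _cov_to_corr(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def condition_dendrogram(model: MixtureModel) -> ConditionTree:
    """Cluster conditions by the weight-averaged class correlation.

    Distance between conditions r and t is 1 minus the pi-weighted average,
    over classes, of the class correlation between r and t; average-linkage
    hierarchical clustering; deterministic.
    """
    if model.D < 2:
        raise ValueError("condition clustering needs at least 2 conditions")
    if model.M < 2:
        raise ValueError("condition clustering needs a fitted model with >= 2 classes")
    Rbar = np.zeros((model.D, model.D))
    for cls, w in zip(model.classes, model.pi):
        Rbar += w * _cov_to_corr(cls.sigma)
    dist = 1.0 - Rbar
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    names = [f"cond{d}" for d in range(model.D)]
    return ConditionTree(linkage=Z, leaves=names)


def merge_classes(model: MixtureModel, G: int) -> ClassGrouping:
    """Merge fitted classes into G parent groups.

    Average-linkage hierarchical clustering of the class mean vectors
    (Euclidean distance), cut at G groups; groups renumbered by
    decreasing total mixing weight (ties by first occurrence).
    """
    if not (1 <= G <= model.M):
        raise ValueError(f"G must lie in [1, M] = [1, {model.M}]")
    means = np.stack([c.mu for c in model.classes])
    if G == model.M:
        raw = np.arange(1, model.M + 1)
    else:
        Z = linkage(pdist(means), method="average")
        raw = fcluster(Z, t=G, criterion="maxclust")
    # relabel by group weight, heaviest first
    weights = {g: model.pi[raw == g].sum() for g in np.unique(raw)}
    order = sorted(weights, key=lambda g: (-weights[g], g))
    remap = {g: i + 1 for i, g in enumerate(order)}
    return ClassGrouping(
        assignments=np.array([remap[g] for g in raw]), G=len(order)
    )


def group_signal(model: MixtureModel, grouping: ClassGrouping) -> np.ndarray:
    """(G, D) per-group signal profile: weight-averaged member-class means."""
    out = np.zeros((grouping.G, model.D))
    means = np.stack([c.mu for c in model.classes])
    for g in range(1, grouping.G + 1):
        idx = grouping.members(g)
        if idx.size == 0:
            raise ValueError(f"group {g} is empty")
        w = model.pi[idx]
        out[g - 1] = (w / w.sum()) @ means[idx]
    return out


def bakers_gamma(tree1: ConditionTree, tree2: ConditionTree) -> float:
    """Baker's Gamma similarity between two dendrograms, in [-1, 1].

    Spearman rank correlation between, over all leaf pairs, the depth of
    the pair's lowest common ancestor in each tree (measured as the merge
    step counted from the leaves, negated so deeper LCA = later merge).
    """
    if sorted(tree1.leaves) != sorted(tree2.leaves):
        raise ValueError("trees must share the same leaf set")
    order = {name: i for i, name in enumerate(tree1.leaves)}
    perm = np.array([order[name] for name in tree2.leaves])
    s1 = tree1.merge_step_matrix()
    s2_raw = tree2.merge_step_matrix()
    # align tree2's leaf indexing to tree1's
    s2 = np.zeros_like(s2_raw)
    s2[np.ix_(perm, perm)] = s2_raw
    iu = np.triu_indices(tree1.D, k=1)
    a, b = s1[iu], s2[iu]
    if np.all(a == a[0]) and np.all(b == b[0]):
        return 1.0  # both trees merge every pair at one height
    rho = spearmanr(-a, -b).statistic
    return float(rho)
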