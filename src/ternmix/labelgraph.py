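"""Step 2 — layered label graph and enumeration of candidate vectors.

The retained pairwise class sets for *adjacent* condition pairs
(d, d+1) define a layered directed acyclic graph: one vertex per
(dimension, label) combination plus dummy source S and target T.  An edge
runs from (d, a1) to (d+1, a2) exactly when the two-dimensional vector
(a1, a2) was retained for the pair (d, d+1).  Every S -> T path spells out
one candidate D-dimensional association vector; candidates whose label
pairs contradict any *non-adjacent* pairwise fit are then pruned.

The enumeration is sound: if every pairwise class set contains the label
pairs of a true D-dimensional class, that class survives both the path
enumeration and the pruning.  It is also invariant (up to relabelling)
under any permutation of the dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import AssociationVector

__all__ = [
    "LabelGraph",
    "CandidateSet",
    "build_label_graph",
    "enumerate_paths",
    "prune_inconsistent",
    "candidates_from_battery",
]

LABELS = (-1, 0, 1)  # lexicographic order used everywhere

#: guard against pathological candidate explosion
DEFAULT_PATH_CAP = 10**7

PairSet = frozenset  # of (a1, a2) tuples


def _as_pairset(s: Iterable) -> frozenset[tuple[int, int]]:
    out = set()
    for v in s:
        a1, a2 = (v.labels if isinstance(v, AssociationVector) else tuple(v))
        if a1 not in LABELS or a2 not in LABELS:
            raise ValueError(f"invalid pairwise label {(a1, a2)}")
        out.add((int(a1), int(a2)))
    return frozenset(out)


@dataclass
class LabelGraph:
    """Layered DAG over (dimension, label) vertices with dummy S and T.

    ``transitions[d]`` maps a label at layer d to the sorted labels it may
    be followed by at layer d+1 (d = 0 .. D-2, zero-based layers).
    """

    D: int
    transitions: list[dict[int, tuple[int, ...]]]

    @property
    def n_vertices(self) -> int:
        return 3 * self.D + 2

    def edge_count(self) -> int:
        """Inter-layer edges only (excludes the 6 S/T terminal edges)."""
        return sum(len(nxt) for layer in self.transitions for nxt in layer.values())

    def has_edge(self, d: int, a1: int, a2: int) -> bool:
        """Edge from (d, a1) to (d+1, a2), layers zero-based."""
        return a2 in self.transitions[d].get(a1, ())

    def source_out_labels(self) -> tuple[int, ...]:
        return LABELS

    def target_in_labels(self) -> tuple[int, ...]:
        return LABELS


@dataclass
class CandidateSet:
    """Ordered, duplicate-free list of candidate association vectors."""

    vectors: list[AssociationVector]
    pruned: bool = False  # True once non-adjacent-pair pruning has run

    def __post_init__(self) -> None:
        if len(set(self.vectors)) != len(self.vectors):
            raise ValueError("candidate vectors must be distinct")
        if self.vectors:
            D = self.vectors[0].D
            if any(v.D != D for v in self.vectors):
                raise ValueError("candidate vectors must share one dimension")

    def __len__(self) -> int:
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)

    def __contains__(self, v: AssociationVector) -> bool:
        return v in set(self.vectors)

    @property
    def D(self) -> int:
        if not self.vectors:
            raise ValueError("empty candidate set has no dimension")
        return self.vectors[0].D


def build_label_graph(adjacent_sets: Sequence[Iterable]) -> LabelGraph:
    """Build the layered graph from the D-1 adjacent-pair class sets.

    ``adjacent_sets[d]`` holds the retained two-dimensional vectors for the
    condition pair (d, d+1), zero-based.
    """
    if len(adjacent_sets) < 1:
        raise ValueError("need at least one adjacent pair set (D >= 2)")
    D = len(adjacent_sets) + 1
    transitions: list[dict[int, tuple[int, ...]]] = []
    for d, s in enumerate(adjacent_sets):
        ps = _as_pairset(s)
        if not ps:
            raise ValueError(
                f"adjacent class set for pair ({d}, {d + 1}) is empty: "
                "no path can cross this layer"
            )
        layer: dict[int, tuple[int, ...]] = {}
        for a1 in LABELS:
            nxt = tuple(sorted(a2 for a2 in LABELS if (a1, a2) in ps))
            if nxt:
                layer[a1] = nxt
        transitions.append(layer)
    return LabelGraph(D=D, transitions=transitions)


def _count_paths(graph: LabelGraph) -> int:
    """Dynamic-programming path count (cheap explosion check before DFS)."""
    counts = {a: 1 for a in LABELS}  # paths from layer D-1 vertex to T
    for layer in reversed(graph.transitions):
        counts = {
            a1: sum(counts.get(a2, 0) for a2 in layer.get(a1, ()))
            for a1 in LABELS
        }
    return sum(counts.values())


def enumerate_paths(graph: LabelGraph, cap: int = DEFAULT_PATH_CAP) -> CandidateSet:
    """Enumerate every S -> T path as a candidate vector.

    Iterative depth-first search with an explicit stack (safe for D in the
    hundreds), emitting paths in lexicographic order with -1 < 0 < 1.
    A configurable cap aborts on pathological explosion instead of
    silently truncating.
    """
    total = _count_paths(graph)
    if total > cap:
        raise RuntimeError(
            f"candidate enumeration would produce {total} paths, "
            f"exceeding the cap of {cap}"
        )
    D = graph.D
    out: list[AssociationVector] = []
    # stack entries: (depth, label); prefix holds the current partial path
    prefix: list[int] = []
    stack: list[tuple[int, int]] = [(0, a) for a in reversed(LABELS)]
    while stack:
        depth, a = stack.pop()
        del prefix[depth:]
        prefix.append(a)
        if depth == D - 1:
            out.append(AssociationVector(tuple(prefix)))
            continue
        for nxt in reversed(graph.transitions[depth].get(a, ())):
            stack.append((depth + 1, nxt))
    return CandidateSet(vectors=out, pruned=False)


def prune_inconsistent(
    candidates: CandidateSet,
    all_sets: Mapping[tuple[int, int], Iterable],
) -> CandidateSet:
    """Drop candidates contradicted by any pairwise class set.

    A candidate h survives iff (h[r], h[t]) is a retained class of every
    pair (r, t) present in ``all_sets``.
    """
    pairsets = {pair: _as_pairset(s) for pair, s in all_sets.items()}
    kept = [
        v
        for v in candidates.vectors
        if all((v[r], v[t]) in ps for (r, t), ps in pairsets.items())
    ]
    return CandidateSet(vectors=kept, pruned=True)


def candidates_from_battery(battery: Mapping[tuple[int, int], "object"]) -> tuple[CandidateSet, CandidateSet]:
    """Graph enumeration + pruning straight from a battery of pairwise fits.

    Returns (pre-pruning candidates, pruned candidates).
    """
    pairs = sorted(battery)
    D = max(t for _, t in pairs) + 1
    sets = {pair: battery[pair].class_set.vectors for pair in pairs}
    adjacent = [sets[(d, d + 1)] for d in range(D - 1)]
    graph = build_label_graph(adjacent)
    pre = enumerate_paths(graph)
    post = prune_inconsistent(pre, sets)
    return pre, post
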