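import itertools

import numpy as np
import pytest

from ternmix.model import AssociationVector


def brute_force_candidates(D, pair_sets):
    """Exhaustive oracle: every vector in {-1,0,1}^D whose label pairs all
    lie in the given pairwise sets (adjacent-only or all-pairs)."""
    out = []
    for vec in itertools.product((-1, 0, 1), repeat=D):
        ok = all(
            (vec[r], vec[t]) in pair_sets[(r, t)] for (r, t) in pair_sets
        )
        if ok:
            out.append(AssociationVector(vec))
    return out


def random_pair_sets(rng, D, adjacent_only=False, p_keep=0.6, ensure_nonempty=True):
    """Random pairwise class sets over all (or adjacent) pairs."""
    all9 = list(itertools.product((-1, 0, 1), repeat=2))
    pairs = (
        [(d, d + 1) for d in range(D - 1)]
        if adjacent_only
        else [(r, t) for r in range(D - 1) for t in range(r + 1, D)]
    )
    sets = {}
    for pair in pairs:
        keep = [v for v in all9 if rng.random() < p_keep]
        if ensure_nonempty and not keep:
            keep = [all9[rng.integers(9)]]
        sets[pair] = set(keep)
    return sets


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
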