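import itertools
from math import comb

import numpy as np
import pytest

from ternmix.labelgraph import CandidateSet
from ternmix.model import AssociationVector, validate_constraints, ConstrainedClassParams
from ternmix.pairwise import PairwiseClassSet, PairwiseFit
from ternmix.weights import (
    SampledLabels,
    _code,
    assemble_hyperparameters,
    delta_search_range,
    estimate_alpha,
    prune_by_alpha,
    sample_pairwise_labels,
    select_delta,
)


def make_fit(pair, vectors, resp):
    """Minimal pairwise fit carrying only what Step 3 consumes."""
    params = [
        ConstrainedClassParams(
            AssociationVector(v),
            np.array([2.0 * v[0], 2.0 * v[1]]),
            np.array(
                [
                    [1.0, 0.5 * v[0] * v[1]],
                    [0.5 * v[0] * v[1], 1.0],
                ]
            ),
        )
        for v in vectors
    ]
    resp = np.asarray(resp, float)
    return PairwiseFit(
        class_set=PairwiseClassSet(pair, [p.h for p in params]),
        params=params,
        weights=resp.mean(axis=0),
        responsibilities=resp,
        loglik_trace=[],
        converged=True,
    )


def labels_from_truth(vectors, D):
    """Noiseless sampled labels: every pair label matches the truth row."""
    pairs = [(r, t) for r in range(D - 1) for t in range(r + 1, D)]
    codes = {
        p: np.array([_code(v[p[0]], v[p[1]]) for v in vectors]) for p in pairs
    }
    return SampledLabels(n=len(vectors), D=D, codes=codes)


class TestSamplePairwiseLabels:
    def test_concentrated_responsibilities_give_argmax(self):
        resp = np.zeros((6, 2))
        resp[:3, 0] = 1.0
        resp[3:, 1] = 1.0
        fit = make_fit((0, 1), [(0, 0), (1, 1)], resp)
        out = sample_pairwise_labels({(0, 1): fit}, seed=0)
        expect = np.array([_code(0, 0)] * 3 + [_code(1, 1)] * 3)
        np.testing.assert_array_equal(out.codes[(0, 1)], expect)

    def test_uniform_responsibilities_balanced(self):
        n = 10_000
        fit = make_fit((0, 1), [(0, 0), (1, 1)], np.full((n, 2), 0.5))
        out = sample_pairwise_labels({(0, 1): fit}, seed=1)
        frac = np.mean(out.codes[(0, 1)] == _code(0, 0))
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        resp = rng.dirichlet((1.0, 1.0), size=200)
        fit = make_fit((0, 1), [(0, 0), (0, 1)], resp)
        a = sample_pairwise_labels({(0, 1): fit}, seed=7)
        b = sample_pairwise_labels({(0, 1): fit}, seed=7)
        np.testing.assert_array_equal(a.codes[(0, 1)], b.codes[(0, 1)])


class TestEstimateAlpha:
    def test_single_matching_candidate_gets_all_weight(self):
        truth = [AssociationVector((1, 0, 1))] * 10
        samples = labels_from_truth(truth, D=3)
        cands = CandidateSet([AssociationVector((1, 0, 1)), AssociationVector((0, 0, 0))])
        est = estimate_alpha(samples, cands, delta=0)
        np.testing.assert_allclose(est.alpha, [1.0, 0.0])

    def test_noiseless_labels_recover_proportions_exactly(self):
        truth = [AssociationVector((1, 1, 0))] * 7 + [AssociationVector((0, 0, 0))] * 3
        samples = labels_from_truth(truth, D=3)
        cands = CandidateSet([AssociationVector((0, 0, 0)), AssociationVector((1, 1, 0))])
        est = estimate_alpha(samples, cands, delta=0)
        np.testing.assert_allclose(est.alpha, [0.3, 0.7])

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_counting(self, trial):
        rng = np.random.default_rng(3000 + trial)
        D = int(rng.integers(3, 5))
        n = int(rng.integers(5, 21))
        pairs = [(r, t) for r in range(D - 1) for t in range(r + 1, D)]
        codes = {p: rng.integers(0, 9, size=n) for p in pairs}
        samples = SampledLabels(n=n, D=D, codes=codes)
        cands = CandidateSet(
            list(
                {
                    AssociationVector(tuple(rng.integers(-1, 2, size=D)))
                    for _ in range(4)
                }
            )
        )
        delta = int(rng.integers(0, len(pairs)))
        # exhaustive oracle over observations x candidates
        counts = []
        for h in cands.vectors:
            c = 0
            for i in range(n):
                agree = sum(
                    codes[(r, t)][i] == _code(h[r], h[t]) for (r, t) in pairs
                )
                c += agree >= len(pairs) - delta
            counts.append(c)
        if sum(counts) == 0:
            with pytest.raises(ValueError):
                estimate_alpha(samples, cands, delta)
        else:
            est = estimate_alpha(samples, cands, delta)
            np.testing.assert_allclose(est.alpha, np.array(counts) / sum(counts))

    def test_full_delta_makes_everything_concordant(self):
        truth = [AssociationVector((1, 1))] * 4
        samples = labels_from_truth(truth, D=2)
        cands = CandidateSet([AssociationVector((0, 0)), AssociationVector((-1, -1))])
        est = estimate_alpha(samples, cands, delta=comb(2, 2))
        np.testing.assert_allclose(est.alpha, [0.5, 0.5])

    def test_monotone_counts_in_delta(self, rng):
        D, n = 4, 50
        pairs = [(r, t) for r in range(D - 1) for t in range(r + 1, D)]
        codes = {p: rng.integers(0, 9, size=n) for p in pairs}
        samples = SampledLabels(n=n, D=D, codes=codes)
        cands = CandidateSet([AssociationVector((0,) * D), AssociationVector((1,) * D)])
        prev = None
        for delta in range(len(pairs) + 1):
            try:
                counts = estimate_alpha(samples, cands, delta).counts
            except ValueError:
                counts = np.zeros(2)
            if prev is not None:
                assert np.all(counts >= prev)
            prev = counts

    def test_delta_out_of_range(self):
        samples = labels_from_truth([AssociationVector((0, 0))], D=2)
        with pytest.raises(ValueError):
            estimate_alpha(samples, CandidateSet([AssociationVector((0, 0))]), delta=5)


class TestSelectDelta:
    def test_search_upper_bound_matches_stated_rule(self):
        assert delta_search_range(comb(18, 2), "well_separated") == (0, 22)
        lo, hi = delta_search_range(comb(18, 2), "weakly_separated")
        assert (lo, hi) == (23, 45)

    def test_insensitive_weights_return_range_minimum(self):
        truth = [AssociationVector((1, 1, 1, 1))] * 30 + [
            AssociationVector((0, 0, 0, 0))
        ] * 30
        samples = labels_from_truth(truth, D=4)
        cands = CandidateSet(
            [AssociationVector((0, 0, 0, 0)), AssociationVector((1, 1, 1, 1))]
        )
        assert select_delta(samples, cands, "well_separated") == 0

    def test_plateau_located_when_small_class_needs_tolerance(self):
        """One small class only becomes visible at delta >= 2: its members'
        labels each disagree with the candidate on exactly 2 pairs."""
        D = 6
        n_pairs = comb(D, 2)
        big = [AssociationVector((0,) * D)] * 200
        small_vec = AssociationVector((1,) * D)
        samples = labels_from_truth(big + [small_vec] * 40, D=D)
        # corrupt two pair labels of every small-class row
        for p in [(0, 1), (2, 3)]:
            samples.codes[p][200:] = _code(0, 0)
        cands = CandidateSet([AssociationVector((0,) * D), small_vec])
        delta = select_delta(samples, cands, "well_separated", c=2)
        assert delta == 2


class TestPruneByAlpha:
    def test_threshold_arithmetic(self):
        cands = CandidateSet(
            [AssociationVector((a,) * 5) for a in (0, 1, -1)]
        )
        from ternmix.weights import AlphaEstimate

        est = AlphaEstimate(
            vectors=list(cands.vectors),
            alpha=np.array([0.99, 0.006, 0.004]),
            delta=0,
            counts=np.array([990, 6, 4]),
        )
        pruned, out = prune_by_alpha(cands, est, n=1000, D=5)
        assert [v.labels for v in pruned] == [(0,) * 5, (1,) * 5]
        np.testing.assert_allclose(out.alpha.sum(), 1.0)

    def test_zero_alpha_always_pruned_and_oracle_filter(self, rng):
        vectors = list(
            {AssociationVector(tuple(rng.integers(-1, 2, size=4))) for _ in range(50)}
        )
        alpha = rng.dirichlet(np.full(len(vectors), 0.2))
        alpha[0] = 0.0
        alpha = alpha / alpha.sum()
        from ternmix.weights import AlphaEstimate

        est = AlphaEstimate(vectors=vectors, alpha=alpha, delta=0, counts=alpha * 500)
        n, D = 500, 4
        keep_oracle = [v for v, a in zip(vectors, alpha) if n * a > D]
        if not keep_oracle:
            with pytest.raises(ValueError):
                prune_by_alpha(CandidateSet(vectors), est, n, D)
        else:
            pruned, _ = prune_by_alpha(CandidateSet(vectors), est, n, D)
            assert pruned.vectors == keep_oracle
            assert vectors[0] not in pruned

    def test_all_pruned_is_error(self):
        cands = CandidateSet([AssociationVector((0, 0))])
        from ternmix.weights import AlphaEstimate

        est = AlphaEstimate(vectors=list(cands.vectors), alpha=np.array([1.0]), delta=0, counts=np.array([1]))
        with pytest.raises(ValueError):
            prune_by_alpha(cands, est, n=2, D=2)


class TestAssembleHyperparameters:
    def _alpha(self, vectors, values):
        from ternmix.weights import AlphaEstimate

        return AlphaEstimate(
            vectors=vectors, alpha=np.array(values), delta=0, counts=np.array(values)
        )

    def test_single_pair_equals_pair_estimates(self):
        resp = np.full((100, 2), 0.5)
        fit = make_fit((0, 1), [(0, 0), (1, 1)], resp)
        cands = CandidateSet([AssociationVector((0, 0)), AssociationVector((1, 1))])
        alpha = self._alpha(list(cands.vectors), [0.5, 0.5])
        hyper = assemble_hyperparameters({(0, 1): fit}, cands, alpha, n=100)
        m = 1  # the (1,1) class
        np.testing.assert_allclose(hyper.mu0[m], fit.params[1].mu)
        implied = hyper.psi0[m] / (hyper.nu[m] - 2 - 1)
        np.testing.assert_allclose(implied, fit.params[1].sigma, atol=1e-8)

    def test_identical_per_pair_estimates_average_to_common_value(self):
        vec3 = (1, 1, 1)
        fits = {
            p: make_fit(p, [(0, 0), (1, 1)], np.full((60, 2), 0.5))
            for p in [(0, 1), (0, 2), (1, 2)]
        }
        cands = CandidateSet([AssociationVector((0, 0, 0)), AssociationVector(vec3)])
        alpha = self._alpha(list(cands.vectors), [0.5, 0.5])
        hyper = assemble_hyperparameters(fits, cands, alpha, n=60)
        np.testing.assert_allclose(hyper.mu0[1], [2.0, 2.0, 2.0])

    def test_null_class_prior_is_standard(self):
        fit = make_fit((0, 1), [(0, 0)], np.ones((50, 1)))
        cands = CandidateSet([AssociationVector((0, 0))])
        alpha = self._alpha(list(cands.vectors), [1.0])
        hyper = assemble_hyperparameters({(0, 1): fit}, cands, alpha, n=50)
        np.testing.assert_allclose(hyper.mu0[0], 0.0)
        implied = hyper.psi0[0] / (hyper.nu[0] - 2 - 1)
        np.testing.assert_allclose(implied, np.eye(2))

    def test_missing_pairwise_class_falls_back_with_warning(self, caplog):
        import logging

        fit = make_fit((0, 1), [(0, 0)], np.ones((50, 1)))
        cands = CandidateSet([AssociationVector((1, 1))])
        alpha = self._alpha(list(cands.vectors), [1.0])
        with caplog.at_level(logging.WARNING):
            hyper = assemble_hyperparameters({(0, 1): fit}, cands, alpha, n=50)
        assert any("defaults" in r.message for r in caplog.records)
        assert hyper.mu0[0][0] > 0  # sign-compatible fallback

    def test_kappa_nu_floor(self):
        fit = make_fit((0, 1), [(0, 0), (1, 1)], np.full((30, 2), 0.5))
        cands = CandidateSet([AssociationVector((0, 0)), AssociationVector((1, 1))])
        alpha = self._alpha(list(cands.vectors), [0.9, 0.1])
        hyper = assemble_hyperparameters({(0, 1): fit}, cands, alpha, n=30)
        # n * 0.1 = 3 < D + 2 = 4 -> floored
        assert hyper.nu[1] == 4.0
        assert hyper.kappa[1] == hyper.nu[1]
        np.testing.assert_allclose(hyper.dirichlet, [27.0, 3.0])
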