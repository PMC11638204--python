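import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from _oracles import brute_std_tau, brute_weighted_tau
from tfkey.rankcorr import (PairedRanks, WeightVector, align_ranks,
                            estimate_densities, make_weights, normalize_scheme,
                            pairs_from_scores, permutation_p, std_tau,
                            association_test, weighted_tau)


def _pairs_with_ranks(ranks):
    """PairedRanks with prescribed list ranks (set side = identity)."""
    ranks = np.asarray(ranks, dtype=np.int64)
    n = ranks.size
    return PairedRanks(genes=tuple(f"g{i}" for i in range(n)),
                       set_scores=np.arange(n, 0, -1, dtype=float),
                       list_scores=(n - ranks).astype(float),
                       ranks=ranks)


class TestAlign:
    def test_hand_example(self):
        pairs = align_ranks({"g1": 3, "g2": 2, "g3": 1},
                            {"g2": 5, "g3": -1, "g4": 0.2}, min_overlap=2)
        assert pairs.genes == ("g2", "g3")
        assert pairs.ranks.tolist() == [1, 2]
        assert pairs.testable

    def test_disjoint_inputs_flagged_untestable(self):
        pairs = align_ranks({"a": 1.0}, {"b": 2.0}, min_overlap=2)
        assert not pairs.testable
        with pytest.raises(ValueError, match="untestable"):
            std_tau(pairs)

    def test_identical_ordering_gives_identity_ranks(self, rng):
        scores = {f"g{i}": float(s) for i, s in
                  enumerate(rng.standard_normal(10))}
        pairs = align_ranks(scores, {g: 2 * v + 1 for g, v in scores.items()},
                            min_overlap=2)
        assert pairs.ranks.tolist() == list(range(1, 11))

    def test_ties_broken_by_gene_id_with_warning(self):
        gene_set = {"a": 3.0, "b": 2.0, "c": 1.0}
        gene_list = {"a": 1.0, "b": 1.0, "c": 0.5}
        with pytest.warns(RuntimeWarning, match="tied"):
            pairs = align_ranks(gene_set, gene_list, min_overlap=2)
        assert pairs.ranks.tolist() == [1, 2, 3]
        assert pairs.n_list_ties == 1


class TestStdTau:
    @pytest.mark.parametrize("ranks,expected", [
        ((1, 2, 3), 1.0),
        ((3, 2, 1), -1.0),
        ((1, 3, 2), 1.0 / 3.0),
    ])
    def test_small_examples(self, ranks, expected):
        assert std_tau(_pairs_with_ranks(ranks)).tau == pytest.approx(
            expected, abs=1e-15)

    def test_z_closed_form_n10(self):
        res = std_tau(_pairs_with_ranks(range(1, 11)))
        assert res.tau == pytest.approx(1.0)
        assert res.z == pytest.approx(3 * np.sqrt(90 / 50), abs=1e-12)

    def test_matches_scipy_kendalltau(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            x, y = rng.standard_normal((2, n))
            pairs = pairs_from_scores(x, y)
            ref = stats.kendalltau(x, y)  # tau-b == tau-a without ties
            res = std_tau(pairs)
            assert res.tau == pytest.approx(ref.statistic, abs=1e-12)


class TestWeights:
    def test_linear_scheme_endpoints(self):
        pairs = _pairs_with_ranks(range(1, 11))
        v = make_weights(pairs, 2).v
        assert v[0] == pytest.approx(0.95)
        assert v[-1] == pytest.approx(0.05)

    def test_mix_linear_reduces_on_diagonal(self):
        # equal set/list ranks: geometric mean of equal terms is the term
        pairs = _pairs_with_ranks(range(1, 9))
        v = make_weights(pairs, 1).v
        expected = 1 - (np.arange(1, 9) - 0.5) / 8
        assert v == pytest.approx(expected, abs=1e-12)

    def test_density_scheme_upweights_isolated_scores(self):
        lst = np.array([-2.0, -1.9, 0.0, 0.1, 2.0, 2.1, 5.0])
        pairs = pairs_from_scores(np.arange(7.0, 0, -1), lst, min_overlap=2)
        w = make_weights(pairs, 8)
        v_by_score = dict(zip(pairs.list_scores, w.v))
        assert max(v_by_score, key=v_by_score.get) == 5.0

    def test_degenerate_scores_error_for_density_schemes(self):
        with pytest.warns(RuntimeWarning, match="tied"):
            pairs = pairs_from_scores(np.arange(6.0), np.full(6, 1.0),
                                      min_overlap=2)
        with pytest.raises(ValueError, match="rank-based"):
            estimate_densities(pairs)

    def test_scheme_aliases(self):
        assert normalize_scheme("w7") == 7
        assert normalize_scheme("LINEAR") == 2
        assert normalize_scheme(0) == 0
        with pytest.raises(ValueError):
            normalize_scheme(3)


class TestWeightedTau:
    def test_constant_weights_reproduce_std_tau_exhaustively(self):
        for perm in itertools.permutations(range(1, 6)):
            pairs = _pairs_with_ranks(perm)
            ref = std_tau(pairs)
            res = weighted_tau(pairs, WeightVector(scheme=0,
                                                   v=np.full(5, 0.7)))
            assert res.tau == pytest.approx(ref.tau, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 51))
            ranks = rng.permutation(n) + 1
            v = rng.uniform(1e-3, 1.0, n)
            res = weighted_tau(_pairs_with_ranks(ranks),
                               WeightVector(scheme=0, v=v))
            assert res.tau == pytest.approx(
                brute_weighted_tau(ranks, v), abs=1e-12)

    def test_spec_n4_example_against_oracle(self):
        ranks = np.array([2, 1, 4, 3])
        v = np.array([1.0, 0.8, 0.6, 0.4])
        res = weighted_tau(_pairs_with_ranks(ranks),
                           WeightVector(scheme=0, v=v))
        assert res.tau == pytest.approx(brute_weighted_tau(ranks, v),
                                        abs=1e-15)

    def test_identity_permutation_gives_tau_one(self, rng):
        pairs = _pairs_with_ranks(range(1, 13))
        v = rng.uniform(0.1, 1.0, 12)
        assert weighted_tau(pairs, WeightVector(scheme=0, v=v)).tau == \
            pytest.approx(1.0)

    def test_antisymmetry_under_rank_reversal(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            ranks = rng.permutation(n) + 1
            v = rng.uniform(0.05, 1.0, n)
            w = WeightVector(scheme=0, v=v)
            t1 = weighted_tau(_pairs_with_ranks(ranks), w).tau
            t2 = weighted_tau(_pairs_with_ranks(n + 1 - ranks), w).tau
            assert t1 == pytest.approx(-t2, abs=1e-14)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(perm=st.permutations(list(range(1, 13))),
           v=st.lists(st.floats(0.01, 1.0), min_size=12, max_size=12))
    def test_tau_bounds_and_reversal_property(self, perm, v):
        """|tau_w| <= 1 for any ranks/weights, and reversing the list
        ordering negates the statistic exactly."""
        ranks = np.array(perm, dtype=np.int64)
        w = WeightVector(scheme=0, v=np.array(v))
        t = weighted_tau(_pairs_with_ranks(ranks), w).tau
        assert -1.0 - 1e-12 <= t <= 1.0 + 1e-12
        t_rev = weighted_tau(_pairs_with_ranks(13 - ranks), w).tau
        assert t == pytest.approx(-t_rev, abs=1e-12)

    def test_all_schemes_give_valid_results(self, rng):
        x = rng.standard_normal(80)
        y = 0.5 * x + rng.standard_normal(80)
        pairs = pairs_from_scores(x, y)
        for scheme in (0, 1, 2, 7, 8):
            res = association_test(pairs, scheme)
            assert -1 <= res.tau <= 1
            assert 0 < res.p <= 1
            assert res.direction == np.sign(res.tau)
            assert res.scheme == scheme


class TestPermutationNull:
    def test_same_seed_reproduces_p(self, rng):
        pairs = pairs_from_scores(*rng.standard_normal((2, 40)))
        w = make_weights(pairs, 1)
        p1 = permutation_p(pairs, w, n_perm=199, seed=5)
        p2 = permutation_p(pairs, w, n_perm=199, seed=5)
        assert p1 == p2

    def test_strong_concordance_is_significant(self, rng):
        pairs = _pairs_with_ranks(range(1, 9))
        w = make_weights(pairs, 1)
        assert permutation_p(pairs, w, n_perm=999, seed=1) <= 0.025

    @pytest.mark.parametrize("scheme", [0, 1, 7])
    def test_agrees_with_asymptotic_p(self, rng, scheme):
        # moderate alternatives at n = 250: the normal approximation and the
        # co-moving permutation null should agree closely (the permutation
        # side itself carries Monte-Carlo noise of about +/-0.015)
        diffs = []
        for rep in range(4):
            x = rng.standard_normal(250)
            y = 0.12 * x + rng.standard_normal(250)
            pairs = pairs_from_scores(x, y)
            res = association_test(pairs, scheme)
            w = make_weights(pairs, scheme)
            p_perm = permutation_p(pairs, w, n_perm=999, seed=rep)
            diffs.append(abs(res.p - p_perm))
        assert np.median(diffs) <= 0.02
        assert max(diffs) <= 0.06
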