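import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopfs import info_theory as it
from coopfs import shapley

import oracles


def feat(codes, n_bins=None):
    codes = np.asarray(codes)
    if n_bins is None:
        n_bins = int(codes.max()) + 1
    return it.DiscretizedFeature(codes, n_bins)


def random_cache(rng, n):
    qmi = rng.uniform(0, 1, n)
    cmi = rng.uniform(0, 1, (n, n))
    np.fill_diagonal(cmi, 0.0)
    return shapley.PairwiseCache(qmi, cmi)


CONST_ONE = it.UtilitySpec("constant_one")


class TestCache:
    def test_duplicate_feature_cmi_zero(self):
        f = feat([0, 1, 0, 1, 1, 0])
        cls = feat([0, 0, 1, 1, 0, 1])
        cache = shapley.build_pairwise_cache([f, feat(f.codes.copy())], cls, CONST_ONE)
        assert cache.cmi_given[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_one_gives_plain_mi(self):
        rng = np.random.default_rng(0)
        feats = [feat(rng.integers(0, 3, 60), 3) for _ in range(4)]
        cls = feat(rng.integers(0, 2, 60), 2)
        cache = shapley.build_pairwise_cache(feats, cls, CONST_ONE)
        for j, f in enumerate(feats):
            assert cache.qmi_class[j] == pytest.approx(it.mutual_information(f, cls), abs=1e-14)

    def test_entries_match_direct_calls(self):
        """Vectorized cache equals per-pair info_theory calls to 1e-12."""
        rng = np.random.default_rng(1)
        feats = [feat(rng.integers(0, rng.integers(2, 6), 100)) for _ in range(5)]
        cls = feat(rng.integers(0, 2, 100), 2)
        cache = shapley.build_pairwise_cache(feats, cls, CONST_ONE)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                direct = it.conditional_mutual_information(feats[j], cls, feats[i])
                assert cache.cmi_given[i, j] == pytest.approx(direct, abs=1e-12)

    def test_fisher_utility_scales_qmi(self):
        rng = np.random.default_rng(2)
        feats = [feat(rng.integers(0, 3, 40), 3) for _ in range(3)]
        cls = feat(rng.integers(0, 2, 40), 2)
        utils = [it.UtilitySpec("fisher", v) for v in (0.5, 2.0, 7.0)]
        cache = shapley.build_pairwise_cache(feats, cls, utils)
        plain = shapley.build_pairwise_cache(feats, cls, CONST_ONE)
        assert np.allclose(cache.qmi_class, plain.qmi_class * [0.5, 2.0, 7.0], atol=1e-13)


class TestInterdependence:
    def test_duplicate_is_redundant(self):
        f = feat([0, 1, 0, 1, 1, 0])
        cls = feat([0, 0, 1, 1, 0, 1])
        cache = shapley.build_pairwise_cache([f, feat(f.codes.copy())], cls, CONST_ONE)
        assert shapley.interdependence_index(0, 1, cache) == 0

    def test_xor_pair_is_interdependent(self):
        fi = feat([0, 0, 1, 1])
        fj = feat([0, 1, 0, 1])
        cls = feat([0, 1, 1, 0])  # class = fi xor fj
        cache = shapley.build_pairwise_cache([fi, fj], cls, CONST_ONE)
        assert cache.cmi_given[0, 1] == pytest.approx(1.0, abs=1e-15)
        assert cache.qmi_class[1] == pytest.approx(0.0, abs=1e-15)
        assert shapley.interdependence_index(0, 1, cache) == 1

    def test_tie_counts_as_redundant(self):
        cache = shapley.PairwiseCache(np.array([0.0, 0.0]), np.zeros((2, 2)))
        assert shapley.interdependence_index(0, 1, cache) == 0

    def test_self_rejected(self):
        cache = random_cache(np.random.default_rng(3), 4)
        with pytest.raises(ValueError):
            shapley.interdependence_index(2, 2, cache)


class TestSetRelevance:
    def test_singleton(self):
        cache = shapley.PairwiseCache(np.array([0.2, 0.4, 0.6]), np.zeros((3, 3)))
        assert shapley.set_relevance([1], cache) == pytest.approx(0.4)

    def test_mean_of_three(self):
        cache = shapley.PairwiseCache(np.array([0.2, 0.4, 0.6]), np.zeros((3, 3)))
        assert shapley.set_relevance([0, 1, 2], cache) == pytest.approx(0.4)

    def test_empty_rejected(self):
        cache = random_cache(np.random.default_rng(4), 3)
        with pytest.raises(ValueError):
            shapley.set_relevance([], cache)


class TestRelevanceChange:
    def test_two_term_mean(self):
        qmi = np.array([0.0, 0.2, 0.5])
        cmi = np.zeros((3, 3))
        cmi[0, 1] = 0.5   # term +0.3
        cmi[0, 2] = 0.4   # term -0.1
        cache = shapley.PairwiseCache(qmi, cmi)
        assert shapley.relevance_change([1, 2], 0, cache) == pytest.approx(0.1, abs=1e-14)

    def test_duplicates_non_positive(self):
        f = feat([0, 1, 0, 1, 1, 0])
        cls = feat([0, 0, 1, 1, 0, 1])
        feats = [f, feat(f.codes.copy()), feat(f.codes.copy())]
        cache = shapley.build_pairwise_cache(feats, cls, CONST_ONE)
        assert shapley.relevance_change([1, 2], 0, cache) <= 0.0

    def test_member_of_K_rejected(self):
        cache = random_cache(np.random.default_rng(5), 4)
        with pytest.raises(ValueError):
            shapley.relevance_change([0, 1], 1, cache)


class TestCoalitionPayoff:
    def test_negative_change_blocks(self):
        qmi = np.array([0.0, 1.0, 1.0])
        cmi = np.zeros((3, 3))
        cmi[0, 1] = 2.0  # psi true for j=1
        cache = shapley.PairwiseCache(qmi, cmi)
        # change = ((2-1) + (0-1))/2 = 0 -> allowed; force negative:
        cmi[0, 1] = 0.5
        cache = shapley.PairwiseCache(qmi, cmi)
        assert shapley.coalition_payoff([1, 2], 0, cache) == 0

    def test_boundary_half_interdependence(self):
        # |K| = 2, psi sum exactly 1 >= 1 and change >= 0 -> payoff 1
        qmi = np.array([0.0, 0.0, 0.1])
        cmi = np.zeros((3, 3))
        cmi[0, 1] = 0.2  # psi(0,1)=1, term +0.2
        cmi[0, 2] = 0.0  # psi(0,2)=0, term -0.1
        cache = shapley.PairwiseCache(qmi, cmi)
        assert shapley.coalition_payoff([1, 2], 0, cache) == 1

    def test_duplicate_pair_fails_psi(self):
        f = feat([0, 1, 0, 1, 1, 0])
        cls = feat([0, 0, 1, 1, 0, 1])
        feats = [f, feat(f.codes.copy()), feat(f.codes.copy())]
        cache = shapley.build_pairwise_cache(feats, cls, CONST_ONE)
        assert shapley.coalition_payoff([1, 2], 0, cache) == 0


class TestShapleyValue:
    def test_zero_payoffs(self):
        cache = shapley.PairwiseCache(np.ones(4), np.zeros((4, 4)))
        assert shapley.shapley_value(0, cache, 2) == 0.0

    def test_all_qualifying_n4_k2(self):
        # all 3 coalitions qualify: phi = 3 * 2!*1!/4! = 0.25
        qmi = np.zeros(4)
        cmi = np.full((4, 4), 0.5)
        np.fill_diagonal(cmi, 0.0)
        cache = shapley.PairwiseCache(qmi, cmi)
        assert shapley.shapley_value(0, cache, 2) == pytest.approx(0.25, abs=1e-15)

    def test_invalid_coalition_size(self):
        cache = random_cache(np.random.default_rng(6), 4)
        with pytest.raises(ValueError):
            shapley.shapley_value(0, cache, 0)
        with pytest.raises(ValueError):
            shapley.shapley_value(0, cache, 4)

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(min_value=0, max_value=2**31),
        n=st.integers(min_value=4, max_value=9),
        k=st.integers(min_value=1, max_value=3),
    )
    def test_matches_enumeration_oracle(self, seed, n, k):
        if k >= n:
            return
        cache = random_cache(np.random.default_rng(seed), n)
        qmi = cache.qmi_class.tolist()
        cmi = cache.cmi_given.tolist()
        fast = shapley.weights_from_cache(cache, k)
        for i in range(n):
            expected = oracles.shapley_bf(i, qmi, cmi, k)
            assert shapley.shapley_value(i, cache, k) == expected
            assert fast.phi[i] == expected


class TestComputeAllWeights:
    def test_all_duplicates_zero_phi(self):
        f = feat([0, 1, 0, 1, 1, 0])
        cls = feat([0, 0, 1, 1, 0, 1])
        feats = [feat(f.codes.copy()) for _ in range(4)]
        w = shapley.compute_all_weights(feats, cls, CONST_ONE, 2)
        assert np.all(w.phi == 0.0)

    def test_xor_pairs_beat_noise(self):
        """Two planted XOR pairs earn strictly larger phi than noise, 10 seeds.

        Exact 2^5 factorial design so empirical independence is exact (with
        sampled noise the plug-in CMI bias saturates every phi at 1/n).  Each
        XOR member qualifies exactly in the 4 pairs containing its partner:
        phi = 4 * 2! * 3! / 6! = 1/15; noise features qualify nowhere.
        """
        bits = np.array([[(r >> s) & 1 for s in range(5)] for r in range(32)])
        a, b, c, n1, n2 = (np.repeat(bits[:, s], 2) for s in range(5))
        cls_codes = a ^ b
        d = c ^ cls_codes
        for seed in range(10):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(a.size)
            feats = [feat(v[perm], 2) for v in (a, b, c, d, n1, n2)]
            w = shapley.compute_all_weights(feats, feat(cls_codes[perm], 2), CONST_ONE, 2)
            assert np.allclose(w.phi[:4], 4 * 12 / 720)
            assert np.all(w.phi[4:] == 0.0)
            assert min(w.phi[:4]) > max(w.phi[4:])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        feats = [feat(rng.integers(0, 3, 80), 3) for _ in range(6)]
        cls = feat(rng.integers(0, 2, 80), 2)
        w = shapley.compute_all_weights(feats, cls, CONST_ONE, 2)
        perm = rng.permutation(6)
        w_perm = shapley.compute_all_weights([feats[p] for p in perm], cls, CONST_ONE, 2)
        assert np.allclose(w_perm.phi, w.phi[perm], atol=1e-14)

    def test_monotonicity_in_payoffs(self):
        """Turning one coalition's payoff on never decreases phi_i."""
        rng = np.random.default_rng(8)
        cache = random_cache(rng, 6)
        base = shapley.shapley_value(0, cache, 2)
        # force coalition {1, 2} to qualify for feature 0
        cmi = cache.cmi_given.copy()
        cmi[0, 1] = cache.qmi_class[1] + 1.0
        cmi[0, 2] = cache.qmi_class[2] + 1.0
        boosted = shapley.shapley_value(0, shapley.PairwiseCache(cache.qmi_class, cmi), 2)
        assert boosted >= base

    def test_too_few_features(self):
        f = feat([0, 1, 0, 1])
        cls = feat([0, 0, 1, 1])
        with pytest.raises(ValueError):
            shapley.compute_all_weights([f, f], cls, CONST_ONE, 2)
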