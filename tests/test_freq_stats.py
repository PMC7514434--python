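import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodca.freq_stats import (StationaryStats, compare_stats,
                                 connected_correlations, count_frequencies,
                                 covariance_matrix, covariance_tensor,
                                 flatten_pair, flatten_site, hamming,
                                 reweighting_weights)
from phylodca.phylo_sim import Msa
from phylodca.potts_core import Alphabet

AB = Alphabet("AB")
ABCD = Alphabet("ACGT")


def make_msa(rows, alphabet=ABCD):
    rows = np.asarray(rows, dtype=np.int8)
    return Msa(rows, [f"s{i}" for i in range(len(rows))], alphabet)


class TestCountFrequencies:
    def test_identical_rows_one_hot(self):
        msa = make_msa([[0, 1, 2]] * 3)
        stats = count_frequencies(msa)
        assert np.allclose(stats.site[0], [1, 0, 0, 0])
        assert np.allclose(stats.site[1], [0, 1, 0, 0])

    def test_two_row_half_half(self):
        msa = make_msa([[0], [1]], alphabet=AB)
        stats = count_frequencies(msa, pairs=False)
        assert np.allclose(stats.site[0], [0.5, 0.5])

    def test_hand_tally_pair(self):
        msa = make_msa([[0, 0], [0, 1], [1, 0], [0, 0]], alphabet=AB)
        stats = count_frequencies(msa)
        tab = stats.get_pair(0, 1)
        assert np.allclose(tab, [[0.5, 0.25], [0.25, 0.0]])

    def test_weighted(self):
        msa = make_msa([[0], [1]], alphabet=AB)
        stats = count_frequencies(msa, weights=[3.0, 1.0], pairs=False)
        assert np.allclose(stats.site[0], [0.75, 0.25])

    def test_marginal_consistency(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(40, 6)))
        w = rng.random(40) + 0.1
        stats = count_frequencies(msa, weights=w)
        for i in range(6):
            for j in range(i + 1, 6):
                tab = stats.get_pair(i, j)
                assert np.allclose(tab.sum(axis=1), stats.site[i], atol=1e-10)
                assert np.allclose(tab.sum(axis=0), stats.site[j], atol=1e-10)
        assert np.allclose(stats.site.sum(axis=1), 1, atol=1e-10)
        assert np.allclose(stats.pair.sum(axis=(1, 2)), 1, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_frequencies(make_msa(np.zeros((0, 3))))


class TestConnectedCorrelations:
    def test_independent_product_is_zero(self, rng):
        site = rng.dirichlet(np.ones(3), size=4)
        pair = []
        for i in range(4):
            for j in range(i + 1, 4):
                pair.append(np.outer(site[i], site[j]))
        stats = StationaryStats(site=site, pair=np.array(pair))
        assert np.allclose(connected_correlations(stats), 0, atol=1e-12)

    def test_perfectly_covarying_binary(self):
        msa = make_msa([[0, 0], [1, 1], [0, 0], [1, 1]], alphabet=AB)
        c = connected_correlations(count_frequencies(msa))
        assert c[0][0, 0] == pytest.approx(0.25)

    def test_entries_sum_to_zero(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(30, 5)))
        c = connected_correlations(count_frequencies(msa))
        assert np.allclose(c.sum(axis=(1, 2)), 0, atol=1e-12)

    def test_requires_pair_tables(self):
        stats = StationaryStats(site=np.full((2, 2), 0.5))
        with pytest.raises(ValueError):
            connected_correlations(stats)

    def test_covariance_matrix_blocks(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(25, 3)))
        stats = count_frequencies(msa)
        C = covariance_matrix(stats)
        c = connected_correlations(stats)
        assert C.shape == (12, 12)
        assert np.allclose(C, C.T)
        assert np.allclose(C[0:4, 4:8], c[0])
        assert np.allclose(C[0:4, 0:4], 0)
        Cr = covariance_matrix(stats, drop_state=0)
        assert Cr.shape == (9, 9)
        assert np.allclose(Cr[0:3, 3:6], c[0][1:, 1:])

    def test_covariance_tensor_layout(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(20, 4)))
        stats = count_frequencies(msa)
        T = covariance_tensor(stats)
        c = connected_correlations(stats)
        assert np.allclose(T[0, 1], c[0])
        assert np.allclose(T[1, 0], 0)  # only i < j blocks are filled


class TestReweighting:
    def test_all_distant(self):
        data = np.array([[0, 1, 2, 3, 0],
                         [0, 1, 0, 1, 2],
                         [3, 2, 2, 3, 1]], dtype=np.int8)  # identities <= 0.6
        msa = make_msa(data)
        assert np.allclose(reweighting_weights(msa), 1.0)

    def test_duplicate_pair(self):
        base = np.array([0, 1, 2, 3, 0, 1, 2, 3, 0, 1], dtype=np.int8)
        far = (base + 2) % 4
        msa = make_msa([base, base, far])
        w = reweighting_weights(msa)
        assert np.allclose(w, [0.5, 0.5, 1.0])

    def test_k_copies_count_once(self):
        k = 5
        base = np.array([0, 1, 2, 3, 0], dtype=np.int8)
        rows = [base] * k + [(base + 1) % 4, (base + 2) % 4]
        msa = make_msa(rows)
        w = reweighting_weights(msa)
        assert np.allclose(w[:k], 1 / k)
        assert w[:k].sum() == pytest.approx(1.0)

    def test_permutation_invariant(self, rng):
        data = rng.integers(0, 2, size=(12, 5))
        msa = make_msa(data, alphabet=AB)
        w = reweighting_weights(msa)
        perm = rng.permutation(12)
        wp = reweighting_weights(make_msa(data[perm], alphabet=AB))
        assert np.allclose(w[perm], wp)


class TestHamming:
    def test_identical(self):
        assert hamming([0, 1, 2], [0, 1, 2]) == 0

    def test_fully_different(self):
        assert hamming(np.zeros(25), np.ones(25)) == 25

    def test_hand_count(self):
        assert hamming((0, 1, 1, 0), (0, 1, 0, 1)) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming([0, 1], [0, 1, 2])


class TestCompareStats:
    def test_identity(self):
        x = np.array([0.1, 0.2, 0.7, 0.4])
        res = compare_stats(x, x)
        assert res["pearson"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(1.0)

    def test_doubling(self):
        x = np.array([0.1, 0.2, 0.7, 0.4])
        res = compare_stats(x, 2 * x)
        assert res["pearson"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)

    def test_textbook_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        # closed forms: slope = cov(x,y)/var(x), r = cov/(sx sy)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        r = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        res = compare_stats(x, y)
        assert res["slope"] == pytest.approx(slope)
        assert res["pearson"] == pytest.approx(r)

    def test_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            compare_stats([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFlatten:
    def test_site_length(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(10, 6)))
        stats = count_frequencies(msa)
        assert flatten_site(stats).shape == (24,)
        assert flatten_site(stats, drop_dominant=True).shape == (18,)

    def test_pair_length(self, rng):
        msa = make_msa(rng.integers(0, 4, size=(10, 5)))
        stats = count_frequencies(msa)
        assert flatten_pair(stats).shape == (10 * 16,)


@settings(max_examples=25, deadline=None)
@given(st.integers(2, 12), st.integers(2, 5), st.integers(0, 10_000))
def test_frequency_invariants_property(M, L, seed):
    rng = np.random.default_rng(seed)
    msa = make_msa(rng.integers(0, 4, size=(M, L)))
    w = rng.random(M) + 0.05
    stats = count_frequencies(msa, weights=w)
    assert np.allclose(stats.site.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(stats.pair.sum(axis=(1, 2)), 1.0, atol=1e-10)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            assert np.allclose(stats.pair[k].sum(axis=1), stats.site[i], atol=1e-10)
            k += 1
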