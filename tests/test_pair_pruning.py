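import numpy as np
import pytest

import oracles
from phylodca.pair_pruning import (correct_all_pairs,
                                   fit_compensatory_fields,
                                   marginal_inconsistency,
                                   optimize_pair_frequencies,
                                   optimize_pair_unconstrained,
                                   pair_likelihood, pair_propagator)
from phylodca.phylo_sim import grow_binary_tree, sample_tree_msa
from phylodca.potts_core import Alphabet, PottsModel
from phylodca.site_pruning import (OptimizerSchedule, correct_all_sites,
                                   site_likelihood)


def random_joint(rng, q=4, concentration=1.0):
    w = rng.dirichlet(np.full(q * q, concentration)).reshape(q, q)
    return w / w.sum()


class TestPairPropagator:
    def test_zero_time_identity(self, rng):
        P = pair_propagator(random_joint(rng), mu=1.0, dt=0.0)
        assert np.allclose(P, np.eye(16), atol=1e-12)

    def test_rows_normalized(self, rng):
        for _ in range(100):
            P = pair_propagator(random_joint(rng), rng.uniform(0.1, 2),
                                rng.uniform(0.05, 3))
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)

    def test_stationarity(self, rng):
        for _ in range(100):
            w = random_joint(rng)
            P = pair_propagator(w, rng.uniform(0.1, 2), rng.uniform(0.05, 3))
            assert np.allclose(w.ravel() @ P, w.ravel(), atol=1e-10)

    def test_infinite_time_rows_equal_joint(self, rng):
        w = random_joint(rng)
        P = pair_propagator(w, 1.0, 1e9)
        assert np.allclose(P, np.tile(w.ravel(), (16, 1)), atol=1e-12)

    def test_matches_bruteforce_matrix(self, rng):
        w = random_joint(rng)
        P = pair_propagator(w, 0.7, 0.9)
        B = oracles.pair_propagator_matrix(w, 0.7, 0.9)
        assert np.allclose(P, B, atol=1e-12)

    def test_zero_marginal_signalled(self):
        w = np.zeros((2, 2))
        w[0, 0] = 1.0
        with pytest.raises(ValueError):
            pair_propagator(w, 1.0, 1.0)


class TestPairLikelihood:
    def test_single_leaf(self, rng):
        tree = oracles.make_tree([-1], ["A"], [0.0])
        w = random_joint(rng)
        ll = pair_likelihood([1], [3], tree, w, mu=1.0)
        assert ll == pytest.approx(np.log(w[1, 3]))

    def test_matches_bruteforce_small_trees(self, rng):
        for parent, labels in oracles.small_trees(max_leaves=3):
            for q in (2, 3):
                blen = rng.uniform(0.1, 1.2, size=len(parent))
                tree = oracles.make_tree(parent, labels, blen)
                w = random_joint(rng, q=q)
                mu = rng.uniform(0.3, 1.5)
                ci = rng.integers(0, q, size=tree.n_leaves)
                cj = rng.integers(0, q, size=tree.n_leaves)
                fast = pair_likelihood(ci, cj, tree, w, mu)
                brute = oracles.pair_tree_loglik_brute(tree, ci, cj, w, mu)
                assert fast == pytest.approx(brute, abs=1e-9)

    def test_bruteforce_four_leaves_q4(self, rng):
        parent, labels = [-1, 0, 0, 1, 1, 2, 2], ["A", "B", "C", "D"]
        tree = oracles.make_tree(parent, labels, rng.uniform(0.1, 1, 7))
        w = random_joint(rng, q=4)
        ci = rng.integers(0, 4, size=4)
        cj = rng.integers(0, 4, size=4)
        fast = pair_likelihood(ci, cj, tree, w, 0.8)
        brute = oracles.pair_tree_loglik_brute(tree, ci, cj, w, 0.8)
        assert fast == pytest.approx(brute, abs=1e-9)

    def test_product_table_factorizes_in_iid_limit(self, rng):
        tree = grow_binary_tree(3, 0.3)
        wi = rng.dirichlet(np.ones(4))
        wj = rng.dirichlet(np.ones(4))
        ci = rng.integers(0, 4, size=8)
        cj = rng.integers(0, 4, size=8)
        mu = 1e7
        joint = pair_likelihood(ci, cj, tree, np.outer(wi, wj), mu)
        split = (site_likelihood(ci, tree, wi, mu)
                 + site_likelihood(cj, tree, wj, mu))
        assert joint == pytest.approx(split, abs=1e-6)

    def test_product_table_factorizes_at_zero_time(self, rng):
        # dt = 0 everywhere: likelihood reduces to the root prior on the
        # (necessarily constant) leaf columns
        parent = [-1, 0, 0]
        tree = oracles.make_tree(parent, ["a", "b"], [0.0, 0.0, 0.0])
        wi = rng.dirichlet(np.ones(4))
        wj = rng.dirichlet(np.ones(4))
        joint = pair_likelihood([2, 2], [0, 0], tree, np.outer(wi, wj), 1.0)
        split = (site_likelihood([2, 2], tree, wi, 1.0)
                 + site_likelihood([0, 0], tree, wj, 1.0))
        assert joint == pytest.approx(np.log(wi[2] * wj[0]), abs=1e-10)
        assert joint == pytest.approx(split, abs=1e-10)


class TestCompensatoryFields:
    def test_zero_coupling_gives_product(self, rng):
        r = rng.dirichlet(np.ones(4))
        c = rng.dirichlet(np.ones(4))
        par = fit_compensatory_fields(np.zeros((4, 4)), r, c)
        assert np.allclose(par.omega, np.outer(r, c), atol=1e-12)

    def test_marginals_match_targets(self, rng):
        for _ in range(10):
            J = rng.normal(scale=1.5, size=(4, 4))
            r = rng.dirichlet(np.ones(4))
            c = rng.dirichlet(np.ones(4))
            par = fit_compensatory_fields(J, r, c)
            assert np.allclose(par.omega.sum(axis=1), r, atol=1e-10)
            assert np.allclose(par.omega.sum(axis=0), c, atol=1e-10)

    def test_q2_uniform_closed_form(self):
        # uniform margins, 2x2: with odds ratio theta = exp(J00+J11-J01-J10),
        # the diagonal entries are x = sqrt(theta)/(2 (1 + sqrt(theta)))
        J = np.array([[0.7, -0.2], [0.1, 0.4]])
        theta = np.exp(J[0, 0] + J[1, 1] - J[0, 1] - J[1, 0])
        x = 0.5 * np.sqrt(theta) / (1 + np.sqrt(theta))
        par = fit_compensatory_fields(J, np.array([0.5, 0.5]),
                                      np.array([0.5, 0.5]))
        assert par.omega[0, 0] == pytest.approx(x, abs=1e-9)
        assert par.omega[1, 1] == pytest.approx(x, abs=1e-9)

    def test_parameterization_consistent(self, rng):
        J = rng.normal(size=(3, 3))
        r = rng.dirichlet(np.ones(3))
        c = rng.dirichlet(np.ones(3))
        par = fit_compensatory_fields(J, r, c)
        rebuilt = np.exp(J + par.h_i[:, None] + par.h_j[None, :] - par.log_z)
        assert np.allclose(rebuilt, par.omega, atol=1e-8)

    def test_positive_targets_required(self):
        with pytest.raises(ValueError):
            fit_compensatory_fields(np.zeros((2, 2)), np.array([1.0, 0.0]),
                                    np.array([0.5, 0.5]))


class TestOptimizePair:
    def _setup(self, rng, K=5):
        model = PottsModel(2, 4, alphabet=Alphabet("ACGT"))
        model.h[:] = rng.normal(size=(2, 4))
        model.set_J(0, 1, 1.2 * np.eye(4))
        tree = grow_binary_tree(K, 0.3)
        msa = sample_tree_msa(model, tree, mu=0.4, seed=11)
        rows = tree.leaf_row_map(msa.labels)[tree.leaves]
        return tree, msa.data[rows, 0].astype(np.int64), msa.data[rows, 1].astype(np.int64)

    def test_improves_on_independence_baseline(self, rng):
        tree, ci, cj = self._setup(rng)
        wi = np.full(4, 0.25)
        wj = np.full(4, 0.25)
        w, trace = optimize_pair_frequencies(
            ci, cj, tree, 0.4, wi, wj, OptimizerSchedule(iters=600, seed=2))
        base = pair_likelihood(ci, cj, tree, np.outer(wi, wj), 0.4)
        final = pair_likelihood(ci, cj, tree, w, 0.4)
        assert final >= base
        assert (np.diff(trace) >= 0).all()

    def test_constraints_hold(self, rng):
        tree, ci, cj = self._setup(rng)
        wi = rng.dirichlet(np.ones(4) * 5)
        wj = rng.dirichlet(np.ones(4) * 5)
        w, _ = optimize_pair_frequencies(
            ci, cj, tree, 0.4, wi, wj, OptimizerSchedule(iters=400, seed=3))
        assert np.allclose(w.sum(axis=1), wi, atol=1e-8)
        assert np.allclose(w.sum(axis=0), wj, atol=1e-8)

    def test_deterministic(self, rng):
        tree, ci, cj = self._setup(rng)
        wi = np.full(4, 0.25)
        a, _ = optimize_pair_frequencies(ci, cj, tree, 0.4, wi, wi,
                                         OptimizerSchedule(iters=200, seed=5))
        b, _ = optimize_pair_frequencies(ci, cj, tree, 0.4, wi, wi,
                                         OptimizerSchedule(iters=200, seed=5))
        assert np.array_equal(a, b)


class TestCorrectAllPairs:
    @pytest.fixture(scope="class")
    def biased_sample(self):
        rng = np.random.default_rng(0)
        model = PottsModel(5, 4, h=0.5 * rng.normal(size=(5, 4)),
                           alphabet=Alphabet("ACGT"))
        model.set_J(0, 1, 1.0 * np.eye(4))
        model.set_J(2, 3, 0.8 * np.eye(4))
        tree = grow_binary_tree(6, 0.3)
        msa = sample_tree_msa(model, tree, mu=0.4, seed=21)
        site = correct_all_sites(msa, tree, 0.4,
                                 OptimizerSchedule(iters=500, seed=1))
        return model, tree, msa, site

    def test_table_count_and_marginals(self, biased_sample):
        _, tree, msa, site = biased_sample
        stats = correct_all_pairs(msa, tree, 0.4, site,
                                  OptimizerSchedule(iters=300, seed=2))
        assert stats.pair.shape == (10, 4, 4)
        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.allclose(stats.pair[k].sum(axis=1), stats.site[i],
                                   atol=1e-7)
                assert np.allclose(stats.pair[k].sum(axis=0), stats.site[j],
                                   atol=1e-7)
                k += 1
        assert np.allclose(marginal_inconsistency(stats), 0, atol=1e-6)

    def test_unconstrained_mode_shows_inconsistencies(self, biased_sample):
        _, tree, msa, site = biased_sample
        stats = correct_all_pairs(msa, tree, 0.4, site,
                                  OptimizerSchedule(iters=300, seed=3),
                                  constrain=False)
        assert marginal_inconsistency(stats).max() > 1e-3


class TestUnconstrainedOptimizer:
    def test_trace_nondecreasing(self, rng):
        tree = grow_binary_tree(4, 0.3)
        ci = rng.integers(0, 4, size=16)
        cj = rng.integers(0, 4, size=16)
        w, trace = optimize_pair_unconstrained(
            ci, cj, tree, 0.5, schedule=OptimizerSchedule(iters=300, seed=4))
        assert abs(w.sum() - 1) < 1e-8
        assert (np.diff(trace) >= 0).all()
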