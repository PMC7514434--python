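"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is written from first principles with explicit loops and
exhaustive enumeration; nothing imports the implementation under test except
for plain data containers (PottsModel, PhyloTree).
"""

from __future__ import annotations

import itertools

import numpy as np

from phylodca.phylo_sim import PhyloTree
from phylodca.potts_core import PottsModel


def brute_hamiltonian(model: PottsModel, seq) -> float:
    """Energy by explicit double loop over pairs and sites."""
    seq = list(int(s) for s in seq)
    e = 0.0
    for i in range(model.L):
        e += model.h[i, seq[i]]
        for j in range(i + 1, model.L):
            e += model.get_J(i, j)[seq[i], seq[j]]
    return -e


def enumerate_sequences(L: int, q: int):
    return itertools.product(range(q), repeat=L)


def exact_distribution(model: PottsModel) -> dict[tuple, float]:
    """Normalized Boltzmann weights over all q**L sequences."""
    energies = {s: brute_hamiltonian(model, s)
                for s in enumerate_sequences(model.L, model.q)}
    mx = min(energies.values())
    weights = {s: np.exp(-(e - mx)) for s, e in energies.items()}
    Z = sum(weights.values())
    return {s: w / Z for s, w in weights.items()}


def site_propagator_matrix(omega, mu, dt) -> np.ndarray:
    """P[a, b] = P(b | a, dt) built entry by entry."""
    q = len(omega)
    e = np.exp(-mu * dt)
    P = np.empty((q, q))
    for a in range(q):
        for b in range(q):
            P[a, b] = (e if a == b else 0.0) + (1.0 - e) * omega[b]
    return P


def pair_propagator_matrix(w, mu, dt) -> np.ndarray:
    """(q*q, q*q) pair-state propagator built entry by entry, (A,B) -> A*q+B."""
    w = np.asarray(w, dtype=float)
    q = w.shape[0]
    wi = w.sum(axis=1)
    wj = w.sum(axis=0)
    e = np.exp(-mu * dt)
    P = np.empty((q * q, q * q))
    for A in range(q):
        for B in range(q):
            for C in range(q):
                for D in range(q):
                    val = (1.0 - e) ** 2 * w[C, D]
                    if A == C:
                        val += e * (1.0 - e) * w[A, D] / wi[A]
                    if B == D:
                        val += e * (1.0 - e) * w[C, B] / wj[B]
                    if A == C and B == D:
                        val += e * e
                    P[A * q + B, C * q + D] = val
    return P


def _enumerate_tree_likelihood(tree: PhyloTree, leaf_states, n_states,
                               prior, trans) -> float:
    """Sum over all internal-node state assignments of the path probability.

    ``leaf_states[node]`` fixes leaf nodes (>= 0); ``prior`` is the root
    distribution, ``trans(parent_state, child_state, child_node)`` the edge
    probability.  Exponential in internal-node count: tiny trees only.
    """
    internal = [n for n in range(tree.n_nodes) if leaf_states[n] < 0]
    total = 0.0
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in range(tree.n_nodes):
            if leaf_states[n] >= 0:
                state[n] = int(leaf_states[n])
        p = prior[state[tree.root]]
        for n in range(tree.n_nodes):
            if n == tree.root:
                continue
            p *= trans(state[tree.parent[n]], state[n], n)
        total += p
    return np.log(total)


def site_tree_loglik_brute(tree: PhyloTree, column, omega, mu) -> float:
    """Column log-likelihood by exhaustive enumeration of internal states."""
    leaf_states = np.full(tree.n_nodes, -1, dtype=int)
    leaf_states[tree.leaves] = np.asarray(column, dtype=int)
    mats = {int(n): site_propagator_matrix(omega, mu, tree.branch_len[n])
            for n in range(tree.n_nodes)}

    def trans(a, b, node):
        return mats[int(node)][a, b]

    return _enumerate_tree_likelihood(tree, leaf_states, len(omega), omega, trans)


def pair_tree_loglik_brute(tree: PhyloTree, column_i, column_j, w, mu) -> float:
    """Pair log-likelihood by exhaustive enumeration over q^2 pair states."""
    w = np.asarray(w, dtype=float)
    q = w.shape[0]
    ci = np.asarray(column_i, dtype=int)
    cj = np.asarray(column_j, dtype=int)
    leaf_states = np.full(tree.n_nodes, -1, dtype=int)
    leaf_states[tree.leaves] = ci * q + cj
    mats = {int(n): pair_propagator_matrix(w, mu, tree.branch_len[n])
            for n in range(tree.n_nodes)}

    def trans(a, b, node):
        return mats[int(node)][a, b]

    return _enumerate_tree_likelihood(tree, leaf_states, q * q, w.ravel(), trans)


def factorized_symmetrized_kl(p: PottsModel, q_model: PottsModel) -> float:
    """Closed-form symmetrized KL for two independent-site (J = 0) models."""
    assert np.allclose(p.J, 0) and np.allclose(q_model.J, 0)
    total = 0.0
    for i in range(p.L):
        pp = np.exp(p.h[i] - p.h[i].max())
        pp /= pp.sum()
        qq = np.exp(q_model.h[i] - q_model.h[i].max())
        qq /= qq.sum()
        total += float(((pp - qq) * (np.log(pp) - np.log(qq))).sum())
    return total


def small_trees(max_leaves: int = 4, dt_rng=None):
    """Assorted rooted topologies with <= max_leaves leaves.

    Returns (parent array, label list) pairs; branch lengths are attached by
    the caller.  Includes unary root, cherries, caterpillars and polytomies.
    """
    shapes = [
        ([-1], ["A"]),                       # single-leaf tree
        ([-1, 0, 0], ["A", "B"]),            # cherry
        ([-1, 0, 0, 0], ["A", "B", "C"]),    # root trifurcation
        ([-1, 0, 0, 1, 1], ["A", "B", "C"]),  # caterpillar, 3 leaves
        ([-1, 0, 0, 1, 1, 2, 2], ["A", "B", "C", "D"]),  # balanced 4
        ([-1, 0, 0, 1, 1, 3, 3], ["A", "B", "C", "D"]),  # caterpillar 4
        ([-1, 0, 0, 0, 0], ["A", "B", "C", "D"]),        # root polytomy 4
    ]
    return [s for s in shapes if len(s[1]) <= max_leaves]


def make_tree(parent, labels, branch_lengths) -> PhyloTree:
    parent = np.asarray(parent)
    blen = np.asarray(branch_lengths, dtype=float).copy()
    blen[parent < 0] = 0.0
    return PhyloTree(parent, blen, labels)
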