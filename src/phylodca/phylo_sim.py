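"""Phylogenetic simulator: trees, MSAs, and sampling a Potts model on a tree.

The "biased" sample runs finite-time Gibbs dynamics down a clock tree; the
"fair" sample is a heavily thinned equilibrium Gibbs chain.  Both share the
same heat-bath move: a uniformly chosen site is redrawn from the conditional
distribution given the rest of the current sequence (a redraw may conserve
the state; it still counts as a mutation event).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import _kernels
from .potts_core import Alphabet, PottsModel

__all__ = ["Msa", "PhyloTree", "grow_binary_tree", "evolve_branch",
           "sample_tree_msa", "sample_iid", "from_newick", "to_newick"]

#: memory guard for grow_binary_tree
MAX_DUPLICATIONS = 22


@dataclass
class Msa:
    """Integer-encoded alignment: M rows x L columns over states 0..q-1."""

    data: np.ndarray
    labels: list[str]
    alphabet: Alphabet
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("MSA data must be a 2-D matrix")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per row required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("row labels must be unique")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.alphabet.q):
            raise ValueError("states out of alphabet range")

    @property
    def M(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


class PhyloTree:
    """Rooted tree in flat-array form.

    Attributes
    ----------
    parent : (n_nodes,) int array, -1 at the root.
    branch_len : (n_nodes,) float array; length of the edge above each node
        (0 at the root).
    leaf_labels : labels of leaf nodes, aligned with :attr:`leaves`.
    """

    def __init__(self, parent, branch_len, leaf_labels: list[str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_len = np.asarray(branch_len, dtype=float)
        n = self.parent.shape[0]
        if self.branch_len.shape != (n,):
            raise ValueError("parent and branch_len must align")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        if not np.isfinite(self.branch_len).all() or (self.branch_len < 0).any():
            raise ValueError("branch lengths must be finite and >= 0")
        # children in CSR form
        order = np.argsort(self.parent, kind="stable")
        counts = np.zeros(n + 1, dtype=np.int64)
        for p in self.parent:
            if p >= 0:
                counts[p + 1] += 1
        self.child_ptr = np.cumsum(counts)
        self.child_idx = np.empty(n - 1, dtype=np.int64)
        fill = self.child_ptr[:-1].copy()
        for c in range(n):
            p = self.parent[c]
            if p >= 0:
                self.child_idx[fill[p]] = c
                fill[p] += 1
        # integer depths (edge counts) and a children-before-parents ordering
        self.depth = np.zeros(n, dtype=np.int64)
        for c in self._preorder():
            if self.parent[c] >= 0:
                self.depth[c] = self.depth[self.parent[c]] + 1
        self.postorder = np.argsort(-self.depth, kind="stable").astype(np.int64)
        self.leaves = np.flatnonzero(
            self.child_ptr[1:] == self.child_ptr[:-1]).astype(np.int64)
        if len(leaf_labels) != len(self.leaves):
            raise ValueError("one label per leaf required")
        if len(set(leaf_labels)) != len(leaf_labels):
            raise ValueError("leaf labels must be unique")
        self.leaf_labels = list(leaf_labels)
        # reachability check (connected, acyclic follow from single parent)
        if self.depth.max() >= n:
            raise ValueError("cycle detected")

    def _preorder(self) -> np.ndarray:
        n = len(self.parent)
        out = np.empty(n, dtype=np.int64)
        out[0] = self.root
        k = 1
        head = 0
        while head < k:
            node = out[head]
            head += 1
            for t in range(self.child_ptr[node], self.child_ptr[node + 1]):
                out[k] = self.child_idx[t]
                k += 1
        if k != n:
            raise ValueError("tree is not connected")
        return out

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def edge_factors(self, mu: float) -> np.ndarray:
        """Per-node no-mutation factors exp(-mu * branch length)."""
        return np.exp(-mu * self.branch_len)

    def leaf_row_map(self, labels: list[str]) -> np.ndarray:
        """Node -> MSA row index (-1 for internal nodes); errors on mismatch."""
        pos = {lab: m for m, lab in enumerate(labels)}
        missing = [lab for lab in self.leaf_labels if lab not in pos]
        if missing:
            raise ValueError(f"leaf labels absent from MSA: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        rows = np.full(self.n_nodes, -1, dtype=np.int64)
        for node, lab in zip(self.leaves, self.leaf_labels):
            rows[node] = pos[lab]
        return rows

    def leaf_column_states(self, msa: Msa, site: int) -> np.ndarray:
        """Per-node states of one MSA column (-1 at internal nodes)."""
        rows = self.leaf_row_map(msa.labels)
        states = np.full(self.n_nodes, -1, dtype=np.int64)
        sel = rows >= 0
        states[sel] = msa.data[rows[sel], site]
        return states


def grow_binary_tree(K: int, branch_time: float, seed=None) -> PhyloTree:
    """Complete binary clock tree after K duplications: 2**K leaves.

    Every branch has length ``branch_time``.  ``seed`` is accepted for
    interface symmetry but unused (the topology is deterministic).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > MAX_DUPLICATIONS:
        raise ValueError(f"K={K} exceeds the cap of {MAX_DUPLICATIONS}")
    if branch_time <= 0:
        raise ValueError("branch_time must be > 0")
    n = 2 ** (K + 1) - 1
    parent = np.empty(n, dtype=np.int64)
    parent[0] = -1
    idx = np.arange(1, n)
    parent[1:] = (idx - 1) // 2
    blen = np.full(n, float(branch_time))
    blen[0] = 0.0
    n_leaves = 2 ** K
    labels = [f"leaf{m:04d}" for m in range(n_leaves)]
    return PhyloTree(parent, blen, labels)


def evolve_branch(model: PottsModel, parent_seq, mu: float, dt: float,
                  rng: np.random.Generator, Jf: np.ndarray | None = None,
                  return_events: bool = False):
    """Evolve a sequence along one branch.

    Draws Poisson(mu * L * dt) mutation events; each event redraws a uniform
    random site from the heat-bath conditional of the model (the redraw may
    conserve the state).  With ``return_events`` the event count is returned
    alongside the child sequence.
    """
    lam = mu * model.L * dt
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("mu * L * dt must be finite and >= 0")
    seq = np.asarray(parent_seq, dtype=np.int64).copy()
    n_mut = int(rng.poisson(lam))
    if n_mut > 0:
        if Jf is None:
            Jf = model.coupling_tensor()
        _kernels.gibbs_updates(seq, Jf, model.h, n_mut,
                               int(rng.integers(1, 2**31 - 1)))
    if return_events:
        return seq, n_mut
    return seq


def sample_tree_msa(model: PottsModel, tree: PhyloTree, mu: float, seed=None,
                    keep_internal: bool = False, burn_in: int | None = None):
    """Sample leaf sequences of the model evolved down the tree.

    The root is drawn from an equilibrated Gibbs chain (``burn_in`` single-site
    updates, default 1000*L), duplicated onto the outgoing branches and evolved
    independently along every branch.  Returns the leaf :class:`Msa`, plus the
    full (n_nodes, L) node-sequence matrix when ``keep_internal`` is set.
    """
    rng = np.random.default_rng(seed)
    L = model.L
    if burn_in is None:
        burn_in = 1000 * L
    Jf = model.coupling_tensor()
    seqs = np.empty((tree.n_nodes, L), dtype=np.int64)
    root_seq = rng.integers(0, model.q, size=L).astype(np.int64)
    _kernels.gibbs_updates(root_seq, Jf, model.h, burn_in,
                           int(rng.integers(1, 2**31 - 1)))
    seqs[tree.root] = root_seq
    for node in tree._preorder():
        if node == tree.root:
            continue
        seqs[node] = evolve_branch(model, seqs[tree.parent[node]], mu,
                                   tree.branch_len[node], rng, Jf=Jf)
    msa = Msa(seqs[tree.leaves].astype(np.int8), list(tree.leaf_labels),
              model.alphabet or _default_alphabet(model.q))
    if keep_internal:
        return msa, seqs
    return msa


def sample_iid(model: PottsModel, M: int, burn_in: int | None = None,
               thinning: int = 10, seed=None) -> Msa:
    """Approximate i.i.d. equilibrium sample via a thinned Gibbs chain.

    ``burn_in`` counts single-site updates (default 1000*L); ``thinning``
    counts full sweeps (L updates) between recorded sequences.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    L = model.L
    if burn_in is None:
        burn_in = 1000 * L
    Jf = model.coupling_tensor()
    seq = rng.integers(0, model.q, size=L).astype(np.int64)
    _kernels.gibbs_updates(seq, Jf, model.h, burn_in,
                           int(rng.integers(1, 2**31 - 1)))
    data = _kernels.gibbs_chain(seq, Jf, model.h, M, thinning * L,
                                int(rng.integers(1, 2**31 - 1)))
    labels = [f"iid{m:05d}" for m in range(M)]
    return Msa(data.astype(np.int8), labels,
               model.alphabet or _default_alphabet(model.q))


def _default_alphabet(q: int) -> Alphabet:
    import string

    return Alphabet(string.ascii_uppercase[:q])


# ---------------------------------------------------------------------------
# Newick conversion (dendropy-backed reader; writer is exact)


def from_newick(text: str, require_branch_lengths: bool = True) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Polytomies are accepted.  Missing branch lengths raise unless
    ``require_branch_lengths`` is disabled (then treated as 0).
    """
    dtree = dendropy.Tree.get(data=text, schema="newick")
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n, dtype=float)
    leaf_labels = []
    for k, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[k] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                if require_branch_lengths:
                    raise ValueError("Newick input lacks branch lengths")
            else:
                blen[k] = float(nd.edge.length)
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise ValueError("leaf without label in Newick input")
            leaf_labels.append(str(lab).replace(" ", "_"))
    return PhyloTree(parent, blen, leaf_labels)


def to_newick(tree: PhyloTree) -> str:
    """Serialize with full-precision branch lengths."""
    label = {int(n): lab for n, lab in zip(tree.leaves, tree.leaf_labels)}

    parts: dict[int, str] = {}
    for n in tree.postorder:
        n = int(n)
        lo, hi = tree.child_ptr[n], tree.child_ptr[n + 1]
        if lo == hi:
            s = label[n]
        else:
            inner = ",".join(parts.pop(int(c)) for c in tree.child_idx[lo:hi])
            s = f"({inner})"
        if n != tree.root:
            s += f":{float(tree.branch_len[n])!r}"
        parts[n] = s
    return parts[tree.root] + ";"
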