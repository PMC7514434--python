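"""Independent-pair pruning likelihood and constrained pair-table correction.

A pair of columns (i, j) evolves under a joint propagator built from the
stationary pair table w = omega_ij: either both states persist, one site is
redrawn from the conditional given the other, or both are redrawn jointly.
The pair table maximizing the pruning likelihood is searched over a coupling
reparameterization w ~ exp(J(A,B) + h_i(A) + h_j(B)) / z whose compensatory
fields are re-fit by iterative proportional scaling after every move, so the
imposed single-site marginals hold at all times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .freq_stats import StationaryStats
from .phylo_sim import Msa, PhyloTree
from .site_pruning import OptimizerSchedule, _check_simplex, _column_leaf_states

__all__ = ["PairParameterization", "pair_propagator", "pair_likelihood",
           "fit_compensatory_fields", "optimize_pair_frequencies",
           "correct_all_pairs", "marginal_inconsistency"]

#: bound on coupling entries during the constrained search
J_BOUND = 8.0


@dataclass
class PairParameterization:
    """Coupling table plus compensatory fields inducing a pair table.

    omega = exp(J(A,B) + h_i(A) + h_j(B) - log_z), with marginals matching
    the imposed targets to the scaling tolerance.
    """

    J: np.ndarray
    h_i: np.ndarray
    h_j: np.ndarray
    log_z: float
    omega: np.ndarray
    residual: float


def _check_joint(w, name: str = "omega_ij") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{name} must be a square table")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a normalized joint table")
    if (w.sum(axis=1) <= 0).any() or (w.sum(axis=0) <= 0).any():
        raise ValueError(f"{name} has a vanishing marginal")
    return w


def pair_propagator(w, mu: float, dt: float) -> np.ndarray:
    """(q^2) x (q^2) stochastic matrix on pair states, row-major (A,B) -> A*q+B.

    P(C,D | A,B) = e^2 d_AC d_BD
                 + e(1-e) [w(D|A) d_AC + w(C|B) d_BD]
                 + (1-e)^2 w(C,D),         e = exp(-mu dt),
    with w(D|A) the conditional of the second site given the first.
    """
    w = _check_joint(w)
    if mu * dt < 0:
        raise ValueError("mu * dt must be >= 0")
    q = w.shape[0]
    wi = w.sum(axis=1)
    wj = w.sum(axis=0)
    cond_ji = w / wi[:, None]  # (A, D): second given first
    cond_ij = (w / wj[None, :]).T  # (B, C): first given second
    e = np.exp(-mu * dt)
    P = np.zeros((q * q, q * q))
    for A in range(q):
        for B in range(q):
            row = np.zeros((q, q))
            row[A, B] += e * e
            row[A, :] += e * (1 - e) * cond_ji[A]
            row[:, B] += e * (1 - e) * cond_ij[B]
            row += (1 - e) ** 2 * w
            P[A * q + B] = row.ravel()
    return P


def pair_likelihood(column_i, column_j, tree: PhyloTree, w, mu: float) -> float:
    """Pruning log-likelihood of a column pair; root prior is the table itself."""
    w = _check_joint(w)
    sa = _column_leaf_states(column_i, tree)
    sb = _column_leaf_states(column_j, tree)
    q = w.shape[0]
    work = np.empty((tree.n_nodes, q, q))
    return float(_kernels.pair_loglik(tree.postorder, tree.child_ptr,
                                      tree.child_idx, tree.edge_factors(mu),
                                      sa, sb, w, work))


def fit_compensatory_fields(J, target_row, target_col, tol: float = 1e-10,
                            max_iter: int = 10000) -> PairParameterization:
    """Rescale exp(J) by iterative proportional fitting to match marginals.

    Alternating row/column normalization until the maximum marginal error
    drops below ``tol``; raises past the iteration cap.  The equivalent
    compensatory fields (zero-mean gauge) are recovered from the result.
    """
    J = np.asarray(J, dtype=float)
    row_t = _check_simplex(target_row, "target_row")
    col_t = _check_simplex(target_col, "target_col")
    if (row_t <= 0).any() or (col_t <= 0).any():
        raise ValueError("marginal targets must be strictly positive")
    w, err, _ = _kernels.ipf_scale(np.exp(J), row_t, col_t, tol, max_iter)
    if err >= tol:
        raise RuntimeError(f"proportional scaling did not converge: residual {err:.3e}")
    R = np.log(w) - J
    log_z = -R.mean()
    h_i = R.mean(axis=1) + log_z
    h_j = R.mean(axis=0) + log_z
    return PairParameterization(J=J, h_i=h_i, h_j=h_j, log_z=float(log_z),
                                omega=w, residual=float(err))


def optimize_pair_frequencies(column_i, column_j, tree: PhyloTree, mu: float,
                              omega_i, omega_j,
                              schedule: OptimizerSchedule | None = None):
    """Constrained pair-table optimization for one column pair.

    Hill climbing over the coupling table; after every move the compensatory
    scaling restores the imposed marginals, then the pruning likelihood
    decides acceptance (strict increase).  Initialization J = 0 is the
    independence baseline omega_i x omega_j.  Returns (omega_ij, trace).
    """
    schedule = schedule or OptimizerSchedule()
    row_t = _check_simplex(omega_i, "omega_i")
    col_t = _check_simplex(omega_j, "omega_j")
    if (row_t <= 0).any() or (col_t <= 0).any():
        raise ValueError("marginal targets must be strictly positive")
    sa = _column_leaf_states(column_i, tree)
    sb = _column_leaf_states(column_j, tree)
    _, w, _, trace = _kernels.pair_optimize(
        tree.postorder, tree.child_ptr, tree.child_idx, tree.edge_factors(mu),
        sa, sb, row_t, col_t, schedule.iters, schedule.mag0, schedule.mag1,
        schedule.p_global, J_BOUND, schedule.seed)
    return w, trace


def optimize_pair_unconstrained(column_i, column_j, tree: PhyloTree, mu: float,
                                init=None,
                                schedule: OptimizerSchedule | None = None):
    """Diagnostic mode: optimize the pair table directly on the q^2 simplex."""
    schedule = schedule or OptimizerSchedule()
    column_i = np.asarray(column_i, dtype=np.int64)
    column_j = np.asarray(column_j, dtype=np.int64)
    q = int(max(column_i.max(), column_j.max())) + 1 if init is None else len(init)
    if init is None:
        counts = np.zeros((q, q))
        np.add.at(counts, (column_i, column_j), 1.0)
        counts = np.maximum(counts / counts.sum(), schedule.eps)
        init = counts / counts.sum()
    init = _check_joint(np.asarray(init, dtype=float), "init")
    sa = _column_leaf_states(column_i, tree)
    sb = _column_leaf_states(column_j, tree)
    w, _, trace = _kernels.pair_optimize_unconstrained(
        tree.postorder, tree.child_ptr, tree.child_idx, tree.edge_factors(mu),
        sa, sb, init, schedule.iters, schedule.mag0, schedule.mag1,
        schedule.p_global, schedule.eps, schedule.seed)
    return w, trace


def correct_all_pairs(msa: Msa, tree: PhyloTree, mu: float,
                      site_stats: StationaryStats,
                      schedule: OptimizerSchedule | None = None,
                      constrain: bool = True) -> StationaryStats:
    """Optimize all L(L-1)/2 pair tables independently.

    Pairs share only read-only inputs (parallel contract).  With
    ``constrain`` the marginals are pinned to the supplied site profiles;
    the unconstrained variant is the diagnostic mode whose overlapping-pair
    marginal disagreements :func:`marginal_inconsistency` quantifies.
    Per-pair failures fall back to the product table and are reported.
    """
    from dataclasses import replace

    schedule = schedule or OptimizerSchedule()
    L = msa.L
    q = msa.alphabet.q
    rows = tree.leaf_row_map(msa.labels)[tree.leaves]
    omega = np.clip(site_stats.site, schedule.eps, None)
    omega /= omega.sum(axis=1, keepdims=True)
    pair = np.empty((L * (L - 1) // 2, q, q))
    failures = []
    k = 0
    for i in range(L):
        ci = msa.data[rows, i].astype(np.int64)
        for j in range(i + 1, L):
            cj = msa.data[rows, j].astype(np.int64)
            sched = replace(schedule, seed=_pair_seed(schedule.seed, i, j))
            try:
                if constrain:
                    pair[k], _ = optimize_pair_frequencies(
                        ci, cj, tree, mu, omega[i], omega[j], sched)
                else:
                    pair[k], _ = optimize_pair_unconstrained(
                        ci, cj, tree, mu,
                        init=None if q == int(max(ci.max(), cj.max())) + 1
                        else _empirical_joint(ci, cj, q, schedule.eps),
                        schedule=sched)
            except Exception as exc:  # noqa: BLE001 - per-pair isolation
                failures.append(((i, j), repr(exc)))
                pair[k] = np.outer(omega[i], omega[j])
            k += 1
    if failures:
        warnings.warn(f"pair correction failed on {len(failures)} pairs", stacklevel=2)
    return StationaryStats(site=omega, pair=pair,
                           provenance="pair-corrected-omega")


def _empirical_joint(ci, cj, q, eps):
    counts = np.zeros((q, q))
    np.add.at(counts, (ci, cj), 1.0)
    counts = np.maximum(counts / counts.sum(), eps)
    return counts / counts.sum()


def marginal_inconsistency(stats: StationaryStats) -> np.ndarray:
    """Per-site maximum disagreement between marginals from different pairs.

    For each site i, every pair (i, j) yields a marginal over the states of
    i; returns the per-site maximum total-variation distance between any two
    of them.  Zero (to tolerance) when marginals were pinned.
    """
    if stats.pair is None:
        raise ValueError("stats lack pair tables")
    L = stats.L
    out = np.zeros(L)
    for i in range(L):
        margs = []
        for j in range(L):
            if j == i:
                continue
            tab = stats.get_pair(i, j)
            margs.append(tab.sum(axis=1))
        margs = np.array(margs)
        tv = 0.5 * np.abs(margs[:, None, :] - margs[None, :, :]).sum(axis=2)
        out[i] = tv.max()
    return out


def _pair_seed(seed: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence(entropy=(seed, i, j)).generate_state(1)[0] % (2**31 - 1)) or 1
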