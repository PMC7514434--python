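"""Independent-site pruning likelihood and stochastic frequency correction.

Each MSA column evolves independently under the propagator

    P(B | A, dt) = exp(-mu dt) delta_AB + (1 - exp(-mu dt)) omega(B),

whose stationary distribution is omega.  The column likelihood on a tree is
computed by post-order pruning; the stationary profile omega_i maximizing it
is found by a seeded stochastic hill climb on the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .freq_stats import StationaryStats
from .phylo_sim import Msa, PhyloTree

__all__ = ["OptimizerSchedule", "site_propagator", "site_likelihood",
           "optimize_site_frequencies", "correct_all_sites"]


@dataclass(frozen=True)
class OptimizerSchedule:
    """Stochastic search schedule: move magnitude decays geometrically."""

    iters: int = 2000
    mag0: float = 0.3
    mag1: float = 0.003
    p_global: float = 0.3
    eps: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        if not 0 < self.mag1 <= self.mag0:
            raise ValueError("move magnitudes must satisfy 0 < mag1 <= mag0")
        if not 0.0 <= self.p_global <= 1.0:
            raise ValueError("p_global must lie in [0, 1]")


def _check_simplex(omega, name: str = "omega") -> np.ndarray:
    omega = np.asarray(omega, dtype=float)
    if omega.ndim != 1 or (omega < 0).any() or abs(omega.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a probability vector")
    return omega


def site_propagator(omega, mu: float, dt: float) -> np.ndarray:
    """q x q stochastic matrix P[a, b] = P(B=b | A=a, dt)."""
    omega = _check_simplex(omega)
    if mu * dt < 0:
        raise ValueError("mu * dt must be >= 0")
    e = np.exp(-mu * dt)
    q = len(omega)
    return e * np.eye(q) + (1.0 - e) * np.tile(omega, (q, 1))


def _column_leaf_states(column, tree: PhyloTree) -> np.ndarray:
    column = np.asarray(column, dtype=np.int64)
    if column.shape != (tree.n_leaves,):
        raise ValueError(
            f"column must hold one state per leaf ({tree.n_leaves}), got {column.shape}")
    states = np.full(tree.n_nodes, -1, dtype=np.int64)
    states[tree.leaves] = column
    return states


def site_likelihood(column, tree: PhyloTree, omega, mu: float) -> float:
    """Pruning log-likelihood of one column; root prior is omega itself.

    ``column[k]`` is the state at the k-th leaf in tree leaf order.
    """
    omega = _check_simplex(omega)
    states = _column_leaf_states(column, tree)
    work = np.empty((tree.n_nodes, len(omega)))
    return float(_kernels.site_loglik(tree.postorder, tree.child_ptr,
                                      tree.child_idx, tree.edge_factors(mu),
                                      states, omega, work))


def optimize_site_frequencies(column, tree: PhyloTree, mu: float,
                              schedule: OptimizerSchedule | None = None,
                              init=None, q: int | None = None):
    """Maximize the column likelihood over omega by stochastic hill climbing.

    Global moves perturb the whole profile, local moves one entry; proposals
    are clipped to the schedule's floor, renormalized, and accepted only on a
    strict likelihood increase.  Returns (best omega, per-iteration
    log-likelihood trace of the accepted state).
    """
    schedule = schedule or OptimizerSchedule()
    column = np.asarray(column, dtype=np.int64)
    if q is None:
        q = int(column.max()) + 1 if init is None else len(init)
    if init is None:
        init = np.bincount(column, minlength=q).astype(float)
        init = np.maximum(init / init.sum(), schedule.eps)
        init /= init.sum()
    init = _check_simplex(np.asarray(init, dtype=float), "init")
    states = _column_leaf_states(column, tree)
    best, best_ll, trace = _kernels.site_optimize(
        tree.postorder, tree.child_ptr, tree.child_idx, tree.edge_factors(mu),
        states, init, schedule.iters, schedule.mag0, schedule.mag1,
        schedule.p_global, schedule.eps, schedule.seed)
    tail = trace[-max(schedule.iters // 10, 1):]
    if tail.max() == trace[0] and schedule.iters > 10:
        warnings.warn("no move accepted during the run", stacklevel=2)
    return best, trace


def correct_all_sites(msa: Msa, tree: PhyloTree, mu: float,
                      schedule: OptimizerSchedule | None = None) -> StationaryStats:
    """Run the site correction independently on every column.

    Columns share no state (embarrassingly parallel contract).  A failing
    column falls back to its empirical frequencies and is reported via a
    warning; the run continues.
    """
    schedule = schedule or OptimizerSchedule()
    q = msa.alphabet.q
    rows = tree.leaf_row_map(msa.labels)[tree.leaves]
    site = np.empty((msa.L, q))
    failures = []
    for i in range(msa.L):
        column = msa.data[rows, i].astype(np.int64)
        col_schedule = replace(schedule, seed=_column_seed(schedule.seed, i))
        try:
            site[i], _ = optimize_site_frequencies(column, tree, mu,
                                                   col_schedule, q=q)
        except Exception as exc:  # noqa: BLE001 - per-column isolation
            failures.append((i, repr(exc)))
            emp = np.bincount(column, minlength=q).astype(float)
            emp = np.maximum(emp / emp.sum(), schedule.eps)
            site[i] = emp / emp.sum()
    if failures:
        warnings.warn(f"site correction failed on columns {failures}", stacklevel=2)
    return StationaryStats(site=site, provenance="site-corrected-omega")


def _column_seed(seed: int, column: int) -> int:
    return int(np.random.SeedSequence(entropy=(seed, column)).generate_state(1)[0] % (2**31 - 1)) or 1
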