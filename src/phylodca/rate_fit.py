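"""Mutation-rate estimation from the Hamming-distance / time-separation curve.

Any two leaves give one observation of the expected Hamming distance after
their patristic time separation; under the single-site propagator that curve
is ``d(t) = plateau * (1 - exp(-mu t))``.  Times are binned, bin averages are
fitted by weighted nonlinear least squares, and the fitted ``mu`` feeds the
pruning corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import _kernels
from .phylo_sim import Msa, PhyloTree

__all__ = ["DistanceCurve", "MuFit", "leaf_pair_times", "binned_curve",
           "fit_mu", "estimate_mu", "sample_leaf_pairs"]

#: cap on the number of leaf pairs used in O(M^2) computations
DEFAULT_MAX_PAIRS = 2_000_000


@dataclass
class DistanceCurve:
    """Binned mean Hamming distance vs. time separation."""

    times: np.ndarray  # bin centers, increasing
    dbar: np.ndarray  # mean Hamming distance per bin
    counts: np.ndarray  # number of pairs per bin

    def __post_init__(self) -> None:
        if not (np.diff(self.times) > 0).all():
            raise ValueError("bin centers must be strictly increasing")
        if (self.counts < 1).any():
            raise ValueError("retained bins need at least one pair")


@dataclass
class MuFit:
    mu: float
    plateau: float
    residual: float  # weighted RMS residual of the fit


def sample_leaf_pairs(n_leaves: int, max_pairs: int = DEFAULT_MAX_PAIRS,
                      seed=0) -> np.ndarray:
    """All leaf pairs (i < j), subsampled with a seeded RNG past the cap."""
    total = n_leaves * (n_leaves - 1) // 2
    if total <= max_pairs:
        iu, ju = np.triu_indices(n_leaves, k=1)
        return np.column_stack([iu, ju]).astype(np.int64)
    rng = np.random.default_rng(seed)
    # draw flat pair indices without replacement and unrank them
    flat = rng.choice(total, size=max_pairs, replace=False)
    iu, ju = np.triu_indices(n_leaves, k=1)
    return np.column_stack([iu[flat], ju[flat]]).astype(np.int64)


def leaf_pair_times(tree: PhyloTree, pairs: np.ndarray | None = None) -> np.ndarray:
    """Patristic time separation for leaf pairs.

    ``pairs`` holds (n, 2) indices into the tree's leaf ordering; all pairs
    by default (guarded by :data:`DEFAULT_MAX_PAIRS`).
    """
    if pairs is None:
        pairs = sample_leaf_pairs(tree.n_leaves)
    pairs = np.asarray(pairs, dtype=np.int64)
    u = tree.leaves[pairs[:, 0]]
    v = tree.leaves[pairs[:, 1]]
    return _kernels.pair_path_lengths(tree.parent, tree.branch_len, tree.depth,
                                      u, v)


def binned_curve(msa: Msa, tree: PhyloTree, pairs: np.ndarray | None = None,
                 n_bins: int = 20) -> DistanceCurve:
    """Equal-count (quantile) binning of pairwise (time, Hamming) points.

    MSA rows are matched to tree leaves by label.  When the observed times
    take fewer distinct values than ``n_bins`` (as on a clock tree), one bin
    per distinct value is used.
    """
    if pairs is None:
        pairs = sample_leaf_pairs(tree.n_leaves)
    pairs = np.asarray(pairs, dtype=np.int64)
    if len(pairs) < 1:
        raise ValueError("need at least one leaf pair")
    times = leaf_pair_times(tree, pairs)
    rows = tree.leaf_row_map(msa.labels)[tree.leaves]
    a = msa.data[rows[pairs[:, 0]]]
    b = msa.data[rows[pairs[:, 1]]]
    dists = (a != b).sum(axis=1).astype(float)
    uniq = np.unique(times)
    if len(uniq) <= n_bins:
        edges = np.concatenate([uniq, [uniq[-1] + 1]])
        idx = np.searchsorted(uniq, times)
    else:
        if len(pairs) < n_bins:
            raise ValueError("fewer pairs than bins")
        qs = np.quantile(times, np.linspace(0, 1, n_bins + 1))
        qs = np.unique(qs)
        idx = np.clip(np.searchsorted(qs, times, side="right") - 1, 0, len(qs) - 2)
        uniq = None
    nb = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=nb)
    sums_t = np.bincount(idx, weights=times, minlength=nb)
    sums_d = np.bincount(idx, weights=dists, minlength=nb)
    keep = counts > 0
    return DistanceCurve(times=sums_t[keep] / counts[keep],
                         dbar=sums_d[keep] / counts[keep],
                         counts=counts[keep])


def fit_mu(curve: DistanceCurve) -> MuFit:
    """Weighted least-squares fit of d(t) = plateau * (1 - exp(-mu t)).

    Weights are the per-bin pair counts; both parameters are free with
    mu > 0.  Raises on non-convergence or a degenerate (flat) curve.
    """
    if len(curve.times) < 3:
        raise ValueError("need at least 3 usable bins")
    if curve.dbar.max() <= 0:
        raise ValueError("degenerate curve: all distances zero")

    def model(t, mu, plateau):
        return plateau * (1.0 - np.exp(-mu * t))

    p_guess = float(curve.dbar.max())
    half = 0.5 * p_guess
    above = np.flatnonzero(curve.dbar >= half)
    t_half = curve.times[above[0]] if len(above) else curve.times[-1]
    mu_guess = 1.0 / max(t_half, 1e-9)
    sigma = 1.0 / np.sqrt(curve.counts)
    try:
        popt, _ = curve_fit(model, curve.times, curve.dbar,
                            p0=[mu_guess, p_guess], sigma=sigma,
                            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"mu fit failed to converge: {exc}") from exc
    mu, plateau = map(float, popt)
    resid = model(curve.times, mu, plateau) - curve.dbar
    wrms = float(np.sqrt(np.average(resid**2, weights=curve.counts)))
    return MuFit(mu=mu, plateau=plateau, residual=wrms)


def estimate_mu(msa: Msa, tree: PhyloTree, n_bins: int = 20,
                max_pairs: int = DEFAULT_MAX_PAIRS, seed=0) -> MuFit:
    """Convenience pipeline: sample pairs, bin, fit; returns the fitted rate."""
    pairs = sample_leaf_pairs(tree.n_leaves, max_pairs=max_pairs, seed=seed)
    curve = binned_curve(msa, tree, pairs=pairs, n_bins=n_bins)
    return fit_mu(curve)
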