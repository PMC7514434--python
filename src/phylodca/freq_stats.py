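"""Empirical MSA statistics and comparison metrics.

Frequencies, connected correlations, Hamming distances, the 80%-identity
reweighting baseline and the Pearson/slope comparison used throughout the
evaluation.  Single-site tables live on (L, q); pair tables are stored once
per unordered pair i < j in lexicographic order, like Potts couplings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .phylo_sim import Msa
from .potts_core import n_pairs, pair_index

__all__ = [
    "StationaryStats",
    "count_frequencies",
    "connected_correlations",
    "covariance_tensor",
    "reweighting_weights",
    "hamming",
    "compare_stats",
    "flatten_site",
    "flatten_pair",
]

PROVENANCES = ("empirical-f", "site-corrected-omega", "pair-corrected-omega",
               "combined")


@dataclass
class StationaryStats:
    """Single-site and pairwise frequency tables with a provenance tag.

    ``site`` has shape (L, q) with simplex rows; ``pair`` has shape
    (L*(L-1)/2, q, q) or is None.  Tables of provenance "combined" may
    contain entries outside [0, 1]; ``out_of_range`` counts them and the
    tables are deliberately not clipped.
    """

    site: np.ndarray
    pair: np.ndarray | None = None
    provenance: str = "empirical-f"
    out_of_range: int = 0

    def __post_init__(self) -> None:
        self.site = np.asarray(self.site, dtype=float)
        if self.site.ndim != 2:
            raise ValueError("site table must be (L, q)")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.allclose(self.site.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("site rows must sum to 1")
        if self.pair is not None:
            self.pair = np.asarray(self.pair, dtype=float)
            L = self.site.shape[0]
            if self.pair.shape != (n_pairs(L), self.site.shape[1], self.site.shape[1]):
                raise ValueError("pair table shape mismatch")
            if self.provenance in ("empirical-f", "pair-corrected-omega"):
                if not np.allclose(self.pair.sum(axis=(1, 2)), 1.0, atol=1e-8):
                    raise ValueError("pair tables must sum to 1")

    @property
    def L(self) -> int:
        return self.site.shape[0]

    @property
    def q(self) -> int:
        return self.site.shape[1]

    @property
    def has_out_of_range(self) -> bool:
        return self.out_of_range > 0

    def get_pair(self, i: int, j: int) -> np.ndarray:
        if self.pair is None:
            raise ValueError("no pair tables available")
        if i < j:
            return self.pair[pair_index(i, j, self.L)]
        return self.pair[pair_index(j, i, self.L)].T


def count_frequencies(msa: Msa, weights=None, pseudocount: float = 0.0,
                      pairs: bool = True) -> StationaryStats:
    """Weighted empirical frequencies f_i and (optionally) f_ij.

    ``pseudocount`` mixes toward the uniform distribution:
    f -> (1-pc) f + pc/q (and pc/q^2 for pairs), preserving marginal
    consistency.  Default 0 (raw counts).
    """
    if msa.M < 1:
        raise ValueError("empty MSA")
    M, L = msa.M, msa.L
    q = msa.alphabet.q
    if weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (M,):
            raise ValueError("one weight per row required")
    wsum = w.sum()
    X = np.zeros((M, L, q))
    X[np.arange(M)[:, None], np.arange(L)[None, :], msa.data.astype(np.int64)] = 1.0
    fi = (w[:, None, None] * X).sum(axis=0) / wsum
    pair = None
    if pairs:
        Y = X.reshape(M, L * q)
        big = (w[:, None] * Y).T @ Y / wsum  # (L q, L q)
        pair = np.empty((n_pairs(L), q, q))
        k = 0
        for i in range(L):
            for j in range(i + 1, L):
                pair[k] = big[i * q:(i + 1) * q, j * q:(j + 1) * q]
                k += 1
    if pseudocount:
        pc = float(pseudocount)
        fi = (1 - pc) * fi + pc / q
        if pair is not None:
            pair = (1 - pc) * pair + pc / q**2
    return StationaryStats(site=fi, pair=pair, provenance="empirical-f")


def connected_correlations(stats: StationaryStats) -> np.ndarray:
    """c_ij(a, b) = f_ij(a, b) - f_i(a) f_j(b), per unordered pair i < j."""
    if stats.pair is None:
        raise ValueError("stats lack pair tables")
    L, q = stats.L, stats.q
    c = np.empty_like(stats.pair)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            c[k] = stats.pair[k] - np.outer(stats.site[i], stats.site[j])
            k += 1
    return c


def covariance_tensor(stats: StationaryStats) -> np.ndarray:
    """Full (L, L, q, q) tensor with c_ij in the i < j blocks (rest zero).

    This is the target layout consumed by the annealing MSA builder;
    site-diagonal blocks are excluded by construction.
    """
    L, q = stats.L, stats.q
    c = connected_correlations(stats)
    T = np.zeros((L, L, q, q))
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            T[i, j] = c[k]
            k += 1
    return T


def covariance_matrix(stats: StationaryStats, drop_state: int | None = None) -> np.ndarray:
    """Flattened covariance matrix over (i, A) with c_ij in off-diagonal blocks.

    ``drop_state`` removes one reference state per site (the usual
    full-rank parameterization); diagonal blocks are zero (pure i != j).
    """
    L, q = stats.L, stats.q
    keep = [a for a in range(q) if a != drop_state]
    qk = len(keep)
    C = np.zeros((L * qk, L * qk))
    c = connected_correlations(stats)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            blk = c[k][np.ix_(keep, keep)]
            C[i * qk:(i + 1) * qk, j * qk:(j + 1) * qk] = blk
            C[j * qk:(j + 1) * qk, i * qk:(i + 1) * qk] = blk.T
            k += 1
    return C


def hamming(a, b) -> int:
    """Number of differing positions between two equal-length sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return int((a != b).sum())


def reweighting_weights(msa: Msa, identity_threshold: float = 0.8) -> np.ndarray:
    """Similarity reweighting: w_m = 1 / #{n : identity(m, n) >= threshold}.

    Identity is 1 - hamming/L with gaps counted as a symbol; the count
    includes m itself, so a cluster of k identical rows gets weight 1/k each
    and counts for one observation in total.
    """
    M, L = msa.M, msa.L
    data = msa.data.astype(np.int8)
    min_matches = identity_threshold * L
    counts = np.zeros(M, dtype=np.int64)
    chunk = max(1, 2**22 // max(M, 1))
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        matches = (data[lo:hi, None, :] == data[None, :, :]).sum(axis=2)
        counts[lo:hi] = (matches >= min_matches).sum(axis=1)
    return 1.0 / counts


def compare_stats(x, y) -> dict:
    """Pearson r and OLS slope of y on x for two flattened stat vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate (zero-variance) input")
    res = sp_stats.linregress(x, y)
    return {"pearson": float(res.rvalue), "slope": float(res.slope)}


def flatten_site(stats: StationaryStats, drop_dominant: bool = False) -> np.ndarray:
    """All (i, A) site entries as a vector.

    ``drop_dominant`` removes the per-site majority state (alternative
    comparison mode); default keeps all entries.
    """
    if not drop_dominant:
        return stats.site.ravel().copy()
    keep = np.ones_like(stats.site, dtype=bool)
    keep[np.arange(stats.L), stats.site.argmax(axis=1)] = False
    return stats.site[keep]


def flatten_pair(stats: StationaryStats) -> np.ndarray:
    """All (i<j, A, B) pair entries as a vector."""
    if stats.pair is None:
        raise ValueError("stats lack pair tables")
    return stats.pair.ravel().copy()
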