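"""Build an artificial MSA matching corrected target statistics.

Two-step construction: draw every column i.i.d. from the target site
profiles, then permute entries within columns by Metropolis-annealed swaps
so the connected-correlation tensor approaches the target.  Column swaps
leave single-site counts exactly invariant, so the profile marginals are
preserved by construction; the best-seen configuration is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .freq_stats import StationaryStats, covariance_tensor
from .phylo_sim import Msa
from .potts_core import Alphabet

__all__ = ["AnnealSchedule", "combine_site_correction", "init_profile_msa",
           "anneal_msa", "incremental_covariance_update"]


@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing move budget and geometric inverse-temperature ladder."""

    moves: int | None = None  # total; defaults to 200 * M * L at run time
    beta0: float = 10.0
    beta1: float = 1e4
    stages: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta1 <= self.beta0 or self.beta0 <= 0:
            raise ValueError("need 0 < beta0 < beta1 (strictly increasing ladder)")
        if self.stages < 1:
            raise ValueError("stages must be >= 1")

    def ladder(self) -> np.ndarray:
        return np.geomspace(self.beta0, self.beta1, self.stages)


def combine_site_correction(f: StationaryStats,
                            omega_site: StationaryStats) -> StationaryStats:
    """Merge empirical pair tables with corrected site profiles.

    omega_ij(A,B) = f_ij(A,B) - f_i(A) f_j(B) + omega_i(A) omega_j(B):
    corrected marginals, uncorrected connected correlations.  Entries outside
    [0, 1] are counted and flagged, never clipped.
    """
    if f.pair is None:
        raise ValueError("empirical stats need pair tables")
    if f.site.shape != omega_site.site.shape:
        raise ValueError("shape mismatch between empirical and corrected stats")
    L, q = f.L, f.q
    pair = np.empty_like(f.pair)
    k = 0
    for i in range(L):
        for j in range(i + 1, L):
            pair[k] = (f.pair[k] - np.outer(f.site[i], f.site[j])
                       + np.outer(omega_site.site[i], omega_site.site[j]))
            k += 1
    oob = int(((pair < 0) | (pair > 1)).sum())
    return StationaryStats(site=omega_site.site.copy(), pair=pair,
                           provenance="combined", out_of_range=oob)


def init_profile_msa(target: StationaryStats, M: int, seed=None,
                     alphabet: Alphabet | None = None) -> Msa:
    """MSA whose column i holds M i.i.d. draws from the target profile i."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    L, q = target.L, target.q
    data = np.empty((M, L), dtype=np.int8)
    for i in range(L):
        data[:, i] = rng.choice(q, size=M, p=target.site[i])
    if alphabet is None:
        import string

        alphabet = Alphabet(string.ascii_uppercase[:q])
    return Msa(data, [f"art{m:05d}" for m in range(M)], alphabet)


def anneal_msa(msa: Msa, target, schedule: AnnealSchedule | None = None):
    """Anneal within-column swaps toward target connected correlations.

    ``target`` is either a :class:`StationaryStats` with pair tables or a
    ready (L, L, q, q) tensor holding c_ij in the i < j blocks (site-diagonal
    blocks excluded).  A swap is accepted with probability
    min(1, exp(-beta * (||C' - C_target|| - ||C - C_target||))) under the
    Frobenius norm on connected correlations.  Returns (best-seen Msa,
    final distance, per-stage trace array of (beta, current, best)).
    """
    schedule = schedule or AnnealSchedule()
    if isinstance(target, StationaryStats):
        T = covariance_tensor(target)
    else:
        T = np.asarray(target, dtype=float)
    L, q = msa.L, msa.alphabet.q
    if T.shape != (L, L, q, q):
        raise ValueError(f"target tensor must have shape {(L, L, q, q)}")
    moves = schedule.moves if schedule.moves is not None else 200 * msa.M * msa.L
    per_stage = max(moves // schedule.stages, 1)
    data = msa.data.astype(np.int64)
    seed = int(np.random.SeedSequence(schedule.seed).generate_state(1)[0] % (2**31 - 1)) or 1
    best, dist, trace = _kernels.anneal(data, T, schedule.ladder(), per_stage, seed)
    out = Msa(best.astype(np.int8), list(msa.labels), msa.alphabet)
    return out, float(dist), trace


def incremental_covariance_update(C: np.ndarray, msa: Msa, move) -> np.ndarray:
    """Connected-correlation tensor after one within-column swap.

    ``C`` is the (L, L, q, q) tensor of the pre-move MSA (i < j blocks);
    ``move = (i, m, n)`` swaps rows m and n in column i.  Only the O(L q)
    touched entries change; equals full recomputation.
    """
    i, m, n = move
    L, q = msa.L, msa.alphabet.q
    if C.shape != (L, L, q, q):
        raise ValueError("covariance tensor shape mismatch")
    Cn = C.copy()
    am = int(msa.data[m, i])
    an = int(msa.data[n, i])
    if am == an or m == n:
        return Cn
    d = 1.0 / msa.M
    for j in range(L):
        if j == i:
            continue
        bm = int(msa.data[m, j])
        bn = int(msa.data[n, j])
        if bm == bn:
            continue
        if i < j:
            blk = Cn[i, j]
            blk[am, bm] -= d
            blk[an, bm] += d
            blk[an, bn] -= d
            blk[am, bn] += d
        else:
            blk = Cn[j, i]
            blk[bm, am] -= d
            blk[bm, an] += d
            blk[bn, an] -= d
            blk[bn, am] += d
    return Cn
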