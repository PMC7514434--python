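"""Numba kernels for the hot loops.

All kernels draw randomness from numba's own global RNG, seeded explicitly at
the top of every stochastic kernel, so that a given (inputs, seed) pair is
bit-reproducible.  Trees are passed as flat arrays: a post-order node listing,
a CSR children structure (child_ptr/child_idx) and per-node edge factors
``efac[n] = exp(-mu * branch_length(n))`` for the edge above node ``n``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Gibbs sampling of a Potts model


@njit(cache=True)
def gibbs_updates(seq, Jf, h, n_updates, seed):
    """In-place heat-bath updates at uniformly random sites."""
    np.random.seed(seed)
    L, q = h.shape
    lg = np.empty(q)
    for _ in range(n_updates):
        i = np.random.randint(L)
        for a in range(q):
            e = h[i, a]
            for j in range(L):
                if j != i:
                    e += Jf[i, j, a, seq[j]]
            lg[a] = e
        mx = lg[0]
        for a in range(1, q):
            if lg[a] > mx:
                mx = lg[a]
        s = 0.0
        for a in range(q):
            lg[a] = np.exp(lg[a] - mx)
            s += lg[a]
        r = np.random.random() * s
        acc = 0.0
        new = q - 1
        for a in range(q):
            acc += lg[a]
            if r < acc:
                new = a
                break
        seq[i] = new


@njit(cache=True)
def gibbs_chain(seq, Jf, h, n_samples, thin_updates, seed):
    """Record ``n_samples`` states of a single chain, ``thin_updates`` apart."""
    np.random.seed(seed)
    L = seq.shape[0]
    out = np.empty((n_samples, L), dtype=np.int64)
    for m in range(n_samples):
        gibbs_updates(seq, Jf, h, thin_updates, np.random.randint(1, 2**31 - 1))
        out[m] = seq
    return out


# ---------------------------------------------------------------------------
# independent-site pruning


@njit(cache=True)
def site_loglik(post, child_ptr, child_idx, efac, leaf_state, omega, work):
    """Log-likelihood of one MSA column under the single-site propagator.

    ``work`` is an (n_nodes, q) scratch table of per-node conditional
    likelihood vectors, rescaled at every internal node to avoid underflow.
    """
    q = omega.shape[0]
    logscale = 0.0
    for idx in range(post.shape[0]):
        n = post[idx]
        if leaf_state[n] >= 0:
            for a in range(q):
                work[n, a] = 0.0
            work[n, leaf_state[n]] = 1.0
        else:
            for a in range(q):
                work[n, a] = 1.0
            for k in range(child_ptr[n], child_ptr[n + 1]):
                c = child_idx[k]
                e = efac[c]
                dot = 0.0
                for b in range(q):
                    dot += omega[b] * work[c, b]
                for a in range(q):
                    work[n, a] *= e * work[c, a] + (1.0 - e) * dot
            s = 0.0
            for a in range(q):
                s += work[n, a]
            if s <= 0.0:
                return -np.inf
            for a in range(q):
                work[n, a] /= s
            logscale += np.log(s)
    root = post[post.shape[0] - 1]
    val = 0.0
    for a in range(q):
        val += omega[a] * work[root, a]
    if val <= 0.0:
        return -np.inf
    return logscale + np.log(val)


@njit(cache=True)
def site_optimize(post, child_ptr, child_idx, efac, leaf_state, omega0,
                  iters, mag0, mag1, p_global, eps, seed):
    """Stochastic hill climb over the q-simplex; strict-increase acceptance.

    Returns (best omega, best log-likelihood, per-iteration current-ll trace).
    """
    np.random.seed(seed)
    q = omega0.shape[0]
    n_nodes = leaf_state.shape[0]
    work = np.empty((n_nodes, q))
    omega = omega0.copy()
    cur = site_loglik(post, child_ptr, child_idx, efac, leaf_state, omega, work)
    best = omega.copy()
    best_ll = cur
    trace = np.empty(iters)
    decay = (mag1 / mag0) ** (1.0 / max(iters - 1, 1))
    mag = mag0
    prop = np.empty(q)
    for t in range(iters):
        for a in range(q):
            prop[a] = omega[a]
        if np.random.random() < p_global:
            for a in range(q):
                prop[a] += mag * np.random.normal()
        else:
            a = np.random.randint(q)
            prop[a] += mag * np.random.normal()
        s = 0.0
        for a in range(q):
            if prop[a] < eps:
                prop[a] = eps
            s += prop[a]
        for a in range(q):
            prop[a] /= s
        ll = site_loglik(post, child_ptr, child_idx, efac, leaf_state, prop, work)
        if ll > cur:
            for a in range(q):
                omega[a] = prop[a]
            cur = ll
            if ll > best_ll:
                best_ll = ll
                for a in range(q):
                    best[a] = omega[a]
        trace[t] = cur
        mag *= decay
    return best, best_ll, trace


# ---------------------------------------------------------------------------
# independent-pair pruning


@njit(cache=True)
def pair_loglik(post, child_ptr, child_idx, efac, leaf_a, leaf_b, w, work):
    """Log-likelihood of a column pair under the pair propagator.

    ``w`` is the joint q x q stationary table; ``work`` an (n_nodes, q, q)
    scratch array.  Returns -inf when a marginal of ``w`` vanishes.
    """
    q = w.shape[0]
    wi = np.empty(q)
    wj = np.empty(q)
    for a in range(q):
        ra = 0.0
        for b in range(q):
            ra += w[a, b]
        wi[a] = ra
    for b in range(q):
        cb = 0.0
        for a in range(q):
            cb += w[a, b]
        wj[b] = cb
    for a in range(q):
        if wi[a] <= 0.0 or wj[a] <= 0.0:
            return -np.inf
    # cond_ji[a, d] = w(a, d) / wi(a); cond_ij[b, c] = w(c, b) / wj(b)
    cond_ji = np.empty((q, q))
    cond_ij = np.empty((q, q))
    for a in range(q):
        for d in range(q):
            cond_ji[a, d] = w[a, d] / wi[a]
    for b in range(q):
        for c in range(q):
            cond_ij[b, c] = w[c, b] / wj[b]
    logscale = 0.0
    rA = np.empty(q)
    cB = np.empty(q)
    msg = np.empty((q, q))
    for idx in range(post.shape[0]):
        n = post[idx]
        if leaf_a[n] >= 0:
            for a in range(q):
                for b in range(q):
                    work[n, a, b] = 0.0
            work[n, leaf_a[n], leaf_b[n]] = 1.0
        else:
            for a in range(q):
                for b in range(q):
                    work[n, a, b] = 1.0
            for k in range(child_ptr[n], child_ptr[n + 1]):
                c = child_idx[k]
                e = efac[c]
                e2 = e * e
                em = e * (1.0 - e)
                f2 = (1.0 - e) * (1.0 - e)
                S = 0.0
                for a in range(q):
                    for b in range(q):
                        S += w[a, b] * work[c, a, b]
                for a in range(q):
                    v = 0.0
                    for d in range(q):
                        v += cond_ji[a, d] * work[c, a, d]
                    rA[a] = v
                for b in range(q):
                    v = 0.0
                    for cc in range(q):
                        v += cond_ij[b, cc] * work[c, cc, b]
                    cB[b] = v
                for a in range(q):
                    for b in range(q):
                        msg[a, b] = e2 * work[c, a, b] + em * (rA[a] + cB[b]) + f2 * S
                for a in range(q):
                    for b in range(q):
                        work[n, a, b] *= msg[a, b]
            s = 0.0
            for a in range(q):
                for b in range(q):
                    s += work[n, a, b]
            if s <= 0.0:
                return -np.inf
            for a in range(q):
                for b in range(q):
                    work[n, a, b] /= s
            logscale += np.log(s)
    root = post[post.shape[0] - 1]
    val = 0.0
    for a in range(q):
        for b in range(q):
            val += w[a, b] * work[root, a, b]
    if val <= 0.0:
        return -np.inf
    return logscale + np.log(val)


@njit(cache=True)
def ipf_scale(K, row_t, col_t, tol, max_iter):
    """Iterative proportional fitting of a positive matrix to given marginals.

    Returns (scaled table, final max marginal error, iterations used).
    """
    q = K.shape[0]
    w = K.copy()
    s = 0.0
    for a in range(q):
        for b in range(q):
            s += w[a, b]
    for a in range(q):
        for b in range(q):
            w[a, b] /= s
    err = 1.0
    it = 0
    while it < max_iter:
        it += 1
        for a in range(q):
            rs = 0.0
            for b in range(q):
                rs += w[a, b]
            f = row_t[a] / rs
            for b in range(q):
                w[a, b] *= f
        for b in range(q):
            cs = 0.0
            for a in range(q):
                cs += w[a, b]
            f = col_t[b] / cs
            for a in range(q):
                w[a, b] *= f
        err = 0.0
        for a in range(q):
            rs = 0.0
            for b in range(q):
                rs += w[a, b]
            d = abs(rs - row_t[a])
            if d > err:
                err = d
        if err < tol:
            break
    return w, err, it


@njit(cache=True)
def pair_optimize(post, child_ptr, child_idx, efac, leaf_a, leaf_b,
                  row_t, col_t, iters, mag0, mag1, p_global, jmax, seed):
    """Hill climb over the coupling table of the constrained pair table.

    The pair table is exp(J) rescaled by IPF to match the imposed marginals
    at every step; moves are accepted only on a strict likelihood increase.
    Returns (best J, best pair table, best ll, current-ll trace).
    """
    np.random.seed(seed)
    q = row_t.shape[0]
    n_nodes = leaf_a.shape[0]
    work = np.empty((n_nodes, q, q))
    J = np.zeros((q, q))
    K = np.exp(J)
    w, _, _ = ipf_scale(K, row_t, col_t, 1e-12, 5000)
    cur = pair_loglik(post, child_ptr, child_idx, efac, leaf_a, leaf_b, w, work)
    bestJ = J.copy()
    best_w = w.copy()
    best_ll = cur
    trace = np.empty(iters)
    decay = (mag1 / mag0) ** (1.0 / max(iters - 1, 1))
    mag = mag0
    for t in range(iters):
        Jp = J.copy()
        if np.random.random() < p_global:
            for a in range(q):
                for b in range(q):
                    Jp[a, b] += mag * np.random.normal()
        else:
            a = np.random.randint(q)
            b = np.random.randint(q)
            Jp[a, b] += mag * np.random.normal()
        for a in range(q):
            for b in range(q):
                if Jp[a, b] > jmax:
                    Jp[a, b] = jmax
                elif Jp[a, b] < -jmax:
                    Jp[a, b] = -jmax
        K = np.exp(Jp)
        w, err, _ = ipf_scale(K, row_t, col_t, 1e-12, 5000)
        ll = pair_loglik(post, child_ptr, child_idx, efac, leaf_a, leaf_b, w, work)
        if ll > cur:
            m = 0.0
            for a in range(q):
                for b in range(q):
                    m += Jp[a, b]
            m /= q * q
            for a in range(q):
                for b in range(q):
                    J[a, b] = Jp[a, b] - m
            cur = ll
            if ll > best_ll:
                best_ll = ll
                bestJ = J.copy()
                best_w = w.copy()
        trace[t] = cur
        mag *= decay
    return bestJ, best_w, best_ll, trace


@njit(cache=True)
def pair_optimize_unconstrained(post, child_ptr, child_idx, efac, leaf_a, leaf_b,
                                w0, iters, mag0, mag1, p_global, eps, seed):
    """Hill climb directly over the q*q-simplex pair table (diagnostic mode)."""
    np.random.seed(seed)
    q = w0.shape[0]
    n_nodes = leaf_a.shape[0]
    work = np.empty((n_nodes, q, q))
    w = w0.copy()
    cur = pair_loglik(post, child_ptr, child_idx, efac, leaf_a, leaf_b, w, work)
    best = w.copy()
    best_ll = cur
    trace = np.empty(iters)
    decay = (mag1 / mag0) ** (1.0 / max(iters - 1, 1))
    mag = mag0
    for t in range(iters):
        prop = w.copy()
        if np.random.random() < p_global:
            for a in range(q):
                for b in range(q):
                    prop[a, b] += mag * np.random.normal()
        else:
            a = np.random.randint(q)
            b = np.random.randint(q)
            prop[a, b] += mag * np.random.normal()
        s = 0.0
        for a in range(q):
            for b in range(q):
                if prop[a, b] < eps:
                    prop[a, b] = eps
                s += prop[a, b]
        for a in range(q):
            for b in range(q):
                prop[a, b] /= s
        ll = pair_loglik(post, child_ptr, child_idx, efac, leaf_a, leaf_b, prop, work)
        if ll > cur:
            w = prop.copy()
            cur = ll
            if ll > best_ll:
                best_ll = ll
                best = w.copy()
        trace[t] = cur
        mag *= decay
    return best, best_ll, trace


# ---------------------------------------------------------------------------
# simulated-annealing MSA permutation sampler


@njit(cache=True)
def pair_freqs(msa, L, q):
    """Upper-triangular pair frequency tensor F[i, j, a, b] for i < j."""
    M = msa.shape[0]
    F = np.zeros((L, L, q, q))
    for m in range(M):
        for i in range(L):
            ai = msa[m, i]
            for j in range(i + 1, L):
                F[i, j, ai, msa[m, j]] += 1.0
    F /= M
    return F


@njit(cache=True)
def _dist2(F, fi, T, L, q):
    d2 = 0.0
    for i in range(L):
        for j in range(i + 1, L):
            for a in range(q):
                for b in range(q):
                    c = F[i, j, a, b] - fi[i, a] * fi[j, b]
                    d2 += (c - T[i, j, a, b]) ** 2
    return d2


@njit(cache=True)
def anneal(msa, T, betas, moves_per_stage, seed):
    """Metropolis column-swap annealing toward target connected correlations.

    ``msa`` is modified in place; ``T[i, j]`` (i < j) holds the target
    connected-correlation tables.  Acceptance uses the change of the
    Frobenius distance between current and target correlation tensors.
    Returns (best-seen msa, best distance, per-stage trace of (beta,
    current distance, best distance)).
    """
    np.random.seed(seed)
    M, L = msa.shape
    q = T.shape[2]
    fi = np.zeros((L, q))
    for m in range(M):
        for i in range(L):
            fi[i, msa[m, i]] += 1.0
    fi /= M
    F = pair_freqs(msa, L, q)
    D2 = _dist2(F, fi, T, L, q)
    best = msa.copy()
    best_D2 = D2
    delta = 1.0 / M
    n_stages = betas.shape[0]
    trace = np.empty((n_stages, 3))
    for stage in range(n_stages):
        beta = betas[stage]
        for _ in range(moves_per_stage):
            i = np.random.randint(L)
            m = np.random.randint(M)
            n = np.random.randint(M)
            am = msa[m, i]
            an = msa[n, i]
            if am == an:
                continue  # identical symbols: accepted, state unchanged
            dD2 = 0.0
            for j in range(L):
                if j == i:
                    continue
                bm = msa[m, j]
                bn = msa[n, j]
                if bm == bn:
                    continue
                if i < j:
                    p, r = i, j
                    t1 = fi[i, am] * fi[j, bm] + T[p, r, am, bm]
                    t2 = fi[i, an] * fi[j, bm] + T[p, r, an, bm]
                    t3 = fi[i, an] * fi[j, bn] + T[p, r, an, bn]
                    t4 = fi[i, am] * fi[j, bn] + T[p, r, am, bn]
                    v1 = F[p, r, am, bm]
                    v2 = F[p, r, an, bm]
                    v3 = F[p, r, an, bn]
                    v4 = F[p, r, am, bn]
                else:
                    p, r = j, i
                    t1 = fi[i, am] * fi[j, bm] + T[p, r, bm, am]
                    t2 = fi[i, an] * fi[j, bm] + T[p, r, bm, an]
                    t3 = fi[i, an] * fi[j, bn] + T[p, r, bn, an]
                    t4 = fi[i, am] * fi[j, bn] + T[p, r, bn, am]
                    v1 = F[p, r, bm, am]
                    v2 = F[p, r, bm, an]
                    v3 = F[p, r, bn, an]
                    v4 = F[p, r, bn, am]
                # (am,bm) loses delta, (an,bm) gains, (an,bn) loses, (am,bn) gains
                dD2 += -2.0 * delta * (v1 - t1) + delta * delta
                dD2 += 2.0 * delta * (v2 - t2) + delta * delta
                dD2 += -2.0 * delta * (v3 - t3) + delta * delta
                dD2 += 2.0 * delta * (v4 - t4) + delta * delta
            nd2 = D2 + dD2
            if nd2 < 0.0:
                nd2 = 0.0
            dd = np.sqrt(nd2) - np.sqrt(D2)
            if dd <= 0.0 or np.random.random() < np.exp(-beta * dd):
                for j in range(L):
                    if j == i:
                        continue
                    bm = msa[m, j]
                    bn = msa[n, j]
                    if bm == bn:
                        continue
                    if i < j:
                        F[i, j, am, bm] -= delta
                        F[i, j, an, bm] += delta
                        F[i, j, an, bn] -= delta
                        F[i, j, am, bn] += delta
                    else:
                        F[j, i, bm, am] -= delta
                        F[j, i, bm, an] += delta
                        F[j, i, bn, an] -= delta
                        F[j, i, bn, am] += delta
                msa[m, i] = an
                msa[n, i] = am
                D2 = nd2
                if D2 < best_D2:
                    best_D2 = D2
                    best[:, :] = msa
        # guard against float drift across stages
        F = pair_freqs(msa, L, q)
        D2 = _dist2(F, fi, T, L, q)
        trace[stage, 0] = beta
        trace[stage, 1] = np.sqrt(D2)
        trace[stage, 2] = np.sqrt(best_D2)
    return best, np.sqrt(best_D2), trace


# ---------------------------------------------------------------------------
# tree path lengths


@njit(cache=True)
def pair_path_lengths(parent, blen, depth, u_arr, v_arr):
    """Patristic distance for each (u, v) node pair via two-pointer LCA walk."""
    out = np.empty(u_arr.shape[0])
    for k in range(u_arr.shape[0]):
        u = u_arr[k]
        v = v_arr[k]
        du = depth[u]
        dv = depth[v]
        t = 0.0
        while du > dv:
            t += blen[u]
            u = parent[u]
            du -= 1
        while dv > du:
            t += blen[v]
            v = parent[v]
            dv -= 1
        while u != v:
            t += blen[u] + blen[v]
            u = parent[u]
            v = parent[v]
        out[k] = t
    return out
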