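"""Fused numba kernel for the likelihood objective.

One call assembles the generator from free rates, exponentiates it along every
branch through a spectral decomposition, and runs the pruning recursion. The
kernel returns NaN whenever the decomposition is numerically untrustworthy
(ill-conditioned eigenvectors, invalid probabilities); the caller then falls
back to the scaling-and-squaring path in :mod:`ptmcoevo.ctmc`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: prior_kind codes
PRIOR_FIXED = 0
PRIOR_STATIONARY = 1


@njit(cache=True)
def neg_loglik(
    logp,  # float64[n_free] log10 rates
    slot_map,  # int64[m] free-parameter index per slot
    slot_rows,  # int64[m]
    slot_cols,  # int64[m]
    k,  # state count
    lengths,  # float64[n] branch length above each node (postorder, root last)
    parent,  # int64[n]
    tip_state,  # int64[n] -2 internal, -1 ambiguous, else 0..k-1
    prior_kind,  # PRIOR_FIXED or PRIOR_STATIONARY
    prior_weights,  # float64[k], used when PRIOR_FIXED
):  # pragma: no cover - jitted
    m = slot_map.shape[0]
    rates = 10.0 ** logp
    Q = np.zeros((k, k))
    for s in range(m):
        Q[slot_rows[s], slot_cols[s]] = rates[slot_map[s]]
    for i in range(k):
        tot = 0.0
        for j in range(k):
            if j != i:
                tot += Q[i, j]
        Q[i, i] = -tot

    if prior_kind == PRIOR_STATIONARY:
        A = np.empty((k + 1, k))
        for i in range(k):
            for j in range(k):
                A[i, j] = Q[j, i]
        for j in range(k):
            A[k, j] = 1.0
        b = np.zeros(k + 1)
        b[k] = 1.0
        pi, _, rank, _ = np.linalg.lstsq(A, b)
        if rank < k:
            return np.nan
        prior = np.empty(k)
        tot = 0.0
        for j in range(k):
            v = pi[j]
            if v < 0.0:
                if v < -1e-8:
                    return np.nan
                v = 0.0
            prior[j] = v
            tot += v
        if tot <= 0.0:
            return np.nan
        for j in range(k):
            prior[j] /= tot
    else:
        prior = prior_weights

    Qc = Q.astype(np.complex128)
    w, V = np.linalg.eig(Qc)
    Vinv = np.linalg.inv(V)
    # 1-norm condition estimate of the eigenvector matrix
    nv = 0.0
    ni = 0.0
    for j in range(k):
        cv = 0.0
        ci = 0.0
        for i in range(k):
            cv += abs(V[i, j])
            ci += abs(Vinv[i, j])
        if cv > nv:
            nv = cv
        if ci > ni:
            ni = ci
    if not np.isfinite(nv * ni) or nv * ni > 1e8:
        return np.nan

    n = lengths.shape[0]
    P = np.empty((n, k, k))
    E = np.empty(k, dtype=np.complex128)
    for t in range(n):
        for j in range(k):
            E[j] = np.exp(w[j] * lengths[t])
        for a in range(k):
            rs = 0.0
            for b2 in range(k):
                acc = 0.0 + 0.0j
                for j in range(k):
                    acc += V[a, j] * E[j] * Vinv[j, b2]
                v = acc.real
                if v < 0.0:
                    if v < -1e-8:
                        return np.nan
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                P[t, a, b2] = v
                rs += v
            if abs(rs - 1.0) > 1e-6:
                return np.nan
            for b2 in range(k):
                P[t, a, b2] /= rs

    # pruning with per-node rescaling
    partial = np.ones((n, k))
    for i in range(n):
        s = tip_state[i]
        if s >= 0:
            for j in range(k):
                partial[i, j] = 0.0
            partial[i, s] = 1.0
    logscale = 0.0
    for i in range(n - 1):
        tot = 0.0
        for j in range(k):
            tot += partial[i, j]
        if tot <= 0.0:
            return np.inf  # impossible data, not a numerical failure
        inv = 1.0 / tot
        for j in range(k):
            partial[i, j] *= inv
        logscale += np.log(tot)
        p = parent[i]
        for a in range(k):
            acc2 = 0.0
            for b2 in range(k):
                acc2 += P[i, a, b2] * partial[i, b2]
            partial[p, a] *= acc2
    tot = 0.0
    for j in range(k):
        tot += prior[j] * partial[n - 1, j]
    if tot <= 0.0:
        return np.inf
    return -(np.log(tot) + logscale)
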