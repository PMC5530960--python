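"""Numba kernel for the pruning (post-order) likelihood.

The tree is flattened once per dataset into postorder arrays; the kernel is
state-dimension agnostic (used with k=4 for the joint character and k=2 for
single-trait factorizations). Per-node rescaling keeps partials in range on
large trees.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pruning_loglik(parent, tip_state, P, prior):  # pragma: no cover - jitted
    """Log-likelihood of tip states by Felsenstein pruning.

    parent     int64[n]   parent index per node; nodes in postorder, root last
    tip_state  int64[n]   -2 internal, -1 ambiguous tip, else state 0..k-1
    P          float64[n,k,k]  transition matrix on the edge above each node
    prior      float64[k] root state distribution
    """
    n = parent.shape[0]
    k = prior.shape[0]
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
            return -np.inf
        inv = 1.0 / tot
        for j in range(k):
            partial[i, j] *= inv
        logscale += np.log(tot)
        p = parent[i]
        for a in range(k):
            acc = 0.0
            for b in range(k):
                acc += P[i, a, b] * partial[i, b]
            partial[p, a] *= acc
    root = n - 1
    tot = 0.0
    for j in range(k):
        tot += prior[j] * partial[root, j]
    if tot <= 0.0:
        return -np.inf
    return np.log(tot) + logscale


@njit(cache=True)
def pruning_partials(parent, tip_state, P, k):  # pragma: no cover - jitted
    """Scaled post-order partial likelihood vectors for every node (used by
    the stochastic-mapping node-state sampler). Returns float64[n, k]."""
    n = parent.shape[0]
    partial = np.ones((n, k))
    for i in range(n):
        s = tip_state[i]
        if s >= 0:
            for j in range(k):
                partial[i, j] = 0.0
            partial[i, s] = 1.0
    for i in range(n - 1):
        tot = 0.0
        for j in range(k):
            tot += partial[i, j]
        if tot <= 0.0:
            continue
        inv = 1.0 / tot
        for j in range(k):
            partial[i, j] *= inv
        p = parent[i]
        for a in range(k):
            acc = 0.0
            for b in range(k):
                acc += P[i, a, b] * partial[i, b]
            partial[p, a] *= acc
    return partial
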