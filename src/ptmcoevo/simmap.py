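"""Stochastic character mapping and transition contingency tests.

Histories of the combined character are sampled conditional on the observed
tip states and a rate matrix: node states are drawn from their joint
conditional distribution (post-order pruning partials followed by pre-order
sampling), and each branch path is then sampled conditional on its endpoint
states by uniformization (a rejection fallback covers numerically extreme
branches).

Transitions are scored Ridley-style: a branch contributes only when its
beginning and end states differ, in which case the *end* state's cell is
incremented. Aggregated over maps, the four end-state counts form a 2x2
table (rows = X value of the end state, columns = Y value), on which Yates'
chi-square and Fisher's exact test ask whether transition outcomes in the two
traits are associated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.stats

from ._pruning import pruning_partials
from .ctmc import (
    BranchPath,
    History,
    ModelSpec,
    RootPrior,
    build_Q,
    transition_matrices_for_lengths,
)
from .inference import TreeIndex, _resolve_prior
from .traits import AMBIGUOUS, STATE_PAIRS

_MAX_BRIDGE_RETRIES = 100


@dataclass(frozen=True)
class TransitionTable:
    """2x2 counts of transition end states: rows X in {0,1}, cols Y in {0,1}."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2) or np.any(c < 0):
            raise ValueError("counts must be a non-negative 2x2 table")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_state_counts(cls, four: Sequence[int]) -> "TransitionTable":
        """From counts in combined-state order 1..4 = (0,0),(0,1),(1,0),(1,1)."""
        four = np.asarray(four, dtype=np.int64)
        table = np.zeros((2, 2), dtype=np.int64)
        for state, cnt in zip((1, 2, 3, 4), four):
            x, y = STATE_PAIRS[state]
            table[x, y] = cnt
        return cls(counts=table)


# ---------------------------------------------------------------------------
# Endpoint-conditioned branch paths (uniformization)
# ---------------------------------------------------------------------------

def _sample_bridge(
    a: int, b: int, t: float, Q: np.ndarray, Pab: float, rng: np.random.Generator
) -> BranchPath:
    """Sample a path on one branch conditional on start state ``a`` and end
    state ``b`` (0-based) via uniformization; states are returned 1-based."""
    k = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0.0 or t <= 0.0:
        if a != b:
            raise RuntimeError("cannot bridge endpoints with zero rate or length")
        return BranchPath([(a + 1, t)])
    R = np.eye(k) + Q / lam
    # number of virtual jumps: P(N=n) ∝ exp(-lam t) (lam t)^n / n! * R^n[a,b]
    mu = lam * t
    Rpow = [np.eye(k)]
    u = rng.random() * Pab
    n_jumps = None
    log_pois = -mu
    cum = 0.0
    n_cap = int(mu + 12.0 * math.sqrt(mu + 1.0) + 50)
    for n in range(n_cap + 1):
        if n > 0:
            Rpow.append(Rpow[-1] @ R)
            log_pois += math.log(mu) - math.log(n)
        term = math.exp(log_pois) * Rpow[n][a, b]
        cum += term
        if u <= cum:
            n_jumps = n
            break
    if n_jumps is None:
        # numerically extreme branch: fall back to the largest plausible n
        n_jumps = n_cap
    if n_jumps == 0:
        return BranchPath([(a + 1, t)])
    times = np.sort(rng.random(n_jumps)) * t
    states = [a]
    for i in range(1, n_jumps):
        s_prev = states[-1]
        w = R[s_prev, :] * Rpow[n_jumps - i][:, b]
        tot = w.sum()
        if tot <= 0:
            raise RuntimeError("bridge sampling failed: zero transition weight")
        states.append(int(rng.choice(k, p=w / tot)))
    states.append(b)
    # collapse virtual (self) jumps into dwell segments
    segments: List[Tuple[int, float]] = []
    bounds = np.concatenate([[0.0], times, [t]])
    cur_state = states[0]
    cur_len = bounds[1] - bounds[0]
    for i in range(1, len(states)):
        seg_len = bounds[i + 1] - bounds[i]
        if states[i] == cur_state:
            cur_len += seg_len
        else:
            segments.append((cur_state + 1, cur_len))
            cur_state = states[i]
            cur_len = seg_len
    segments.append((cur_state + 1, cur_len))
    return BranchPath(segments)


def sample_branch_path(
    a: int, b: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> BranchPath:
    """Endpoint-conditioned path for 1-based states ``a`` -> ``b``."""
    from .ctmc import transition_matrix

    Pab = float(transition_matrix(Q, t)[a - 1, b - 1])
    last_err = None
    for _ in range(_MAX_BRIDGE_RETRIES):
        try:
            return _sample_bridge(a - 1, b - 1, t, Q, Pab, rng)
        except RuntimeError as err:
            last_err = err
    raise RuntimeError(f"failed to bridge branch after {_MAX_BRIDGE_RETRIES} tries: {last_err}")


# ---------------------------------------------------------------------------
# History sampling
# ---------------------------------------------------------------------------

def sample_histories(
    tree,
    tips: Dict[str, int],
    Q: np.ndarray,
    n_maps: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    prior: Union[str, RootPrior] = "equal",
) -> List[History]:
    """Sample ``n_maps`` character histories conditional on the tip states.

    Node states are drawn from their exact joint conditional distribution
    under ``Q`` and the root prior; branch paths are then filled in by
    uniformization conditioned on the sampled endpoints.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    prior_r = _resolve_prior(prior, tips)
    weights = prior_r.resolve(Q, k=k)

    nodes = list(tree.postorder_node_iter())
    idx = TreeIndex(tree)
    tip_arr = idx.tip_state_array(tips, k=k)
    P = transition_matrices_for_lengths(Q, idx.lengths)
    partial = pruning_partials(idx.parent, tip_arr, P, k)

    node_order = nodes  # same postorder as TreeIndex
    histories: List[History] = []
    for _ in range(n_maps):
        states = np.full(idx.n_nodes, -1, dtype=np.int64)
        # root (last in postorder)
        w = weights * partial[idx.n_nodes - 1]
        tot = w.sum()
        if tot <= 0:
            raise ValueError("tip states have zero likelihood under this model")
        states[idx.n_nodes - 1] = rng.choice(k, p=w / tot)
        # pre-order = reversed postorder
        for i in range(idx.n_nodes - 2, -1, -1):
            par = states[idx.parent[i]]
            w = P[i][par, :] * partial[i]
            tot = w.sum()
            if tot <= 0:
                raise ValueError("conditional node sampling failed (zero weight)")
            states[i] = rng.choice(k, p=w / tot)
        node_states: Dict[int, int] = {}
        branch_paths: Dict[int, BranchPath] = {}
        tip_states: Dict[str, int] = {}
        for i, node in enumerate(node_order):
            node_states[id(node)] = int(states[i]) + 1
            if node.parent_node is not None:
                a = int(states[idx.parent[i]]) + 1
                b = int(states[i]) + 1
                branch_paths[id(node)] = sample_branch_path(
                    a, b, idx.lengths[i], Q, rng
                )
            if node.is_leaf():
                tip_states[node.taxon.label] = int(states[i]) + 1
        histories.append(
            History(node_states=node_states, branch_paths=branch_paths, tip_states=tip_states)
        )
    return histories


def sample_q_posterior(
    tree,
    tips: Dict[str, int],
    n_draws: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    prior: Union[str, RootPrior] = "equal",
    step: float = 0.3,
    burn_in: int = 200,
    thin: int = 50,
) -> List[np.ndarray]:
    """Approximate posterior draws of the dependent-model Q.

    A deliberately simple random-walk Metropolis sampler over log10 rates with
    independent Exp(1) priors on the rates; intended for sensitivity checks of
    the mapping to rate uncertainty rather than for rigorous Bayesian
    inference.
    """
    from .inference import _neg_loglik_factory

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = ModelSpec.dependent()
    prior_r = _resolve_prior(prior, tips)
    idx = TreeIndex(tree)
    tip_arr = idx.tip_state_array(tips, k=4)
    neg = _neg_loglik_factory(idx, tip_arr, spec, prior_r, k=4)

    def log_post(logp: np.ndarray) -> float:
        ll = -neg(logp)
        rates = 10.0 ** logp
        # Exp(1) prior on each rate, plus the log-scale Jacobian
        return ll - rates.sum() + np.log(rates).sum()

    x = rng.uniform(-1.0, 0.0, size=spec.n_free)
    lp = log_post(x)
    draws: List[np.ndarray] = []
    total = burn_in + n_draws * thin
    for it in range(total):
        prop = x + rng.normal(0.0, step, size=x.shape)
        prop = np.clip(prop, -8.0, 3.0)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            draws.append(build_Q(10.0 ** x, spec))
    return draws


# ---------------------------------------------------------------------------
# Transition scoring and contingency tests
# ---------------------------------------------------------------------------

def count_transition_endstates(
    histories: Sequence[History],
) -> Tuple[TransitionTable, np.ndarray]:
    """Tally branches whose begin and end states differ, by end state.

    Branches with no net change are not scored (their endpoints share the
    ancestor's state and are not independent data points). Counts aggregate
    over all histories. Returns the 2x2 table and the raw 4-vector in
    combined-state order.
    """
    if not histories:
        raise ValueError("no histories to count")
    four = np.zeros(4, dtype=np.int64)
    for h in histories:
        for path in h.branch_paths.values():
            if path.start_state != path.end_state:
                four[path.end_state - 1] += 1
    return TransitionTable.from_state_counts(four), four


def yates_chi2(table: TransitionTable) -> Tuple[float, float]:
    """Yates-corrected chi-square test of independence on a 2x2 table.

    statistic = sum of max(|o - e| - 0.5, 0)^2 / e with expectations from the
    product of margins; p from the upper chi-square(1) tail.
    """
    obs = table.counts.astype(float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("Yates' test requires all margins > 0")
    expected = np.outer(rows, cols) / total
    stat = float(np.sum(np.maximum(np.abs(obs - expected) - 0.5, 0.0) ** 2 / expected))
    return stat, float(scipy.stats.chi2.sf(stat, 1))


def fisher_exact(table: TransitionTable) -> float:
    """Two-sided Fisher exact test p-value on the 2x2 table."""
    return float(scipy.stats.fisher_exact(table.counts, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# SIMMAP-style export
# ---------------------------------------------------------------------------

def history_to_simmap(tree, history: History) -> str:
    """Render one history as a SIMMAP-style annotated Newick string, each
    branch carrying its {state,dwell:...} segments child-to-parent."""

    def render(node) -> str:
        if node.is_leaf():
            body = node.taxon.label
        else:
            body = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
        if node.parent_node is None:
            return body + ";"
        path = history.branch_paths[id(node)]
        segs = ":".join(f"{s},{l:.6g}" for s, l in reversed(path.segments))
        return f"{body}:{{{segs}}}"

    return render(tree.seed_node)
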