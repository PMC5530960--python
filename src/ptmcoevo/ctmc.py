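"""The four-state continuous-time Markov model of paired binary traits.

States 1..4 encode the ordered trait pair (X, Y) as (0,0), (0,1), (1,0),
(1,1). Single-trait transitions are allowed; simultaneous changes of both
traits, 1<->4 and 2<->3, have rate zero (the probability of two changes in
the same instant dt is negligible). The generator is therefore specified by
eight rates:

    q12: (0,0)->(0,1)  Y gained while X=0      q21: its reversal
    q13: (0,0)->(1,0)  X gained while Y=0      q31: its reversal
    q24: (0,1)->(1,1)  X gained while Y=1      q42: its reversal
    q34: (1,0)->(1,1)  Y gained while X=1      q43: its reversal

The *dependent* model leaves all eight free. The *independent* model forbids
either trait's rates from depending on the other's state, tying
q12=q34, q13=q24, q21=q43 and q31=q42 (four free parameters). Arbitrary
extra equality ties (e.g. ``"q12=q34"`` alone) define the reduced models used
to ask directional questions about which trait drives the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg

#: Fixed slot order used everywhere rates are packed into vectors.
SLOTS: Tuple[str, ...] = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")

_SLOT_POS: Dict[str, Tuple[int, int]] = {
    "q12": (0, 1),
    "q13": (0, 2),
    "q21": (1, 0),
    "q24": (1, 3),
    "q31": (2, 0),
    "q34": (2, 3),
    "q42": (3, 1),
    "q43": (3, 2),
}

#: Forbidden instantaneous double transitions.
FORBIDDEN: Tuple[Tuple[int, int], ...] = ((0, 3), (3, 0), (1, 2), (2, 1))

RATE_LOWER = 1e-8
RATE_UPPER = 1e3


@dataclass(frozen=True)
class ModelSpec:
    """A parameterization of the 8 transition slots.

    ``tying`` maps every slot name to a free-parameter index; slots sharing an
    index share a rate. Free parameters are indexed by first appearance in
    :data:`SLOTS` order, so parameter vectors are reproducible across runs.
    """

    tying: Dict[str, int]
    name: str = "custom"

    def __post_init__(self) -> None:
        if set(self.tying) != set(SLOTS):
            missing = set(SLOTS) - set(self.tying)
            extra = set(self.tying) - set(SLOTS)
            raise ValueError(f"tying must map all 8 slots (missing={missing}, extra={extra})")
        idx = [self.tying[s] for s in SLOTS]
        # canonical: indices are 0..n_free-1 in first-appearance order
        seen: List[int] = []
        for i in idx:
            if i not in seen:
                seen.append(i)
        if seen != list(range(len(seen))):
            raise ValueError("tying indices must be 0..n_free-1 in first-appearance order")

    @property
    def n_free(self) -> int:
        return len(set(self.tying.values()))

    def index_array(self) -> np.ndarray:
        return np.array([self.tying[s] for s in SLOTS], dtype=np.int64)

    @classmethod
    def dependent(cls) -> "ModelSpec":
        return cls(tying={s: i for i, s in enumerate(SLOTS)}, name="dependent")

    @classmethod
    def independent(cls) -> "ModelSpec":
        """Four free parameters, in slot order: Y-gain (q12=q34), X-gain
        (q13=q24), Y-loss (q21=q43), X-loss (q31=q42)."""
        tying = {
            "q12": 0, "q13": 1, "q21": 2, "q24": 1,
            "q31": 3, "q34": 0, "q42": 3, "q43": 2,
        }
        return cls(tying=tying, name="independent")

    @classmethod
    def from_preset(cls, name: str) -> "ModelSpec":
        if name == "dependent":
            return cls.dependent()
        if name == "independent":
            return cls.independent()
        raise ValueError(f"unknown preset {name!r}")

    @classmethod
    def with_ties(cls, constraints: str, name: Optional[str] = None) -> "ModelSpec":
        """Dependent model with extra equality ties, e.g. ``"q12=q34"`` or
        ``"q12=q34,q21=q43"``. Slots within one '=' group share a rate."""
        groups: List[set] = [{s} for s in SLOTS]

        def find(slot: str) -> set:
            for g in groups:
                if slot in g:
                    return g
            raise ValueError(f"unknown slot {slot!r}")

        for part in constraints.split(","):
            part = part.strip()
            if not part:
                continue
            members = [m.strip() for m in part.split("=")]
            if len(members) < 2:
                raise ValueError(f"malformed constraint {part!r}")
            base = find(members[0])
            for m in members[1:]:
                g = find(m)
                if g is not base:
                    base |= g
                    groups.remove(g)
        tying: Dict[str, int] = {}
        next_idx = 0
        for s in SLOTS:
            if s not in tying:
                g = find(s)
                for m in g:
                    tying[m] = next_idx
                next_idx += 1
        return cls(tying=tying, name=name or f"dependent[{constraints}]")


def build_Q(params: Sequence[float], spec: ModelSpec) -> np.ndarray:
    """Assemble the 4x4 generator from free rates under ``spec``'s tying."""
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_free,):
        raise ValueError(f"expected {spec.n_free} rates, got {params.shape}")
    if np.any(params < 0):
        raise ValueError("rates must be non-negative")
    Q = np.zeros((4, 4))
    for slot, (i, j) in _SLOT_POS.items():
        Q[i, j] = params[spec.tying[slot]]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def rates_by_slot(params: Sequence[float], spec: ModelSpec) -> Dict[str, float]:
    params = np.asarray(params, dtype=float)
    return {s: float(params[spec.tying[s]]) for s in SLOTS}


# ---------------------------------------------------------------------------
# Transition probabilities and stationary distribution
# ---------------------------------------------------------------------------

def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt), cleaned to a proper stochastic matrix.

    Spectral decomposition is used when it is numerically trustworthy;
    otherwise (near-defective Q) the scaling-and-squaring Padé exponential is
    the fallback. Entries are clipped to [0, 1] (negatives beyond 1e-8 or row
    sums off by more than 1e-6 trigger the fallback rather than being hidden).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    Q = np.asarray(Q, dtype=float)
    P = _expm_eig_batch(Q, np.array([t]))
    if P is None:
        P = np.asarray([scipy.linalg.expm(Q * t)])
    return _clean_stochastic(P[0])


def _expm_eig_batch(Q: np.ndarray, ts: np.ndarray) -> Optional[np.ndarray]:
    """exp(Q t) for a batch of times via one eigendecomposition; ``None`` when
    the decomposition is ill-conditioned or produces an invalid result."""
    try:
        w, V = np.linalg.eig(Q.astype(np.complex128))
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        return None
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e8:
        return None
    E = np.exp(np.multiply.outer(ts, w))  # (m, k)
    P = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
    if not np.all(np.isfinite(P)):
        return None
    if np.any(P < -1e-8) or np.any(np.abs(P.sum(axis=2) - 1.0) > 1e-6):
        return None
    return P


def _clean_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.clip(P, 0.0, 1.0)
    rows = P.sum(axis=-1, keepdims=True)
    return P / rows


def transition_matrices_for_lengths(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every branch length; eigen path with Padé fallback."""
    P = _expm_eig_batch(Q, lengths)
    if P is None:
        P = np.stack([scipy.linalg.expm(Q * t) for t in lengths])
    return _clean_stochastic(P)


def is_irreducible(Q: np.ndarray, tol: float = 0.0) -> bool:
    """Strong connectivity of the positive-rate transition graph."""
    k = Q.shape[0]
    adj = Q > tol
    for start in range(k):
        seen = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for j in range(k):
                if j != i and adj[i, j] and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(seen) != k:
            return False
    return True


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1; raises if Q is reducible."""
    Q = np.asarray(Q, dtype=float)
    if not is_irreducible(Q):
        raise ValueError("rate matrix is reducible; stationary distribution not unique")
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, k))])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Root priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RootPrior:
    """Distribution over the four states at the root.

    ``kind`` is one of ``equal``, ``stationary``, ``observed`` or ``custom``.
    For ``stationary`` the weights are a function of the rate matrix and are
    recomputed wherever Q changes (e.g. inside the likelihood optimizer);
    ``weights`` then stores the realized values for the final Q.
    """

    kind: str
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("equal", "stationary", "observed", "custom"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("weights must be a probability vector")
            object.__setattr__(self, "weights", w)
        elif self.kind in ("observed", "custom"):
            raise ValueError(f"{self.kind!r} prior requires explicit weights")

    def resolve(self, Q: Optional[np.ndarray] = None, k: int = 4) -> np.ndarray:
        if self.kind == "equal":
            return np.full(k, 1.0 / k)
        if self.kind == "stationary":
            if Q is None:
                raise ValueError("stationary prior needs a rate matrix")
            return stationary_distribution(Q)
        return self.weights


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class BranchPath:
    """Piecewise-constant state path along one branch: (state, dwell) segments
    in parent-to-child order; dwells sum to the branch length."""

    segments: List[Tuple[int, float]]

    @property
    def start_state(self) -> int:
        return self.segments[0][0]

    @property
    def end_state(self) -> int:
        return self.segments[-1][0]

    @property
    def n_changes(self) -> int:
        return len(self.segments) - 1


@dataclass
class History:
    """A complete character history on a tree: a state (1..4) at every node
    and a :class:`BranchPath` above every non-root node, keyed by node id."""

    node_states: Dict[int, int]
    branch_paths: Dict[int, BranchPath]
    tip_states: Dict[str, int]


def _draw_root_state(root: Union[int, RootPrior], Q: np.ndarray, rng: np.random.Generator, k: int) -> int:
    if isinstance(root, RootPrior):
        weights = root.resolve(Q, k=k)
        return int(rng.choice(k, p=weights)) + 1
    if not 1 <= int(root) <= k:
        raise ValueError(f"root state must be in 1..{k}")
    return int(root)


def _gillespie_branch(state0: int, t: float, Q: np.ndarray, rng: np.random.Generator) -> BranchPath:
    """Exact simulation of the chain along one branch (exponential waits,
    jump probabilities q_ij / -q_ii). States are 1-based."""
    segments: List[Tuple[int, float]] = []
    s = state0 - 1
    remaining = t
    while True:
        rate = -Q[s, s]
        if rate <= 0.0:
            segments.append((s + 1, remaining))
            return BranchPath(segments)
        wait = rng.exponential(1.0 / rate)
        if wait >= remaining:
            segments.append((s + 1, remaining))
            return BranchPath(segments)
        segments.append((s + 1, wait))
        remaining -= wait
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = probs / rate
        s = int(rng.choice(Q.shape[0], p=probs))


def simulate_history(
    tree,
    Q: np.ndarray,
    root: Union[int, RootPrior],
    seed: Union[int, np.random.Generator],
) -> History:
    """Evolve the character down the tree by Gillespie simulation, retaining
    the full piecewise-constant path on every branch."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    node_states: Dict[int, int] = {}
    branch_paths: Dict[int, BranchPath] = {}
    tip_states: Dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_states[id(node)] = _draw_root_state(root, Q, rng, k)
        else:
            parent_state = node_states[id(node.parent_node)]
            path = _gillespie_branch(parent_state, node.edge.length or 0.0, Q, rng)
            branch_paths[id(node)] = path
            node_states[id(node)] = path.end_state
        if node.is_leaf():
            tip_states[node.taxon.label] = node_states[id(node)]
    return History(node_states=node_states, branch_paths=branch_paths, tip_states=tip_states)


def simulate_tip_states(
    tree,
    Q: np.ndarray,
    root: Union[int, RootPrior],
    seed: Union[int, np.random.Generator],
    n_replicates: int = 1,
) -> List[Dict[str, int]]:
    """Sample tip states only (no within-branch paths), vectorized across
    replicates: each branch uses its exact transition matrix, so the marginal
    law of the tips matches :func:`simulate_history`."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    nodes = list(tree.preorder_node_iter())
    lengths = np.array([n.edge.length or 0.0 for n in nodes[1:]], dtype=float)
    P = transition_matrices_for_lengths(Q, lengths) if len(lengths) else np.empty((0, k, k))
    cum = np.cumsum(P, axis=2)
    states: Dict[int, np.ndarray] = {}
    if isinstance(root, RootPrior):
        weights = root.resolve(Q, k=k)
        states[id(nodes[0])] = rng.choice(k, size=n_replicates, p=weights)
    else:
        states[id(nodes[0])] = np.full(n_replicates, int(root) - 1)
    out: List[Dict[str, int]] = [dict() for _ in range(n_replicates)]
    for bi, node in enumerate(nodes[1:]):
        ps = states[id(node.parent_node)]
        u = rng.random(n_replicates)
        s = (u[:, None] > cum[bi][ps]).sum(axis=1)
        states[id(node)] = s
        if node.is_leaf():
            lab = node.taxon.label
            for r in range(n_replicates):
                out[r][lab] = int(s[r]) + 1
    return out
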