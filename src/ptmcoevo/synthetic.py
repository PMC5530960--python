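"""Synthetic trees, trait histories and alignments for end-to-end testing.

Every stage of the pipeline can be exercised without external data: a Yule
(pure-birth) tree is simulated, the combined four-state character is evolved
along it under an independent, dependent, or single-origin ("darwin")
scenario, and an alignment is emitted whose two focal columns carry residues
consistent with the simulated trait states (phospho-acceptors S/T and
methionine M for state 1; residues from a disjoint pool for state 0), so that
decoding the alignment with the generating trait definitions returns exactly
the simulated states.

The single-origin scenario plants both traits once in one internal clade and
lets nothing else change: the co-distribution it produces is the classic
confound for correlation tests (shared ancestry, not repeated correlated
change), and is what the pairwise-contrast machinery is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import dendropy
import numpy as np

from .ctmc import History, ModelSpec, RootPrior, build_Q, simulate_history
from .phylo import Alignment
from .traits import STATE_PAIRS, TraitDefinition

#: residues drawn for trait state 1, per trait
X_STATE1_POOL = "ST"
Y_STATE1_POOL = "M"
#: residue pool for trait state 0, disjoint from both state-1 sets
STATE0_POOL = "AGLVE"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ScenarioConfig:
    """Everything needed to regenerate a synthetic dataset bit-for-bit."""

    n_tips: int = 100
    birth_rate: float = 1.0
    model: str = "independent"  # independent | dependent | darwin
    rates: Optional[Sequence[float]] = None
    root_state: Union[int, str] = "prior"  # a state 1..4 or "prior" (equal)
    focal_positions: Tuple[int, int] = (6, 10)
    background_length: int = 20
    gap_rate: float = 0.0  # per focal residue, to exercise ambiguity handling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if self.model not in ("independent", "dependent", "darwin"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.focal_positions[0] == self.focal_positions[1]:
            raise ValueError("focal positions must be distinct")
        if self.rates is not None and np.any(np.asarray(self.rates, float) < 0):
            raise ValueError("rates must be non-negative")

    def default_rates(self) -> np.ndarray:
        if self.rates is not None:
            return np.asarray(self.rates, dtype=float)
        if self.model == "independent":
            # (y_gain, x_gain, y_loss, x_loss)
            return np.array([0.5, 0.5, 1.0, 1.0])
        if self.model == "dependent":
            # strong interaction: gains 10x faster on the modified background
            base = {"q12": 0.5, "q13": 0.5, "q21": 1.0, "q24": 5.0,
                    "q31": 1.0, "q34": 5.0, "q42": 0.2, "q43": 0.2}
            from .ctmc import SLOTS
            return np.array([base[s] for s in SLOTS])
        return np.zeros(0)  # darwin: no Markov rates


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant tips, labeled sp0001, sp0002, ...

    Waiting times between birth events are exponential with rate
    ``k * birth_rate`` for ``k`` live lineages; all lineages extend to the
    present, so the tree is ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    live: List[dendropy.Node] = []
    birth_time: Dict[int, float] = {}
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        live.append(child)
        birth_time[id(child)] = 0.0
    while len(live) < n_tips:
        t += rng.exponential(1.0 / (len(live) * birth_rate))
        i = int(rng.integers(len(live)))
        node = live.pop(i)
        node.edge.length = t - birth_time[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            live.append(child)
            birth_time[id(child)] = t
    t += rng.exponential(1.0 / (len(live) * birth_rate))
    for i, node in enumerate(live):
        node.edge.length = t - birth_time[id(node)]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = dendropy.Taxon(label=f"sp{i + 1:04d}")
        leaf.taxon = taxon
        tree.taxon_namespace.add_taxon(taxon)
    return tree


def _darwin_states(tree, rng: np.random.Generator) -> Tuple[Dict[str, int], Dict[int, int]]:
    """Plant states: one internal clade (20-50% of tips) fixed at state 4,
    everything else state 1, no subsequent change."""
    n = len(tree.leaf_nodes())
    lo, hi = max(2, int(0.2 * n)), max(3, int(0.5 * n))
    candidates = []
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        size = len(node.leaf_nodes())
        if lo <= size <= hi:
            candidates.append(node)
    if not candidates:  # tiny trees: fall back to any non-root internal node
        candidates = [
            nd for nd in tree.preorder_internal_node_iter() if nd.parent_node is not None
        ]
    clade = candidates[int(rng.integers(len(candidates)))]
    clade_leaves = {id(l) for l in clade.leaf_nodes()}
    clade_nodes = {id(d) for d in clade.preorder_iter()}
    tips: Dict[str, int] = {}
    node_states: Dict[int, int] = {}
    for node in tree.preorder_node_iter():
        state = 4 if id(node) in clade_nodes else 1
        node_states[id(node)] = state
        if node.is_leaf():
            tips[node.taxon.label] = state
    return tips, node_states


def simulate_dataset(
    config: ScenarioConfig,
) -> Tuple[dendropy.Tree, Alignment, Dict[str, int], Dict]:
    """Generate (tree, alignment, combined tip states, truth record).

    The truth record stores the configuration, generating rates, internal
    node states and the trait definitions needed to decode the alignment, so
    the dataset is reproducible bit-for-bit from the seed.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, rng)
    truth: Dict = {
        "config": {
            "n_tips": config.n_tips,
            "birth_rate": config.birth_rate,
            "model": config.model,
            "root_state": config.root_state,
            "focal_positions": list(config.focal_positions),
            "background_length": config.background_length,
            "gap_rate": config.gap_rate,
            "seed": config.seed,
        }
    }
    if config.model == "darwin":
        tips, node_states = _darwin_states(tree, rng)
        truth["rates"] = None
    else:
        spec = ModelSpec.from_preset(config.model)
        rates = config.default_rates()
        Q = build_Q(rates, spec)
        root = (
            RootPrior(kind="equal")
            if config.root_state == "prior"
            else int(config.root_state)
        )
        hist = simulate_history(tree, Q, root, rng)
        tips = hist.tip_states
        node_states = hist.node_states
        truth["rates"] = list(map(float, rates))
        truth["Q"] = Q.tolist()
    truth["node_states"] = {
        (node.taxon.label if node.is_leaf() else f"node{i}"): node_states[id(node)]
        for i, node in enumerate(tree.preorder_node_iter())
    }
    truth["tip_states"] = dict(tips)

    # alignment: background columns i.i.d. uniform; focal columns encode traits
    xpos, ypos = config.focal_positions
    L = config.background_length
    if not (1 <= xpos <= L and 1 <= ypos <= L):
        raise ValueError("focal positions must lie within the background length")
    records: List[Tuple[str, str]] = []
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    for lab in labels:
        chars = [_AA20[i] for i in rng.integers(0, 20, size=L)]
        x, y = STATE_PAIRS[tips[lab]]
        pool_x = X_STATE1_POOL if x == 1 else STATE0_POOL
        pool_y = Y_STATE1_POOL if y == 1 else STATE0_POOL
        chars[xpos - 1] = pool_x[int(rng.integers(len(pool_x)))]
        chars[ypos - 1] = pool_y[int(rng.integers(len(pool_y)))]
        # the first tip acts as the (ungapped) reference, so it never gets gaps
        if config.gap_rate > 0.0 and lab != labels[0]:
            for pos in (xpos - 1, ypos - 1):
                if rng.random() < config.gap_rate:
                    chars[pos] = "-"
        records.append((lab, "".join(chars)))
    alignment = Alignment(records=records, reference_label=labels[0])
    truth["trait_x"] = {"position": xpos, "state1_residues": sorted(X_STATE1_POOL)}
    truth["trait_y"] = {"position": ypos, "state1_residues": sorted(Y_STATE1_POOL)}
    return tree, alignment, tips, truth


def trait_definitions(config: ScenarioConfig) -> Tuple[TraitDefinition, TraitDefinition]:
    """The trait definitions that decode a dataset from ``config``."""
    xpos, ypos = config.focal_positions
    return (
        TraitDefinition(position=xpos, state1_residues=frozenset(X_STATE1_POOL)),
        TraitDefinition(position=ypos, state1_residues=frozenset(Y_STATE1_POOL)),
    )
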