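"""Workflow drivers: the control battery of residue-set definitions and the
tree-robustness battery, returned as tidy DataFrames ready for TSV export."""

from __future__ import annotations

import hashlib
import json
import logging
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import phylo
from .inference import chi2_pvalue, run_coevolution_test
from .traits import AMBIGUOUS, TraitDefinition, control_sets, encode_traits

logger = logging.getLogger(__name__)


def _set_string(residues: Iterable[str]) -> str:
    return "{" + ",".join(sorted(residues)) + "}"


def _is_degenerate(states: Dict[str, int]) -> Tuple[bool, bool]:
    """(X constant, Y constant) across unambiguous tips."""
    xs = {(s - 1) // 2 for s in states.values() if s != AMBIGUOUS}
    ys = {(s - 1) % 2 for s in states.values() if s != AMBIGUOUS}
    return len(xs) <= 1, len(ys) <= 1


def run_control_battery(
    tree,
    alignment: phylo.Alignment,
    x_position: int,
    y_position: int,
    prior: str = "equal",
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    sets: Optional[Sequence[Tuple[frozenset, frozenset]]] = None,
) -> pd.DataFrame:
    """Coevolution LRT for the positive residue-set pair and every control.

    The same two alignment positions are re-scored under each residue-set
    definition; only the genuinely modification-related definition is expected
    to show a signal. When a definition leaves one trait constant across all
    (unambiguous) tips the two models coincide, so LRT = 0 and p = 1 are
    reported without running the optimizer. Raw (uncorrected) p-values are
    reported; pass the result to :func:`holm_correction` if desired.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for xset, yset in (sets if sets is not None else control_sets()):
        x = TraitDefinition(position=x_position, state1_residues=xset)
        y = TraitDefinition(position=y_position, state1_residues=yset)
        states = encode_traits(alignment, x, y)
        x_const, y_const = _is_degenerate(states)
        if x_const or y_const:
            lrt, p = 0.0, 1.0
        else:
            test, _, _ = run_coevolution_test(
                tree, states, prior=prior, n_restarts=n_restarts, seed=rng
            )
            lrt, p = test.lrt, test.p_chi2
        rows.append(
            {
                "set_x": _set_string(xset),
                "set_y": _set_string(yset),
                "lrt": round(lrt, 1),
                "p_value": round(p, 3),
            }
        )
    return pd.DataFrame(rows)


def holm_correction(table: pd.DataFrame, column: str = "p_value") -> pd.DataFrame:
    """Holm step-down adjusted p-values appended as ``p_holm``."""
    p = table[column].to_numpy(dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    out = table.copy()
    out["p_holm"] = np.round(adj, 3)
    return out


def run_robustness(
    trees: Sequence,
    alignment: phylo.Alignment,
    x: TraitDefinition,
    y: TraitDefinition,
    tree_ids: Optional[Sequence[str]] = None,
    prior: str = "equal",
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
) -> pd.DataFrame:
    """Repeat the coevolution test across alternative phylogenies.

    The first tree is the reference: topology difference and branch score are
    measured against it after pruning every tree to the taxa shared with the
    alignment. The reported log-likelihood is the dependent-model fit on the
    trait data (the quantity this pipeline maximizes); the Fitch score is the
    parsimony length of the full alignment on the tree.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if tree_ids is None:
        tree_ids = [f"tree{i}" for i in range(len(trees))]
    labels = set(alignment.labels)
    pruned = [phylo.prune_to_common_taxa(t, labels) for t in trees]
    common = set(phylo.tip_labels(pruned[0]))
    for t in pruned[1:]:
        common &= set(phylo.tip_labels(t))
    pruned = [
        phylo.prune_to_common_taxa(t, common) if set(phylo.tip_labels(t)) != common else t
        for t in pruned
    ]
    rows = []
    for tid, tree in zip(tree_ids, pruned):
        dist = phylo.tree_distance(pruned[0], tree)
        keep = [(lab, seq) for lab, seq in alignment.records if lab in common]
        sub_aln = phylo.Alignment(
            records=keep,
            reference_label=alignment.reference_label
            if alignment.reference_label in common
            else keep[0][0],
        )
        fitch = phylo.fitch_score(tree, sub_aln)
        states = encode_traits(sub_aln, x, y)
        test, _, dep = run_coevolution_test(
            tree, states, prior=prior, n_restarts=n_restarts, seed=rng
        )
        rows.append(
            {
                "tree": tid,
                "log_likelihood": dep.log_likelihood,
                "fitch_score": fitch,
                "topology_difference": dist.topology_difference,
                "branch_score": dist.branch_score,
                "lrt": round(test.lrt, 1),
                "p_value": round(test.p_chi2, 4),
            }
        )
    return pd.DataFrame(rows)


def config_hash(config: Dict) -> str:
    """Stable short hash of a JSON-serializable run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
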