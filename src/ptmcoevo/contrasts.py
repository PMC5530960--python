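"""Pairwise comparisons of phylogenetically separate contrasting tip pairs.

An anti-pseudo-replication complement to the likelihood machinery: find a
maximal set of tip pairs such that (a) the two members of each pair differ in
*both* binary traits, and (b) the tree paths connecting distinct pairs share
no nodes or edges. A pair is *positive* when the phospho-acceptor co-occurs
with the methionine in the same member — i.e. one member is in combined state
4 = (1,1) and the other in state 1 = (0,0); a pair of states {3, 2} =
{(1,0), (0,1)} is *negative*. A sign imbalance among the pairs is evidence of
correlated gains/losses that cannot be explained by one ancestral origin.

The maximal pairing is found by dynamic programming over the rooted tree: at
most one pair's path can cross any node, so each subtree contributes either a
closed solution or one "open" tip whose path continues upward. Among equally
large pairings the tie-break prefers smaller total patristic path length and
then lexicographic tip names, so results are deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import scipy.stats

from .traits import AMBIGUOUS

#: complementary state pairs and the sign of the pair they form
_PAIR_SIGN = {frozenset((1, 4)): "positive", frozenset((2, 3)): "negative"}


@dataclass(frozen=True)
class ContrastPairing:
    """pairs: (tipA, tipB, sign) with tipA < tipB lexicographically."""

    pairs: Tuple[Tuple[str, str, str], ...]
    maximal: bool = True

    @property
    def n_positive(self) -> int:
        return sum(1 for _, _, s in self.pairs if s == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for _, _, s in self.pairs if s == "negative")


# a DP cell is (count, total_len, names_key, pairs); "open" cells additionally
# carry the open tip and the path length from it to the current node.
_Cell = Tuple[int, float, Tuple[str, ...], Tuple[Tuple[str, str, str], ...]]


def _better(a: Optional[_Cell], b: Optional[_Cell]) -> Optional[_Cell]:
    if a is None:
        return b
    if b is None:
        return a
    ka = (-a[0], a[1], a[2])
    kb = (-b[0], b[1], b[2])
    return a if ka <= kb else b


def find_maximal_pairing(tree, tips: Dict[str, int], seed=None) -> ContrastPairing:
    """One maximal set of node-disjoint contrasting pairs.

    ``tips`` maps labels to combined states 1..4 (AMBIGUOUS tips are
    excluded from pairing). ``seed`` is accepted for interface stability but
    unused: tie-breaking is deterministic.
    """
    # closed[id(node)]: best cell with no open path leaving the subtree
    # open_[id(node)][state]: best cell with one open tip of that state, value
    #   = (count, total_len + len(open tip -> node), names, pairs, open_tip)
    closed: Dict[int, _Cell] = {}
    open_: Dict[int, Dict[int, Tuple]] = {}

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            state = tips.get(lab, AMBIGUOUS)
            closed[id(node)] = (0, 0.0, (), ())
            open_[id(node)] = (
                {state: (0, 0.0, (), (), lab)} if state != AMBIGUOUS else {}
            )
            continue
        kids = node.child_nodes()
        kid_closed = [closed[id(c)] for c in kids]
        base_count = sum(c[0] for c in kid_closed)
        base_len = sum(c[1] for c in kid_closed)

        # lift children's open cells across their edges
        lifted: List[Dict[int, Tuple]] = []
        for c in kids:
            el = c.edge.length or 0.0
            d = {}
            for st, (cnt, ln, names, pairs, tip) in open_[id(c)].items():
                d[st] = (cnt, ln + el, names, pairs, tip)
            lifted.append(d)

        def assemble(pairs_by_child, extra_pair=None) -> Tuple[tuple, tuple]:
            pairs = tuple(sorted(
                [p for ps in pairs_by_child for p in ps]
                + ([extra_pair] if extra_pair else [])
            ))
            names = tuple(sorted(n for t in pairs for n in t[:2]))
            return pairs, names

        base_pairs, base_names = assemble([c[3] for c in kid_closed])
        best_closed: Optional[_Cell] = (base_count, base_len, base_names, base_pairs)
        # pair two open tips from different children through this node
        for i, j in itertools.combinations(range(len(kids)), 2):
            for si, cell_i in lifted[i].items():
                for sj, cell_j in lifted[j].items():
                    sign = _PAIR_SIGN.get(frozenset((si, sj)))
                    if sign is None:
                        continue
                    cnt = base_count - kid_closed[i][0] - kid_closed[j][0] + cell_i[0] + cell_j[0] + 1
                    ln = base_len - kid_closed[i][1] - kid_closed[j][1] + cell_i[1] + cell_j[1]
                    a, b = sorted((cell_i[4], cell_j[4]))
                    contribs = [
                        kid_closed[c][3] for c in range(len(kids)) if c not in (i, j)
                    ] + [cell_i[3], cell_j[3]]
                    pairs, names = assemble(contribs, extra_pair=(a, b, sign))
                    cand = (cnt, ln, names, pairs)
                    best_closed = _better(best_closed, cand)
        closed[id(node)] = best_closed

        # pass at most one open tip upward
        node_open: Dict[int, Tuple] = {}
        for i in range(len(kids)):
            for st, (cnt, ln, names, pairs, tip) in lifted[i].items():
                cand_cnt = base_count - kid_closed[i][0] + cnt
                cand_ln = base_len - kid_closed[i][1] + ln
                contribs = [
                    kid_closed[c][3] for c in range(len(kids)) if c != i
                ] + [pairs]
                cand_pairs, cand_names = assemble(contribs)
                cand = (cand_cnt, cand_ln, cand_names, cand_pairs, tip)
                cur = node_open.get(st)
                if cur is None:
                    node_open[st] = cand
                else:
                    ka = (-cand[0], cand[1], cand[4])
                    kb = (-cur[0], cur[1], cur[4])
                    node_open[st] = cand if ka < kb else cur
        open_[id(node)] = node_open

    count, _, _, pairs = closed[id(tree.seed_node)]
    return ContrastPairing(pairs=tuple(sorted(pairs)), maximal=True)


def pairing_paths_disjoint(tree, pairing: ContrastPairing) -> bool:
    """Post-hoc check that the tree paths of the pairs share no nodes."""
    leaf = {l.taxon.label: l for l in tree.leaf_node_iter()}
    used: set = set()
    for a, b, _ in pairing.pairs:
        na, nb = leaf[a], leaf[b]
        anc_a = []
        n = na
        while n is not None:
            anc_a.append(n)
            n = n.parent_node
        anc_ids = {id(n): i for i, n in enumerate(anc_a)}
        path = []
        n = nb
        while id(n) not in anc_ids:
            path.append(n)
            n = n.parent_node
        mrca_pos = anc_ids[id(n)]
        path += anc_a[: mrca_pos + 1]
        ids = {id(n) for n in path}
        if ids & used:
            return False
        used |= ids
    return True


def sign_test(pairing: ContrastPairing) -> float:
    """Two-sided exact binomial test of positive vs negative pair counts."""
    n = len(pairing.pairs)
    if n == 0:
        raise ValueError("sign test needs at least one pair")
    k = pairing.n_positive
    return float(scipy.stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
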