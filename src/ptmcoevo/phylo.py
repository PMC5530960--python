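"""Trees, alignments and the tree-level utilities of the pipeline.

Trees are plain :class:`dendropy.Tree` objects throughout the package; this
module wraps reading/writing and adds the operations the coevolution analysis
needs around them: ortholog (paralog) selection, masking an alignment to the
ungapped coordinates of a reference sequence, pruning a tree to a taxon set,
split-based tree comparison, neighbor-joining reconstruction from a distance
matrix, and Fitch parsimony scoring.

Conventions
-----------
* Branch lengths missing from a Newick string default to 1.0.
* Reference-sequence positions are 1-based on the ungapped reference.
* Gap characters (``-``, ``.``) and ``X`` are treated as missing data.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import dendropy
import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_BRANCH_LENGTH = 1.0
GAP_CHARS = frozenset("-.")
MISSING_CHARS = GAP_CHARS | frozenset("Xx?")


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or violates invariants."""


@dataclass
class Alignment:
    """An aligned set of protein sequences with a designated reference.

    Parameters
    ----------
    records
        Ordered ``(label, gapped_sequence)`` pairs; all sequences must have
        equal length.
    reference_label
        Label of the reference sequence (must be present in ``records``).
    """

    records: List[Tuple[str, str]]
    reference_label: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sequence labels in alignment")
        if self.reference_label not in set(labels):
            raise ValueError(f"reference {self.reference_label!r} not in alignment")

    @property
    def labels(self) -> List[str]:
        return [lab for lab, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def sequence(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(label)

    @property
    def reference_sequence(self) -> str:
        return self.sequence(self.reference_label)


def read_fasta_alignment(source, reference_label: str) -> Alignment:
    """Read an aligned FASTA file (path or handle) into an :class:`Alignment`."""
    if isinstance(source, (str, bytes)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    return Alignment(records=records, reference_label=reference_label)


def write_fasta_alignment(alignment: Alignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=lab, description="") for lab, seq in alignment.records
    ]
    SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted :class:`dendropy.Tree`.

    Missing branch lengths default to ``DEFAULT_BRANCH_LENGTH``; polytomies
    are preserved. Raises :class:`NewickError` on syntax errors, duplicate
    tip labels, or fewer than two tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise NewickError(f"tree must have at least 2 tips, found {len(labels)}")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            node.edge.length = DEFAULT_BRANCH_LENGTH
    return tree


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a one-line Newick string with branch lengths."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def tip_labels(tree: dendropy.Tree) -> List[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Ortholog selection and reference masking
# ---------------------------------------------------------------------------

def _ungap(seq: str) -> str:
    return "".join(c for c in seq if c not in GAP_CHARS)


def levenshtein(a: str, b: str) -> int:
    """Edit distance between two (ungapped) sequences."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def select_orthologs(
    alignment: Alignment, species_of: Mapping[str, str]
) -> Alignment:
    """Keep one record per species: the paralog closest to the reference.

    Closeness is Levenshtein distance between ungapped sequences; ties are
    broken by lexicographically smallest sequence label. Labels missing from
    ``species_of`` are treated as singleton species. The reference is always
    retained (it has distance 0 to itself).
    """
    ref = _ungap(alignment.reference_sequence)
    best: Dict[str, Tuple[int, str]] = {}
    for lab, seq in alignment.records:
        sp = species_of.get(lab, lab)
        key = (levenshtein(_ungap(seq), ref), lab)
        if sp not in best or key < best[sp]:
            best[sp] = key
    keep = {lab for _, lab in best.values()}
    keep.add(alignment.reference_label)
    records = [(lab, seq) for lab, seq in alignment.records if lab in keep]
    return Alignment(records=records, reference_label=alignment.reference_label)


def mask_to_reference(alignment: Alignment) -> Tuple[Alignment, Dict[int, int]]:
    """Drop columns that are gaps in the reference sequence.

    Returns the masked alignment and a map from 1-based ungapped reference
    position to the 1-based column index of the masked alignment (which is the
    identity once reference gap columns are removed).
    """
    ref = alignment.reference_sequence
    keep_cols = [i for i, c in enumerate(ref) if c not in GAP_CHARS]
    column_map = {p: p for p in range(1, len(keep_cols) + 1)}
    records = [
        (lab, "".join(seq[i] for i in keep_cols)) for lab, seq in alignment.records
    ]
    return Alignment(records=records, reference_label=alignment.reference_label), column_map


# ---------------------------------------------------------------------------
# Pruning
# ---------------------------------------------------------------------------

def prune_to_common_taxa(tree: dendropy.Tree, labels: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``labels`` ∩ tips; unary nodes are suppressed with
    their branch lengths summed, so tip-to-tip path lengths are preserved."""
    labels = set(labels)
    present = [l for l in tip_labels(tree) if l in labels]
    if len(present) < 2:
        raise ValueError(f"only {len(present)} tips survive pruning; need >= 2")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(present)
    # dendropy can leave a unifurcating root; collapse it into its child.
    root = pruned.seed_node
    while len(root.child_nodes()) == 1:
        child = root.child_nodes()[0]
        pruned.seed_node = child
        child.parent_node = None
        child.edge.length = None
        root = child
    return pruned


def patristic_distances(tree: dendropy.Tree) -> Dict[Tuple[str, str], float]:
    """All pairwise tip-to-tip path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out: Dict[Tuple[str, str], float] = {}
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()]
    for t1, t2 in itertools.combinations(taxa, 2):
        key = tuple(sorted((t1.label, t2.label)))
        out[key] = pdm.patristic_distance(t1, t2)
    return out


# ---------------------------------------------------------------------------
# Tree comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeDistance:
    """Split-based distances between two trees on the same taxa.

    ``topology_difference`` is the Robinson–Foulds count: the number of
    non-trivial splits present in exactly one of the two trees (an even
    number when both trees are binary). ``branch_score`` is the sum over all
    splits (pendant edges included) of the squared difference between the
    branch lengths associated with the split in each tree, a split absent
    from a tree contributing length zero.
    """

    topology_difference: int
    branch_score: float


def _split_length_map(tree: dendropy.Tree) -> Dict[frozenset, float]:
    """Map each split (as the frozenset of tip labels on one side) to its
    branch length, in an unrooted sense: the two edges joining a bifurcating
    root induce the same split and their lengths are summed."""
    all_tips = frozenset(tip_labels(tree))
    anchor = min(all_tips)
    below: Dict[int, frozenset] = {}
    lengths: Dict[frozenset, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
        if node.parent_node is None:
            continue
        side = below[id(node)]
        if len(side) == 0 or side == all_tips:
            continue
        # canonical side: the one not containing the anchor taxon
        if anchor in side:
            side = all_tips - side
        if len(side) == 0:
            continue
        length = node.edge.length or 0.0
        lengths[side] = lengths.get(side, 0.0) + length
    return lengths


def tree_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> TreeDistance:
    """Robinson–Foulds topology difference and squared branch-score distance."""
    tips1, tips2 = set(tip_labels(t1)), set(tip_labels(t2))
    if tips1 != tips2:
        raise ValueError("trees have different tip label sets")
    n = len(tips1)
    m1, m2 = _split_length_map(t1), _split_length_map(t2)

    def nontrivial(split: frozenset) -> bool:
        return 1 < len(split) < n - 1

    s1 = {s for s in m1 if nontrivial(s)}
    s2 = {s for s in m2 if nontrivial(s)}
    topo = len(s1 ^ s2)
    score = 0.0
    for split in set(m1) | set(m2):
        d = m1.get(split, 0.0) - m2.get(split, 0.0)
        score += d * d
    return TreeDistance(topology_difference=topo, branch_score=score)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def read_phylip_distances(source) -> Tuple[List[str], np.ndarray]:
    """Read a square PHYLIP distance matrix: first line the taxon count, then
    one row per taxon (label followed by the distances)."""
    if isinstance(source, (str, bytes)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    lines = [l for l in text.splitlines() if l.strip()]
    n = int(lines[0].split()[0])
    labels: List[str] = []
    rows: List[List[float]] = []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return labels, np.asarray(rows, dtype=float)


def nj_tree(labels: Sequence[str], distances: np.ndarray) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Ties in the minimum-Q criterion are broken deterministically by the
    (lexicographically smallest tip label of each cluster) pair. Negative
    branch-length estimates are clamped to zero, the deficit being moved onto
    the sibling edge so the pair's summed length is preserved. The result is
    returned as a tree with a trifurcating root (the standard unrooted NJ
    output).
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match label count")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    tree = dendropy.Tree()
    nodes: Dict[int, dendropy.Node] = {}
    names: Dict[int, str] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=lab)
        nodes[i] = node
        names[i] = lab
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d(i, j) - r[i] - r[j]
            key = (q, tuple(sorted((names[i], names[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        u = next_id
        next_id += 1
        nodes[u] = parent
        names[u] = min(names[i], names[j])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: names[k])
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    root = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(lk, 0.0)
    tree.seed_node = root
    # register taxa
    for leaf in tree.leaf_node_iter():
        tree.taxon_namespace.add_taxon(leaf.taxon)
    return tree


def p_distance_matrix(alignment: Alignment) -> Tuple[List[str], np.ndarray]:
    """Proportion of differing (both non-missing) sites between each pair."""
    labs = alignment.labels
    seqs = [seq for _, seq in alignment.records]
    n = len(labs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = tot = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in MISSING_CHARS or b in MISSING_CHARS:
                    continue
                tot += 1
                if a != b:
                    diff += 1
            D[i, j] = D[j, i] = diff / tot if tot else 0.0
    return labs, D


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
_FULL_SET = frozenset(_AA)


def fitch_score(tree: dendropy.Tree, alignment: Alignment) -> int:
    """Total Fitch parsimony length of the alignment on the tree.

    Each column contributes the minimum number of state changes needed to
    explain it (post-order set intersection/union). Gaps and ``X`` are
    wildcards (any state). Raises ``KeyError`` if a tip has no sequence.
    """
    seqs = dict(alignment.records)
    leaves = tip_labels(tree)
    for lab in leaves:
        if lab not in seqs:
            raise KeyError(f"tip {lab!r} has no sequence in the alignment")
    post = list(tree.postorder_node_iter())
    total = 0
    for col in range(alignment.length):
        changes = 0
        sets: Dict[int, frozenset] = {}
        for node in post:
            if node.is_leaf():
                c = seqs[node.taxon.label][col]
                sets[id(node)] = _FULL_SET if c in MISSING_CHARS else frozenset([c])
            else:
                kids = [sets[id(k)] for k in node.child_nodes()]
                cur = kids[0]
                for s in kids[1:]:
                    inter = cur & s
                    if inter:
                        cur = inter
                    else:
                        cur = cur | s
                        changes += 1
                sets[id(node)] = cur
        total += changes
    return total
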