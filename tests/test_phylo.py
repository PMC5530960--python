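"""Tree and alignment plumbing: Newick I/O, pruning, ortholog selection,
reference masking, tree comparison, neighbor joining, Fitch scoring."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptmcoevo as pc
from ptmcoevo.phylo import (
    Alignment,
    levenshtein,
    p_distance_matrix,
    patristic_distances,
    read_phylip_distances,
)
from ptmcoevo.synthetic import simulate_yule_tree


# ---------------------------------------------------------------------- newick
def test_read_newick_basic_shape():
    tree = pc.read_newick("((A:1,B:1):1,C:2);")
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]
    assert len(tree.seed_node.child_nodes()) == 2


def test_read_newick_rejects_single_tip_and_duplicates():
    with pytest.raises(pc.NewickError):
        pc.read_newick("(A:1);")
    with pytest.raises(pc.NewickError):
        pc.read_newick("((A:1,A:1):1,B:1);")
    with pytest.raises(pc.NewickError):
        pc.read_newick("((A:1,B:1:1,C);")  # malformed


def test_read_newick_defaults_missing_lengths():
    tree = pc.read_newick("((A,B),C);")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            assert node.edge.length == 1.0


def test_newick_round_trip_identity():
    text = "((A:1.5,B:0.25):0.5,(C:2.0,D:1.0):0.75);"
    tree = pc.read_newick(text)
    again = pc.read_newick(pc.write_newick(tree))
    d = pc.tree_distance(tree, again)
    assert d.topology_difference == 0
    assert d.branch_score == pytest.approx(0.0, abs=1e-12)


def test_round_trip_preserves_random_yule_trees(rng):
    for seed in range(3):
        tree = simulate_yule_tree(12, seed=seed)
        again = pc.read_newick(pc.write_newick(tree))
        d = pc.tree_distance(tree, again)
        assert d.topology_difference == 0
        assert d.branch_score < 1e-15


# --------------------------------------------------------------------- pruning
def test_prune_sums_suppressed_branch_lengths():
    tree = pc.read_newick("((A:1,B:1):1,C:2);")
    pruned = pc.prune_to_common_taxa(tree, {"A", "C"})
    dists = patristic_distances(pruned)
    assert dists[("A", "C")] == pytest.approx(4.0)
    assert pc.write_newick(pruned).count(":2") >= 1  # A lifted to length 2


def test_prune_to_all_tips_is_identity():
    tree = pc.read_newick("((A:1,B:1):1,(C:2,D:0.5):0.3);")
    pruned = pc.prune_to_common_taxa(tree, {"A", "B", "C", "D"})
    d = pc.tree_distance(tree, pruned)
    assert d.topology_difference == 0 and d.branch_score == pytest.approx(0.0)


def test_prune_preserves_pairwise_patristic_distances(rng):
    tree = simulate_yule_tree(14, seed=5)
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    keep = set(labels[::2])
    before = patristic_distances(tree)
    after = patristic_distances(pc.prune_to_common_taxa(tree, keep))
    for pair, dist in after.items():
        assert dist == pytest.approx(before[pair], rel=1e-9)


def test_prune_needs_two_survivors():
    tree = pc.read_newick("((A:1,B:1):1,C:2);")
    with pytest.raises(ValueError):
        pc.prune_to_common_taxa(tree, {"A"})


# ----------------------------------------------------------- ortholog selection
def _dp_levenshtein(a, b):
    """Classic dynamic-programming edit distance (oracle)."""
    m, n = len(a), len(b)
    d = np.zeros((m + 1, n + 1), dtype=int)
    d[:, 0] = np.arange(m + 1)
    d[0, :] = np.arange(n + 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i, j] = min(
                d[i - 1, j] + 1,
                d[i, j - 1] + 1,
                d[i - 1, j - 1] + (a[i - 1] != b[j - 1]),
            )
    return int(d[m, n])


def test_levenshtein_against_dp_oracle():
    assert levenshtein("kitten", "sitting") == _dp_levenshtein("kitten", "sitting") == 3
    rng = np.random.default_rng(1)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(20):
        a = "".join(rng.choice(list(aas), size=rng.integers(0, 12)))
        b = "".join(rng.choice(list(aas), size=rng.integers(0, 12)))
        assert levenshtein(a, b) == _dp_levenshtein(a, b)


def test_select_orthologs_keeps_closest_paralog():
    aln = Alignment(
        records=[("human", "ACDE"), ("sp1_a", "ACDE"), ("sp1_b", "ACDF")],
        reference_label="human",
    )
    out = pc.select_orthologs(aln, {"sp1_a": "sp1", "sp1_b": "sp1", "human": "human"})
    assert out.labels == ["human", "sp1_a"]


def test_select_orthologs_single_paralog_identity():
    aln = Alignment(
        records=[("human", "ACDE"), ("mouse", "ACDD")], reference_label="human"
    )
    out = pc.select_orthologs(aln, {"human": "h", "mouse": "m"})
    assert out.records == aln.records


def test_select_orthologs_tie_breaks_lexicographically():
    aln = Alignment(
        records=[("ref", "AAAA"), ("z_par", "AAAC"), ("a_par", "AACA")],
        reference_label="ref",
    )
    out = pc.select_orthologs(aln, {"z_par": "sp", "a_par": "sp", "ref": "r"})
    assert "a_par" in out.labels and "z_par" not in out.labels


# ----------------------------------------------------------------- ref masking
def test_mask_to_reference_example():
    aln = Alignment(
        records=[("ref", "A-CD"), ("sp", "AWC-")], reference_label="ref"
    )
    masked, colmap = pc.mask_to_reference(aln)
    assert masked.reference_sequence == "ACD"
    assert masked.sequence("sp") == "AC-"
    assert colmap[2] == 2  # reference position 2 -> column 2 of masked alignment


def test_mask_no_gaps_is_identity():
    aln = Alignment(records=[("ref", "ACD"), ("sp", "AC-")], reference_label="ref")
    masked, colmap = pc.mask_to_reference(aln)
    assert masked.records == aln.records
    assert colmap == {1: 1, 2: 2, 3: 3}


@settings(max_examples=50, derandomize=True)
@given(st.text(alphabet="ACDEF-", min_size=1, max_size=30))
def test_masked_reference_length_equals_ungapped_length(ref):
    aln = Alignment(records=[("ref", ref), ("sp", "G" * len(ref))], reference_label="ref")
    masked, colmap = pc.mask_to_reference(aln)
    ungapped = ref.replace("-", "")
    assert masked.length == len(ungapped)
    assert masked.reference_sequence == ungapped
    assert len(colmap) == len(ungapped)


# --------------------------------------------------------------- tree distance
def test_tree_distance_identical_is_zero():
    t1 = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    d = pc.tree_distance(t1, t2)
    assert d.topology_difference == 0 and d.branch_score == 0.0


def test_tree_distance_four_taxon_swap():
    t1 = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = pc.read_newick("((A:1,C:1):1,(B:1,D:1):1);")
    d = pc.tree_distance(t1, t2)
    assert d.topology_difference == 2  # one split on each side, unshared


def test_tree_distance_single_length_change():
    t1 = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = pc.read_newick("((A:1,B:1.5):1,(C:1,D:1):1);")
    d = pc.tree_distance(t1, t2)
    assert d.topology_difference == 0
    assert d.branch_score == pytest.approx(0.25)


def test_tree_distance_symmetric_and_even(rng):
    for seed in range(4):
        t1 = simulate_yule_tree(10, seed=seed)
        t2 = simulate_yule_tree(10, seed=seed + 100)
        d12 = pc.tree_distance(t1, t2)
        d21 = pc.tree_distance(t2, t1)
        assert d12.topology_difference == d21.topology_difference
        assert d12.branch_score == pytest.approx(d21.branch_score)
        assert d12.topology_difference % 2 == 0


def test_tree_distance_label_mismatch():
    t1 = pc.read_newick("((A:1,B:1):1,C:1);")
    t2 = pc.read_newick("((A:1,B:1):1,D:1);")
    with pytest.raises(ValueError):
        pc.tree_distance(t1, t2)


# ------------------------------------------------------------ neighbor joining
def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:2,B:3):1,(C:4,D:5)); distances are path lengths
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 0, 0],
        ],
        dtype=float,
    )
    D[2, 3] = D[3, 2] = 9.0
    tree = pc.nj_tree(labels, D)
    dists = patristic_distances(tree)
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        assert dists[tuple(sorted((a, b)))] == pytest.approx(D[i, j])


def test_nj_three_taxa_closed_form():
    labels = ["A", "B", "C"]
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = pc.nj_tree(labels, D)
    # three-point formulas: la=(dab+dac-dbc)/2=1, lb=2, lc=3
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_rejects_asymmetric_matrix():
    D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError):
        pc.nj_tree(["A", "B", "C"], D)


def test_nj_tip_set_matches_input():
    rng = np.random.default_rng(3)
    tree = simulate_yule_tree(8, seed=9)
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    dists = patristic_distances(tree)
    n = len(labels)
    D = np.zeros((n, n))
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        D[i, j] = D[j, i] = dists[tuple(sorted((a, b)))]
    out = pc.nj_tree(labels, D)
    assert sorted(l.taxon.label for l in out.leaf_node_iter()) == sorted(labels)
    # additive input: NJ must reproduce all pairwise path lengths
    out_d = patristic_distances(out)
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        assert out_d[tuple(sorted((a, b)))] == pytest.approx(D[i, j], abs=1e-9)


def test_read_phylip_distances(tmp_path):
    path = tmp_path / "d.phy"
    path.write_text("3\nA 0 1 2\nB 1 0 3\nC 2 3 0\n")
    labels, D = read_phylip_distances(str(path))
    assert labels == ["A", "B", "C"]
    assert D[0, 2] == 2.0 and D[1, 2] == 3.0


# ------------------------------------------------------------------ fitch score
def _brute_fitch(tree, column):
    """Minimum changes over all internal-state assignments (binary trees)."""
    alphabet = sorted(set(column.values()) | {"A"})
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    best = None
    for assign in itertools.product(alphabet, repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for leaf in tree.leaf_node_iter():
            amap[id(leaf)] = column[leaf.taxon.label]
        changes = 0
        for n in tree.postorder_node_iter():
            if n.parent_node is not None and amap[id(n)] != amap[id(n.parent_node)]:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best


def test_fitch_trivial_columns():
    tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    aln = Alignment(
        records=[("A", "KK"), ("B", "KK"), ("C", "KR"), ("D", "KR")],
        reference_label="A",
    )
    # column 1 invariant -> 0; column 2 splits with the topology -> 1
    assert pc.fitch_score(tree, aln) == 1


def test_fitch_gaps_are_wildcards():
    tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    aln = Alignment(
        records=[("A", "K"), ("B", "-"), ("C", "R"), ("D", "R")],
        reference_label="A",
    )
    assert pc.fitch_score(tree, aln) == 1


def test_fitch_matches_brute_force_on_small_trees():
    rng = np.random.default_rng(7)
    for seed in range(6):
        tree = simulate_yule_tree(6, seed=seed)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        column = {lab: "KRD"[rng.integers(3)] for lab in labels}
        aln = Alignment(
            records=[(lab, column[lab]) for lab in labels], reference_label=labels[0]
        )
        assert pc.fitch_score(tree, aln) == _brute_fitch(tree, column)


def test_fitch_missing_tip_sequence_raises(quartet_tree):
    aln = Alignment(records=[("A", "K"), ("B", "K"), ("C", "K")], reference_label="A")
    with pytest.raises(KeyError):
        pc.fitch_score(quartet_tree, aln)
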