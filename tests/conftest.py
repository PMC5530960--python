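import numpy as np
import pytest

import ptmcoevo as pc


@pytest.fixture
def quartet_tree():
    """Balanced 4-tip tree with assorted branch lengths."""
    return pc.read_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")


@pytest.fixture
def cherry_tree():
    return pc.read_newick("(A:0.7,B:0.4);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rate_matrix(rng, spec=None, low=0.1, high=2.0):
    """A random generator under the given spec (dependent by default)."""
    spec = spec or pc.ModelSpec.dependent()
    return pc.build_Q(rng.uniform(low, high, spec.n_free), spec)


def brute_force_loglik(tree, states, Q, prior):
    """Exhaustive sum over all internal-state assignments (independent oracle:
    uses scipy's expm directly, not the package's pruning machinery)."""
    import itertools

    import scipy.linalg

    k = Q.shape[0]
    nodes = list(tree.postorder_node_iter())
    leaves = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    Ps = {
        id(n): scipy.linalg.expm(Q * (n.edge.length or 0.0))
        for n in nodes
        if n.parent_node is not None
    }
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        for leaf in leaves:
            s = states[leaf.taxon.label]
            amap[id(leaf)] = None if s == pc.AMBIGUOUS else s - 1
        # ambiguous leaves: sum over their states too
        amb = [id(l) for l in leaves if amap[id(l)] is None]
        for sub in itertools.product(range(k), repeat=len(amb)):
            for key, s in zip(amb, sub):
                amap[key] = s
            p = prior[amap[id(tree.seed_node)]]
            for n in nodes:
                if n.parent_node is not None:
                    p *= Ps[id(n)][amap[id(n.parent_node)], amap[id(n)]]
            total += p
            for key in amb:
                amap[key] = None
    return np.log(total)
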