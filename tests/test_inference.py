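"""Pruning likelihood correctness, ML fitting, and the likelihood ratio test."""

import itertools

import numpy as np
import pytest

import ptmcoevo as pc
from ptmcoevo.ctmc import ModelSpec
from ptmcoevo.inference import TreeIndex
from ptmcoevo.synthetic import ScenarioConfig, simulate_dataset, simulate_yule_tree
from ptmcoevo.traits import swap_traits
from tests.conftest import brute_force_loglik, random_rate_matrix


# ------------------------------------------------------------------- likelihood
def test_two_tip_zero_rate_closed_form(cherry_tree):
    ll = pc.log_likelihood(cherry_tree, {"A": 1, "B": 1}, np.zeros((4, 4)), "equal")
    assert ll == pytest.approx(np.log(0.25), abs=1e-12)


def test_pruning_equals_enumeration_on_random_instances(rng):
    """Exhaustive sum over internal-state assignments, 4-6 tips, random Q."""
    for n_tips in (4, 5, 6):
        for rep in range(4):
            tree = simulate_yule_tree(n_tips, seed=100 * n_tips + rep)
            Q = random_rate_matrix(rng)
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            states = {lab: int(rng.integers(1, 5)) for lab in labels}
            states[labels[0]] = pc.AMBIGUOUS  # exercise missing data too
            prior = rng.dirichlet(np.ones(4))
            ll = pc.log_likelihood(tree, states, Q, prior)
            oracle = brute_force_loglik(tree, states, Q, prior)
            assert ll == pytest.approx(oracle, abs=1e-10)


def test_independent_likelihood_factorizes(rng):
    """4-state log-likelihood under tied rates = sum of 2-state pruning
    log-likelihoods for X and Y computed separately."""
    tree = simulate_yule_tree(12, seed=3)
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    for rep in range(5):
        yg, xg, yl, xl = rng.uniform(0.1, 2.0, 4)
        Q = pc.build_Q([yg, xg, yl, xl], ModelSpec.independent())
        states = {lab: int(rng.integers(1, 5)) for lab in labels}
        ll4 = pc.log_likelihood(tree, states, Q, "equal")
        Qx = np.array([[-xg, xg], [xl, -xl]])
        Qy = np.array([[-yg, yg], [yl, -yl]])
        xs = {lab: 1 + (s - 1) // 2 for lab, s in states.items()}
        ys = {lab: 1 + (s - 1) % 2 for lab, s in states.items()}
        llx = pc.log_likelihood(tree, xs, Qx, "equal")
        lly = pc.log_likelihood(tree, ys, Qy, "equal")
        assert ll4 == pytest.approx(llx + lly, abs=1e-9)


def test_likelihood_invariant_to_child_and_tip_order(rng):
    t1 = pc.read_newick("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")
    t2 = pc.read_newick("((D:0.1,C:0.4):0.6,(B:0.5,A:0.3):0.2);")
    Q = random_rate_matrix(rng)
    states = {"A": 1, "B": 4, "C": 2, "D": 3}
    states_rev = dict(reversed(list(states.items())))
    assert pc.log_likelihood(t1, states, Q) == pytest.approx(
        pc.log_likelihood(t2, states_rev, Q), abs=1e-12
    )


def test_all_ambiguous_likelihood_is_one(cherry_tree, rng):
    Q = random_rate_matrix(rng)
    ll = pc.log_likelihood(cherry_tree, {"A": pc.AMBIGUOUS, "B": pc.AMBIGUOUS}, Q)
    assert ll == pytest.approx(0.0, abs=1e-12)


def test_impossible_data_flagged_minus_inf(cherry_tree):
    # zero rates, contradictory tips, prior concentrated on state 1
    prior = np.array([1.0, 0.0, 0.0, 0.0])
    ll = pc.log_likelihood(cherry_tree, {"A": 2, "B": 3}, np.zeros((4, 4)), prior)
    assert ll == -np.inf


# ------------------------------------------------------------------------- fit
def test_factorized_independent_fit_matches_joint_optimization():
    cfg = ScenarioConfig(n_tips=40, model="independent", seed=8)
    tree, _, tips, _ = simulate_dataset(cfg)
    fast = pc.fit(tree, tips, ModelSpec.independent(), seed=1, n_restarts=4)
    joint = pc.fit(tree, tips, ModelSpec.independent(), seed=2, n_restarts=8,
                   factorize=False)
    assert fast.log_likelihood == pytest.approx(joint.log_likelihood, abs=1e-4)
    assert fast.log_likelihood >= joint.log_likelihood - 1e-4


def test_dependent_fit_dominates_independent_fit():
    for seed in (0, 1):
        cfg = ScenarioConfig(n_tips=30, model="dependent", seed=seed)
        tree, _, tips, _ = simulate_dataset(cfg)
        test, ind, dep = pc.run_coevolution_test(tree, tips, seed=seed, n_restarts=3)
        assert dep.log_likelihood >= ind.log_likelihood - 1e-6
        assert test.lrt >= 0.0


def test_three_tip_mle_matches_grid_search():
    """Independent-model MLE vs a dense 2-state grid (0.05 in log10)."""
    tree = pc.read_newick("((A:0.6,B:0.9):0.4,C:1.2);")
    tips = {"A": 4, "B": 1, "C": 3}
    fitted = pc.fit(tree, tips, ModelSpec.independent(), seed=0, n_restarts=6)

    idx = TreeIndex(tree)
    grid = np.arange(-2.0, 1.0001, 0.05)

    def best_2state(binary):
        tip_arr = idx.tip_state_array(binary, k=2)
        from ptmcoevo._pruning import pruning_loglik
        from ptmcoevo.ctmc import transition_matrices_for_lengths

        best = -np.inf
        for lg in grid:
            for ll_ in grid:
                g, l = 10.0 ** lg, 10.0 ** ll_
                Q = np.array([[-g, g], [l, -l]])
                P = transition_matrices_for_lengths(Q, idx.lengths)
                val = pruning_loglik(idx.parent, tip_arr, P, np.array([0.5, 0.5]))
                best = max(best, val)
        return best

    xs = {lab: 1 + (s - 1) // 2 for lab, s in tips.items()}
    ys = {lab: 1 + (s - 1) % 2 for lab, s in tips.items()}
    grid_best = best_2state(xs) + best_2state(ys)
    # the optimizer must do at least as well as the grid, and the grid should
    # come close to the optimum at this resolution
    assert fitted.log_likelihood >= grid_best - 1e-6
    assert fitted.log_likelihood - grid_best < 0.05


def test_parameter_recovery_within_30_percent():
    """Median relative error of independent-model MLE rates, over 20
    replicates of 200-tip simulations with gains 0.5 and losses 1.0 (the
    median is taken over all recovered rates across replicates)."""
    true = np.array([0.5, 0.5, 1.0, 1.0])  # (y_gain, x_gain, y_loss, x_loss)
    errors = []
    for seed in range(20):
        cfg = ScenarioConfig(n_tips=200, model="independent",
                             rates=true, seed=1000 + seed)
        tree, _, tips, _ = simulate_dataset(cfg)
        f = pc.fit(tree, tips, ModelSpec.independent(), seed=seed, n_restarts=2)
        errors.append(np.abs(f.params - true) / true)
    assert np.median(np.stack(errors)) < 0.30


def test_relabeling_traits_transposes_mle():
    """Swapping X and Y maps the dependent MLE onto the transposed tying with
    the same maximized log-likelihood."""
    cfg = ScenarioConfig(n_tips=60, model="dependent", seed=5)
    tree, _, tips, _ = simulate_dataset(cfg)
    dep = pc.fit(tree, tips, ModelSpec.dependent(), seed=0, n_restarts=6)
    dep_sw = pc.fit(tree, swap_traits(tips), ModelSpec.dependent(), seed=1, n_restarts=6)
    assert dep_sw.log_likelihood == pytest.approx(dep.log_likelihood, abs=1e-3)
    # slot correspondence under (x,y) -> (y,x): q12<->q13, q21<->q31, q24<->q34, q42<->q43
    mapping = {"q12": "q13", "q13": "q12", "q21": "q31", "q31": "q21",
               "q24": "q34", "q34": "q24", "q42": "q43", "q43": "q42"}
    r, rs = dep.rates, dep_sw.rates
    for a, b in mapping.items():
        assert rs[b] == pytest.approx(r[a], rel=0.15, abs=0.02)


# ------------------------------------------------------------------------- LRT
@pytest.mark.parametrize(
    "l_i,l_d,expected",
    [(-38.9, -23.3, 31.2), (-10.0, -10.0, 0.0), (-108.2, -100.2, 16.0)],
)
def test_lrt_statistic_examples(l_i, l_d, expected):
    assert pc.lrt_statistic(l_i, l_d) == pytest.approx(expected, abs=1e-12)


def test_lrt_statistic_clamps_optimizer_noise():
    assert pc.lrt_statistic(-10.0, -10.0000004) == 0.0


def test_chi2_pvalue_closed_form_df4():
    for x in (0.0, 1.7, 5.0, 15.9, 31.2):
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert pc.chi2_pvalue(x, 4) == pytest.approx(closed, rel=1e-12)
    assert pc.chi2_pvalue(0.0, 4) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pc.chi2_pvalue(-1.0, 4)
    with pytest.raises(ValueError):
        pc.chi2_pvalue(1.0, 0)


def test_run_coevolution_test_all_ambiguous_is_null(cherry_tree):
    states = {"A": pc.AMBIGUOUS, "B": pc.AMBIGUOUS}
    test, ind, dep = pc.run_coevolution_test(cherry_tree, states, seed=0, n_restarts=2)
    assert test.lrt == pytest.approx(0.0, abs=1e-8)
    assert ind.log_likelihood == pytest.approx(0.0, abs=1e-10)
    assert dep.log_likelihood == pytest.approx(0.0, abs=1e-10)


def test_run_coevolution_test_reports_df4(quartet_tree):
    test, _, _ = pc.run_coevolution_test(
        quartet_tree, {"A": 1, "B": 4, "C": 2, "D": 3}, seed=0, n_restarts=2
    )
    assert test.df == 4
    assert 0.0 <= test.p_chi2 <= 1.0


# -------------------------------------------------------------- reduced models
def test_reduced_model_test_reports_df1():
    cfg = ScenarioConfig(n_tips=40, model="dependent", seed=2)
    tree, _, tips, _ = simulate_dataset(cfg)
    test, restricted, dep = pc.reduced_model_test(tree, tips, "q12=q34",
                                                  seed=0, n_restarts=2)
    assert test.df == 1
    assert restricted.spec.n_free == 7
    assert dep.log_likelihood >= restricted.log_likelihood - 1e-6


def test_reduced_model_test_rejects_degenerate_constraints(quartet_tree):
    tips = {"A": 1, "B": 4, "C": 2, "D": 3}
    with pytest.raises(ValueError):
        pc.reduced_model_test(quartet_tree, tips, "")  # equal to dependent spec
    with pytest.raises(ValueError):
        pc.reduced_model_test(quartet_tree, tips, "q12=q34,q21=q43")  # two ties


def test_stationary_and_observed_priors_run(quartet_tree):
    tips = {"A": 1, "B": 4, "C": 2, "D": 3}
    for prior in ("stationary", "observed"):
        test, ind, dep = pc.run_coevolution_test(quartet_tree, tips, prior=prior,
                                                 seed=0, n_restarts=2)
        assert np.isfinite(test.lrt)
        assert dep.log_likelihood >= ind.log_likelihood - 1e-6
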