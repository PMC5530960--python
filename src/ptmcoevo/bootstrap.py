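"""Monte Carlo parametric bootstrap for the dependent-vs-independent LRT.

The null distribution of the LRT is built by simulating paired-trait tip
states under the independent model's MLE rates along the observed tree,
refitting both models to each simulated dataset, and recording the LRT. The
empirical p-value uses the add-one estimator (1 + #{null >= observed}) /
(n_sims + 1), which avoids reporting exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .ctmc import ModelSpec, SLOTS, simulate_tip_states
from .inference import FitResult, fit, lrt_statistic

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    null_lrts: np.ndarray
    n_sims: int
    seed: Optional[int]
    observed_lrt: Optional[float] = None
    p_empirical: Optional[float] = None

    def with_observed(self, observed_lrt: float) -> "BootstrapResult":
        return BootstrapResult(
            null_lrts=self.null_lrts,
            n_sims=self.n_sims,
            seed=self.seed,
            observed_lrt=observed_lrt,
            p_empirical=empirical_pvalue(self.null_lrts, observed_lrt),
        )


def empirical_pvalue(null_lrts: Sequence[float], observed: float) -> float:
    """Add-one empirical upper-tail probability."""
    null_lrts = np.asarray(null_lrts, dtype=float)
    if null_lrts.size == 0:
        raise ValueError("empty null sample")
    return float((1 + np.sum(null_lrts >= observed)) / (null_lrts.size + 1))


def _all_equal(states: Dict[str, int]) -> bool:
    vals = set(states.values())
    return len(vals) == 1


def bootstrap_null(
    tree,
    indep_fit: FitResult,
    n_sims: int = 1000,
    seed: Optional[Union[int, np.random.Generator]] = None,
    n_restarts: int = 0,
    maxiter: int = 60,
    ftol: float = 1e-8,
) -> BootstrapResult:
    """Null LRT sample under the independent-model MLE.

    Each replicate draws a root state from the fitted prior, evolves the four
    combined states down the tree, and refits both models. Refits are seeded
    at the generating independent MLE (and, for the dependent model, at the
    replicate's own independent MLE expanded to the 8 slots), which makes a
    single seeded optimizer start per refit sufficient; ``n_restarts`` adds
    random restarts on top. Replicates where the refit fails outright are
    redrawn (with a retry cap and a log message).

    Datasets in which every tip has the same state carry no information: both
    models attain the same supremum (all rates at zero), so the LRT is
    recorded as 0 without running the optimizer.
    """
    if indep_fit.spec.name != "independent":
        raise ValueError("bootstrap_null requires a fit of the independent model")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q0 = indep_fit.Q
    prior = indep_fit.root_prior
    datasets = simulate_tip_states(tree, Q0, prior, rng, n_replicates=n_sims)
    indep_spec = ModelSpec.independent()
    dep_spec = ModelSpec.dependent()
    from .inference import TreeIndex

    idx = TreeIndex(tree)
    prior_arg = prior.kind if prior.kind != "custom" else prior
    null: List[float] = []
    retries_left = max(10, n_sims // 10)
    i = 0
    while i < len(datasets):
        tips = datasets[i]
        i += 1
        if _all_equal(tips):
            null.append(0.0)
            continue
        try:
            ind = fit(tree, tips, indep_spec, prior=prior_arg,
                      n_restarts=n_restarts, seed=rng, tree_index=idx,
                      init_params=[indep_fit.params], maxiter=maxiter, ftol=ftol)
            ind_full = np.array([ind.rates[s] for s in SLOTS])
            dep = fit(tree, tips, dep_spec, prior=prior_arg,
                      n_restarts=n_restarts, seed=rng, tree_index=idx,
                      init_params=[ind_full], maxiter=maxiter, ftol=ftol)
        except Exception as exc:  # numerical failure: redraw this replicate
            if retries_left > 0:
                retries_left -= 1
                logger.warning("bootstrap replicate failed (%s); redrawing", exc)
                datasets.extend(simulate_tip_states(tree, Q0, prior, rng, n_replicates=1))
                continue
            raise
        null.append(lrt_statistic(ind.log_likelihood, dep.log_likelihood))
    return BootstrapResult(null_lrts=np.asarray(null[:n_sims]), n_sims=n_sims, seed=seed_val)


def matched_policy_lrt(
    tree,
    tips: Dict[str, int],
    indep_fit: FitResult,
    seed=None,
    n_restarts: int = 0,
    maxiter: int = 60,
    ftol: float = 1e-8,
    tree_index=None,
) -> float:
    """Observed LRT recomputed with the bootstrap refit policy.

    The parametric bootstrap approximates the distribution of the statistic
    *as computed*; comparing a heavily optimized observed LRT against nulls
    from cheap seeded refits would bias the empirical p-value downward, so the
    observed statistic entering the p-value uses the identical policy."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior = indep_fit.root_prior
    prior_arg = prior.kind if prior.kind != "custom" else prior
    ind = fit(tree, tips, ModelSpec.independent(), prior=prior_arg,
              n_restarts=n_restarts, seed=rng, tree_index=tree_index,
              init_params=[indep_fit.params], maxiter=maxiter, ftol=ftol)
    ind_full = np.array([ind.rates[s] for s in SLOTS])
    dep = fit(tree, tips, ModelSpec.dependent(), prior=prior_arg,
              n_restarts=n_restarts, seed=rng, tree_index=tree_index,
              init_params=[ind_full], maxiter=maxiter, ftol=ftol)
    return lrt_statistic(ind.log_likelihood, dep.log_likelihood)


def run_bootstrap_test(
    tree,
    tips: Dict[str, int],
    prior: str = "equal",
    n_sims: int = 1000,
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
):
    """Observed-data LRT plus its parametric-bootstrap p-value.

    The reported LRT comes from the fully optimized fits; the empirical
    p-value compares a policy-matched observed statistic (see
    :func:`matched_policy_lrt`) against the null sample. Returns
    ``(CoevolutionTest with p_bootstrap, indep_fit, dep_fit, BootstrapResult)``."""
    from .inference import run_coevolution_test

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test, ind, dep = run_coevolution_test(tree, tips, prior=prior,
                                          n_restarts=n_restarts, seed=rng)
    obs_matched = matched_policy_lrt(tree, tips, ind, seed=rng)
    boot = bootstrap_null(tree, ind, n_sims=n_sims, seed=rng).with_observed(obs_matched)
    test.p_bootstrap = boot.p_empirical
    return test, ind, dep, boot
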