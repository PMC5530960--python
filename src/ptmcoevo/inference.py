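"""Maximum-likelihood fitting of the paired-trait models and the LRT.

The likelihood of the tip states under a rate matrix is the pruning
(post-order) likelihood: tip partials are indicator vectors (all ones for
ambiguous tips), each internal node's partial is the elementwise product over
children of ``P(t_child) @ partial_child``, and the data likelihood is the
prior-weighted sum over root states.

Fitting maximizes this over log10 rates (bounded in [1e-8, 1e3]) with
multi-start L-BFGS-B. For the independent model with an ``equal`` or
``stationary`` root prior the four-state likelihood factorizes exactly into
two two-state likelihoods (one per trait), and the fit is performed on the
factors; this is both faster and immune to the joint optimizer's local
optima, and is verified against the joint optimization in the test suite.

The dependent (8 free rates) and independent (4) models are nested, so
LRT = -2 ln L(I)/L(D) is asymptotically chi-square with 4 degrees of freedom;
a parametric bootstrap (see :mod:`ptmcoevo.bootstrap`) is available when the
asymptotics are in doubt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.optimize
import scipy.stats

from ._pruning import pruning_loglik
from .ctmc import (
    ModelSpec,
    RootPrior,
    SLOTS,
    build_Q,
    rates_by_slot,
    stationary_distribution,
    transition_matrices_for_lengths,
)
from .traits import AMBIGUOUS, observed_state_frequencies

logger = logging.getLogger(__name__)

LOG10_LOWER = -8.0
LOG10_UPPER = 3.0
INIT_LOW, INIT_HIGH = -2.0, 1.0  # range of uniform log10 starting rates

_BIG = 1e12  # finite stand-in for -inf log-likelihoods inside the optimizer


class TreeIndex:
    """Postorder array view of a dendropy tree, reused across likelihood
    evaluations (root is the last node; ``parent[i]`` indexes into the same
    ordering)."""

    def __init__(self, tree) -> None:
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.lengths = np.zeros(n, dtype=float)
        self.tip_index: Dict[str, int] = {}
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                self.parent[i] = index[id(node.parent_node)]
                self.lengths[i] = node.edge.length or 0.0
            if node.is_leaf():
                self.tip_index[node.taxon.label] = i
        self._internal_mask = np.ones(n, dtype=bool)
        for i in self.tip_index.values():
            self._internal_mask[i] = False

    def tip_state_array(self, states: Dict[str, int], k: int = 4) -> np.ndarray:
        """Encode a label->state map (states 1..k, AMBIGUOUS allowed) as the
        kernel's int array; every tree tip must be present in the map."""
        arr = np.full(self.n_nodes, -2, dtype=np.int64)
        for label, i in self.tip_index.items():
            if label not in states:
                raise KeyError(f"tip {label!r} has no assigned state")
            s = states[label]
            if s == AMBIGUOUS:
                arr[i] = -1
            else:
                if not 1 <= s <= k:
                    raise ValueError(f"state {s} out of range 1..{k}")
                arr[i] = s - 1
        return arr


def _tips_as_binary(states: Dict[str, int]) -> Tuple[Dict[str, int], Dict[str, int]]:
    """Split combined states into the two marginal binary traits, each coded
    1=absent, 2=present (AMBIGUOUS propagates to both)."""
    xs: Dict[str, int] = {}
    ys: Dict[str, int] = {}
    for lab, s in states.items():
        if s == AMBIGUOUS:
            xs[lab] = ys[lab] = AMBIGUOUS
        else:
            xs[lab] = 1 + (s - 1) // 2
            ys[lab] = 1 + (s - 1) % 2
    return xs, ys


def _resolve_prior(
    prior: Union[str, RootPrior], tips: Dict[str, int]
) -> RootPrior:
    if isinstance(prior, RootPrior):
        return prior
    if prior == "observed":
        return RootPrior(kind="observed", weights=observed_state_frequencies(tips))
    if prior in ("equal", "stationary"):
        return RootPrior(kind=prior)
    raise ValueError(f"unknown prior {prior!r}")


def log_likelihood(
    tree,
    tips: Dict[str, int],
    Q: np.ndarray,
    prior: Union[str, RootPrior, np.ndarray] = "equal",
) -> float:
    """Pruning log-likelihood of the tip states under rate matrix ``Q``."""
    if isinstance(prior, np.ndarray):
        prior = RootPrior(kind="custom", weights=prior)
    prior = _resolve_prior(prior, tips)
    idx = TreeIndex(tree)
    k = Q.shape[0]
    P = transition_matrices_for_lengths(np.asarray(Q, float), idx.lengths)
    weights = prior.resolve(Q, k=k)
    return float(pruning_loglik(idx.parent, idx.tip_state_array(tips, k=k), P, weights))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A maximized model: free rates, their slot expansion, and bookkeeping."""

    spec: ModelSpec
    params: np.ndarray  # free rates (natural scale), slot-order indices
    log_likelihood: float
    root_prior: RootPrior
    converged: bool
    n_restarts_used: int

    @property
    def rates(self) -> Dict[str, float]:
        return rates_by_slot(self.params, self.spec)

    @property
    def Q(self) -> np.ndarray:
        return build_Q(self.params, self.spec)

    def to_dict(self) -> Dict:
        return {
            "model": self.spec.name,
            "log_likelihood": self.log_likelihood,
            "rates": self.rates,
            "prior": self.root_prior.kind,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }


def _slot_arrays(spec: Optional[ModelSpec], k: int):
    from .ctmc import _SLOT_POS

    if k == 4:
        rows = np.array([_SLOT_POS[s][0] for s in SLOTS], dtype=np.int64)
        cols = np.array([_SLOT_POS[s][1] for s in SLOTS], dtype=np.int64)
        smap = spec.index_array()
    else:  # 2-state (gain, loss)
        rows = np.array([0, 1], dtype=np.int64)
        cols = np.array([1, 0], dtype=np.int64)
        smap = np.array([0, 1], dtype=np.int64)
    return smap, rows, cols


def _neg_loglik_factory(idx: TreeIndex, tip_arr, spec: Optional[ModelSpec], prior: RootPrior, k: int = 4):
    from . import _core

    smap, rows, cols = _slot_arrays(spec, k)
    if prior.kind == "stationary":
        prior_kind = _core.PRIOR_STATIONARY
        fixed_weights = np.full(k, 1.0 / k)  # placeholder, unused
    else:
        prior_kind = _core.PRIOR_FIXED
        fixed_weights = prior.resolve(None, k=k)

    def _build_Q(rates: np.ndarray) -> np.ndarray:
        Q = np.zeros((k, k))
        Q[rows, cols] = rates[smap]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def neg(logp: np.ndarray) -> float:
        val = _core.neg_loglik(
            np.asarray(logp, dtype=float), smap, rows, cols, k,
            idx.lengths, idx.parent, tip_arr, prior_kind, fixed_weights,
        )
        if not np.isnan(val):
            return min(val, _BIG)
        # fallback: scaling-and-squaring exponentials (near-defective Q)
        Q = _build_Q(10.0 ** np.asarray(logp, dtype=float))
        if prior_kind == _core.PRIOR_STATIONARY:
            try:
                weights = stationary_distribution(Q)
            except ValueError:
                return _BIG
        else:
            weights = fixed_weights
        P = transition_matrices_for_lengths(Q, idx.lengths)
        ll = pruning_loglik(idx.parent, tip_arr, P, weights)
        if not np.isfinite(ll):
            return _BIG
        return -ll

    return neg


def _multistart_minimize(
    neg, n_params: int, rng: np.random.Generator, n_restarts: int,
    extra_inits: Sequence[np.ndarray] = (), ftol: float = 1e-10, maxiter: int = 200,
):
    bounds = [(LOG10_LOWER, LOG10_UPPER)] * n_params
    best = None
    any_converged = False
    starts = [np.clip(np.asarray(x0, float), LOG10_LOWER, LOG10_UPPER) for x0 in extra_inits]
    starts += [rng.uniform(INIT_LOW, INIT_HIGH, size=n_params) for _ in range(n_restarts)]
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = scipy.optimize.minimize(
                neg, x0, method="L-BFGS-B", bounds=bounds,
                options={"ftol": ftol, "maxiter": maxiter},
            )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_converged, len(starts)


def fit(
    tree,
    tips: Dict[str, int],
    spec: ModelSpec,
    prior: Union[str, RootPrior] = "equal",
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    init_params: Optional[Sequence[Sequence[float]]] = None,
    ftol: float = 1e-10,
    maxiter: int = 200,
    factorize: bool = True,
    tree_index: Optional[TreeIndex] = None,
) -> FitResult:
    """Maximize the pruning likelihood over the free rates of ``spec``.

    ``init_params`` are extra starting points (natural-scale free rates) tried
    before the ``n_restarts`` random ones. For the independent model with an
    equal or stationary prior the fit is factorized into the two marginal
    two-state fits unless ``factorize=False``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior_r = _resolve_prior(prior, tips)
    idx = tree_index if tree_index is not None else TreeIndex(tree)
    extra = []
    if init_params is not None:
        extra = [np.log10(np.clip(np.asarray(p, float), 1e-8, None)) for p in init_params]

    if (
        factorize
        and spec.name == "independent"
        and prior_r.kind in ("equal", "stationary")
    ):
        return _fit_independent_factorized(
            tree, idx, tips, prior_r, n_restarts, rng, extra, ftol, maxiter
        )

    tip_arr = idx.tip_state_array(tips, k=4)
    neg = _neg_loglik_factory(idx, tip_arr, spec, prior_r, k=4)
    best, converged, n_used = _multistart_minimize(
        neg, spec.n_free, rng, n_restarts, extra_inits=extra, ftol=ftol, maxiter=maxiter
    )
    params = 10.0 ** best.x
    Q = build_Q(params, spec)
    weights = prior_r.resolve(Q, k=4)
    result = FitResult(
        spec=spec,
        params=params,
        log_likelihood=-float(best.fun),
        root_prior=RootPrior(kind=prior_r.kind, weights=weights)
        if prior_r.kind != "equal"
        else prior_r,
        converged=converged,
        n_restarts_used=n_used,
    )
    if not converged:
        # common and benign in capped-iteration bootstrap refits; the flag is
        # carried on the result for callers that care
        logger.debug("optimizer did not report convergence after %d starts", n_used)
    return result


def _fit_independent_factorized(
    tree, idx, tips, prior_r, n_restarts, rng, extra, ftol, maxiter
) -> FitResult:
    """Independent-model MLE via the exact two-trait factorization.

    With an equal or stationary root prior the joint prior is the product of
    the marginal priors, so the 4-state log-likelihood is the sum of the two
    2-state log-likelihoods and the optimization separates."""
    xs, ys = _tips_as_binary(tips)
    # independent free-param order: (y_gain, x_gain, y_loss, x_loss)
    extra_x = [e[[1, 3]] for e in extra]
    extra_y = [e[[0, 2]] for e in extra]
    fits = []
    for binary_tips, extra_i in ((xs, extra_x), (ys, extra_y)):
        tip_arr = idx.tip_state_array(binary_tips, k=2)
        prior2 = RootPrior(kind=prior_r.kind)
        neg = _neg_loglik_factory(idx, tip_arr, None, prior2, k=2)
        best, conv, n_used = _multistart_minimize(
            neg, 2, rng, n_restarts, extra_inits=extra_i, ftol=ftol, maxiter=maxiter
        )
        fits.append((best, conv, n_used))
    (bx, cx, nx), (by, cy, ny) = fits
    gx, lx = 10.0 ** bx.x
    gy, ly = 10.0 ** by.x
    params = np.array([gy, gx, ly, lx])
    spec = ModelSpec.independent()
    Q = build_Q(params, spec)
    weights = prior_r.resolve(Q, k=4)
    return FitResult(
        spec=spec,
        params=params,
        log_likelihood=-float(bx.fun) - float(by.fun),
        root_prior=RootPrior(kind=prior_r.kind, weights=weights)
        if prior_r.kind != "equal"
        else prior_r,
        converged=cx and cy,
        n_restarts_used=max(nx, ny),
    )


# ---------------------------------------------------------------------------
# Likelihood ratio testing
# ---------------------------------------------------------------------------

@dataclass
class CoevolutionTest:
    """An LRT between two nested trait-evolution models."""

    lrt: float
    df: int
    p_chi2: float
    p_bootstrap: Optional[float] = None

    def to_dict(self) -> Dict:
        out = {"lrt": self.lrt, "df": self.df, "p_chi2": self.p_chi2}
        if self.p_bootstrap is not None:
            out["p_bootstrap"] = self.p_bootstrap
        return out


def lrt_statistic(l_indep: float, l_dep: float, tol: float = 1e-6) -> float:
    """-2 (lnL_restricted - lnL_full), clamped at zero.

    A full-model likelihood below the restricted one (beyond ``tol``) can only
    be optimizer noise on nested models; it is clamped and logged."""
    lrt = -2.0 * (l_indep - l_dep)
    if lrt < 0.0:
        if lrt < -2.0 * tol:
            logger.warning(
                "restricted log-likelihood exceeds full (%.6g > %.6g); clamping LRT to 0",
                l_indep, l_dep,
            )
        return 0.0
    return lrt


def chi2_pvalue(lrt: float, df: int) -> float:
    """Upper-tail chi-square probability; for df=4 this is the closed form
    exp(-x/2) (1 + x/2)."""
    if lrt < 0:
        raise ValueError("lrt must be >= 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(scipy.stats.chi2.sf(lrt, df))


def run_coevolution_test(
    tree,
    tips: Dict[str, int],
    prior: Union[str, RootPrior] = "equal",
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    **fit_kwargs,
) -> Tuple[CoevolutionTest, FitResult, FitResult]:
    """Fit independent (4 rates) and dependent (8 rates) models and compare.

    The dependent fit is seeded with the independent MLE (mapped into the
    8-slot space) in addition to its random restarts, which both speeds
    convergence and enforces the nesting inequality in practice."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    indep = fit(tree, tips, ModelSpec.independent(), prior=prior,
                n_restarts=n_restarts, seed=rng, **fit_kwargs)
    dep_spec = ModelSpec.dependent()
    indep_full = np.array([indep.rates[s] for s in SLOTS])
    dep = fit(tree, tips, dep_spec, prior=prior, n_restarts=n_restarts,
              seed=rng, init_params=[indep_full], **fit_kwargs)
    lrt = lrt_statistic(indep.log_likelihood, dep.log_likelihood)
    test = CoevolutionTest(lrt=lrt, df=4, p_chi2=chi2_pvalue(lrt, 4))
    return test, indep, dep


def reduced_model_test(
    tree,
    tips: Dict[str, int],
    constraint: str,
    prior: Union[str, RootPrior] = "equal",
    n_restarts: int = 10,
    seed: Optional[Union[int, np.random.Generator]] = None,
    **fit_kwargs,
) -> Tuple[CoevolutionTest, FitResult, FitResult]:
    """Test one equality between dependent-model rates (df = 1).

    ``constraint`` must tie exactly one pair of slots, e.g. ``"q12=q34"`` to
    ask whether the Y-gain rate depends on the X background."""
    reduced = ModelSpec.with_ties(constraint)
    if reduced.n_free != 7:
        raise ValueError(
            f"constraint {constraint!r} must tie exactly one pair of slots "
            f"(got {reduced.n_free} free parameters)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    restricted = fit(tree, tips, reduced, prior=prior, n_restarts=n_restarts,
                     seed=rng, **fit_kwargs)
    # seed the full fit at the restricted optimum (expanded to all 8 slots) so
    # the nesting inequality holds in practice, plus its own random restarts
    restricted_full = np.array([restricted.rates[s] for s in SLOTS])
    dep = fit(tree, tips, ModelSpec.dependent(), prior=prior,
              n_restarts=n_restarts, seed=rng,
              init_params=[restricted_full], **fit_kwargs)
    lrt = lrt_statistic(restricted.log_likelihood, dep.log_likelihood)
    test = CoevolutionTest(lrt=lrt, df=1, p_chi2=chi2_pvalue(lrt, 1))
    return test, restricted, dep
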