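# Methods

## The model

Two binary site-traits (presence of a phospho-acceptor residue at one
reference position, presence of a sulfoxidable methionine at another) are
combined into a four-state character, states 1..4 = (0,0), (0,1), (1,0),
(1,1), evolving along a rooted tree with branch lengths as a continuous-time
Markov chain. Instantaneous double transitions (1↔4, 2↔3) have rate zero;
the eight single-trait rates q_ij are the free parameters of the dependent
model. The independent model ties q12=q34, q13=q24, q21=q43 and q31=q42,
leaving four parameters; arbitrary additional equalities (e.g. `q12=q34`
alone, a df = 1 contrast) express directional hypotheses about which trait
conditions the other's rates. Ambiguous tips (gap or unknown residue at
either focal position) enter the pruning algorithm with an all-ones partial
likelihood vector, the standard missing-data treatment; an option drops them
instead.

Root state frequencies can be `equal` (default), `stationary` (recomputed
from the candidate rate matrix inside the optimizer), `observed` (empirical
tip-state frequencies), or custom. The default is `equal` because the
substantive conclusions should be — and in our tests are — insensitive to
the choice; all four options are exposed.

## Likelihood, optimization, and numerics

The likelihood is the pruning (post-order) algorithm with per-node rescaling.
Transition matrices come from a spectral decomposition of Q, batched over all
branch lengths of the tree; the decomposition is rejected (and the
scaling-and-squaring Padé exponential used instead) when the eigenvector
matrix has a 1-norm condition estimate above 1e8, when any probability is
below −1e-8, or when a row sum strays from 1 by more than 1e-6. Accepted
matrices are clipped to [0, 1] and row-renormalized. The hot path (rate
assembly, exponentials, pruning) is a single numba kernel shared by the
4-state model and the 2-state factors.

Rates are optimized on the log10 scale, bounded in [1e-8, 1e3], with
multi-start L-BFGS-B (default 10 restarts, initial log10 rates uniform in
[−2, 1]; convergence tolerance 1e-10 relative on the objective). For the
independent model with an equal or stationary prior the 4-state likelihood
factorizes exactly into the two marginal 2-state likelihoods (the joint
prior is the product of the marginal priors and ambiguity always hits both
traits at once), so that fit is performed on the factors: it is faster and
avoids the joint optimizer's local optima; its equality with the joint
optimization is asserted in the tests. Dependent fits are additionally
seeded at the independent MLE expanded to the eight slots, which enforces
the nesting inequality L(D) ≥ L(I) in practice; any residual optimizer noise
is clamped to LRT = 0 with a logged warning.

## Parametric bootstrap

The null distribution of LRT = −2 ln L(I)/L(D) is built by simulating tip
states under the independent-model MLE (root drawn from the fitted prior),
refitting both models per replicate, and recording the LRT; the empirical
p-value uses the add-one estimator (1 + #{null ≥ observed})/(n_sims + 1).
Default n_sims = 1000; desk-scale analyses reduce it. Replicate refits are
seeded at the generating rates (independent refit) and at the replicate's own
independent MLE (dependent refit) with no random restarts by default —
and, importantly, the observed statistic entering the p-value is recomputed
under this *same* fitting policy (`matched_policy_lrt`): a bootstrap
approximates the distribution of the statistic as computed, so comparing a
heavily optimized observed LRT with cheaply refitted nulls would bias p
downward. Replicates in which every tip shares one state are scored LRT = 0
without optimization (both models attain the same supremum as all rates go
to zero).

Calibration, measured by the test suite at the documented problem sizes: on
a 100-tip tree the null sample (500 simulations) has mean ≈ 4.0 and variance
≈ 7.2, consistent with χ²₄; the type-I error of the bootstrap test at
α = 0.05 is within the binomial confidence band at 100 tips (0.033, n = 60)
but inflated on a 50-tip tree (≈ 0.12 at 100 replicates × 99 simulations).
The 50-tip inflation is a plug-in effect, not an implementation defect: an
oracle bootstrap simulating from the true generator calibrates correctly on
the same trees, while the fitted 4-rate generator is noisy at 50 tips and
its null quantiles are on average lower than under the true rates. The
corresponding acceptance test is left failing with this analysis on record;
analyses of 50-species datasets should lean on the χ² calibration with
caution and prefer larger taxon samples.

## Pairwise contrasts

A maximal set of tip pairs is sought such that the two members of each pair
differ in both traits — combined states {1, 4} (a *positive* pair: the
phospho-acceptor and the methionine co-occur in one member) or {2, 3}
(*negative*) — and the tree paths of distinct pairs share no nodes or edges.
A dynamic program over the rooted tree computes the maximum: since at most
one pair's path can cross any node, each subtree contributes either a closed
sub-solution or one open tip whose path continues upward. Among equally
large pairings, ties are broken deterministically by smaller total path
length, then lexicographic tip names (the tie-break is greedy per node; the
pair *count* is exactly maximal and is verified against exhaustive search on
small trees). The sign imbalance is tested with a two-sided exact binomial
test at p = 0.5. Ambiguous tips never pair.

## Stochastic character mapping

Histories conditional on the tip states and a rate matrix are sampled in two
stages: node states from their exact joint conditional distribution (pruning
partials upward, categorical sampling downward), then each branch path by
uniformization conditioned on its endpoints (Poisson-mixed numbers of
virtual jumps via incremental powers of R = I + Q/Λ, jump times as uniform
order statistics, intermediate states by forward–backward weights; virtual
self-jumps are collapsed into dwell segments). A retry cap guards
numerically extreme branches. The default rate matrix is the dependent-model
MLE ("empirical" mode); a deliberately simple random-walk Metropolis sampler
over log10 rates with Exp(1) priors provides approximate posterior draws of
Q for sensitivity checks ("mcmc" mode), not rigorous Bayesian inference.

Transitions are scored Ridley-style to blunt pseudo-replication: a branch
counts only if its begin and end states differ, and it increments the cell
of its *end* state. Aggregated over maps (default 10), the four counts form
a 2×2 table with rows = X of the end state and columns = Y, tested with
Yates' continuity-corrected χ² — statistic Σ max(|o−e|−0.5, 0)²/e, p from
the upper χ²₁ tail — and with Fisher's exact two-sided test.

## Synthetic data

The generator emulates the statistical shape of a real ortholog analysis
without external downloads. Trees are pure-birth (Yule) with birth rate 1.0
— ultrametric, like taxonomy-calibrated species trees, and simple; tree
shape is not a quantity the analysis constrains. Traits evolve by exact
Gillespie simulation under a configurable generator: independent defaults
(gains 0.5, losses 1.0 — presence rarer than absence, as for modifiable
residues) or dependent defaults in which gains are 10× faster on the
modified background (q24 = q34 = 5.0 vs 0.5) and losses 5× slower (q42 =
q43 = 0.2 vs 1.0), a strong interaction suitable for power checks. A third,
"darwin" scenario plants both traits once in a single internal clade
(20–50% of tips) with no further change — the single-origin confound that
correlation tests must not mistake for repeated coevolution; the
pairwise-contrast machinery correctly finds at most one separate pair there.

Alignments carry the traits at two focal columns: state-1 residues are drawn
from {S, T} (X) or {M} (Y), state-0 residues from the disjoint pool
{A, G, L, V, E}, so decoding with the generating trait definitions returns
the simulated states exactly; background columns are i.i.d. uniform over the
20 amino acids and carry no signal. An optional gap rate (default 0) writes
gaps at focal positions to exercise ambiguity handling. What the generator
does *not* emulate: realistic substitution processes at background columns,
alignment error, rate heterogeneity across lineages, or non-ultrametric
branch lengths — so green tests certify the statistical machinery, not
robustness to alignment artifacts.

Every dataset is reproducible bit-for-bit from its config (the truth record
stores the config, generating rates, and all node states).

## Problem sizes used by the test suite

Chosen to keep the full suite within a desk-scale budget while leaving the
checks statistically meaningful: parameter recovery at 20 replicates × 200
tips; bootstrap null moments at 500 simulations × 100 tips; type-I
calibration at 100 replicates × 99 bootstrap simulations × 50 tips; power at
8 + 8 replicates × 60 tips × 59 simulations; brute-force oracles at ≤ 8 tips;
stochastic-mapping conditionals at 10⁴ maps on 4 tips.

## Known limitations

* The bootstrap test is anticonservative on small (~50-tip) trees (see
  above); the χ²₄ reference itself is slightly conservative in variance on
  100-tip trees (null variance ≈ 7 rather than 8).
* The LRT's regularity conditions erode when a trait is nearly constant:
  rates sit on the [1e-8, 1e3] boundary and the LRT piles up near 0. The
  control-battery driver short-circuits exactly constant traits to LRT = 0,
  p = 1.
* The contrast DP returns one deterministic maximal pairing; enumerating all
  maximal pairings is not implemented (counts across ties can differ in
  composition, never in size).
* The "mcmc" mode for mapping is a convenience sampler (short random-walk
  chains, no convergence diagnostics).
* Tree inference is out of scope: trees are inputs (the neighbor-joining
  implementation is provided for robustness comparisons, with deterministic
  tie-breaking by taxon label and negative branch estimates clamped to zero,
  the deficit moved to the sibling edge). Branch lengths are used as given;
  missing Newick lengths default to 1.0.
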