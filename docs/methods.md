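# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite shows.  Everything quantitative below is computed by
the tests or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Data model and encoding

A wordlist is a set of (doculect, concept, form, cognate-set) records.
Cognate sets are scoped to one concept (root-meaning coding); a set id
appearing under two concepts is a hard validation error.  Encoding produces
one binary character per cognate set with three-valued cells.  Two policies
the source data format leaves open are configurable:

* **Synonyms** — a doculect with entries in several sets of one concept is
  *present* on each (soft membership; the alternative "first entry only" is
  a flag in the TIGER computation, where multistate characters make the
  choice visible).
* **Singletons** — characters present in exactly one taxon are kept by
  default (`drop_singletons` drops them); the ascertainment correction
  assumes they are observable, so keeping them is the coherent default.

Concept filtering keeps concepts attested in at least (1 − max_missing) of
the doculects, with a 1e-9 tolerance so exact boundaries (8 of 10 at 20%)
are kept.  Partitioning assigns whole concepts to k partitions by greedy
descending-size bin balancing, ties broken by concept id, so the split is
deterministic and concepts are never divided.

## Reticulation statistics

* Pairwise cognacy uses the *mutually attested* concepts as denominator;
  pairs with no shared concepts are undefined (NaN) and must be dropped
  before the network stage (an error lists the taxa).
* Diversity D = (C − M)/(W − M); undefined when W = M.
* TIGER: for concepts i, j the partition agreement pa(i→j) is the mean over
  j's cognate classes of the best overlap fraction with any class of i,
  computed over taxa non-missing in both; rate(j) is the mean of pa(i→j)
  over i ≠ j.  Concepts with fewer than two non-missing taxa are excluded
  and logged.
* δ-scores / Q-residuals: quartets are enumerated exhaustively up to 45
  taxa (C(45,4) ≈ 149k) and subsampled (10⁵, seeded) above; Q-residuals
  are computed on a copy of the distance matrix rescaled to mean
  off-diagonal 1, so they are invariant to the overall distance scale.
  δ of a fully degenerate quartet (m₁ = m₃) is 0 by convention.

## NeighborNet

The circular ordering follows the classic agglomerative scheme: clusters of
1–2 linked nodes, cluster pair chosen by the neighbor-joining criterion on
cluster-averaged distances, node pair inside the chosen clusters by the
same criterion with those nodes treated as singleton clusters, three-node
paths reduced to two replacement nodes with (2/3, 1/3) weighted distances,
reductions expanded in reverse at the end.  Split weights solve a
nonnegative least-squares problem over all n(n−1)/2 splits of the circular
ordering (scipy's NNLS); splits below 1e-6 are dropped.  On additive
distances the output reproduces the generating tree's splits to machine
precision (tested to 1e-8), which is the key correctness oracle.

## Covarion model and likelihood

States are ordered (0 fast, 1 fast, 0 slow, 1 slow).  Visible moves occur
at rate 1 (fast) or α (slow), weighted by the target visible frequency;
regime switches occur at rate s weighted by the target hidden frequency and
preserve the visible state.  The stationary distribution is the outer
product of visible and hidden frequencies, and the generator is rescaled so
the expected *visible* substitution rate at stationarity is 1 — branch
lengths are expected visible changes.  A flag selects the alternative
dialect without visible-frequency weighting (which then requires uniform
visible frequencies).  Transition matrices come from one eigendecomposition
per likelihood evaluation, applied to all branches at once.

Pruning marginalises the hidden regime at the tips and rescales partials
per node.  Ascertainment corrects per partition only for all-absent
patterns (all-present cognate sets are observable in wordlists):
log L − N·log(1 − L₀).  Correctness is pinned by brute-force enumeration
over all internal-state assignments on 4-taxon trees (1e-10) and by the
s = 0 mixture identity against two independent binary models.

## Priors and MCMC

* Birth–death tree prior conditioned on the root age with complete
  sampling: interior heights i.i.d. with density
  v′(t)/V(T), v′(t) = r(1−a)e^{−rt}/(1−a e^{−rt})², net diversification r,
  turnover a; the Yule case reduces to the truncated exponential, checked
  against the closed form.  Serially sampled tips are accepted by the
  machinery but the density is derived for contemporaneous tips.
* Uniform root prior on user-set bounds (the shipped default, 1500–5000 BP,
  is an archaeologically plausible window for a mid-Holocene family, as
  documentation rather than dogma); monophyly constraints reject by −∞,
  optional uniform height ranges per constraint.
* UCLN branch rates are sampled directly as continuous parameters
  (lognormal with mean equal to the clock mean — no discretised rate
  categories), stdev 0 degenerating to a strict clock.
* Scalar defaults: α ~ U(0,1], s ~ Exp(1), ucln-sd ~ Exp(1/3), net
  diversification ~ Exp anchored at ln(n)/root-midpoint (deliberately
  independent of the sampled heights so the root marginal stays uniform
  under the prior), turnover ~ U[0,1), optional lognormal prior on the
  clock mean.
* Operators: node-height slide, root and whole-tree scalers, narrow/wide
  exchange, per-branch rate and scalar multipliers, and a joint
  **up–down** move (stretch heights, shrink rates) — without it the chain
  cannot traverse the rate–time ridge and root-age posteriors are
  effectively frozen near their starting point.  Scalar multipliers use a
  4× wider log-window than the tree scalers; acceptance rates are logged.
* Chain length "2.5e7 iterations" style runs are the full-scale setting;
  all shipped defaults are desk-scale (2×10⁵ default config; tests use
  10³–10⁴ with burn-in 0.5), chosen as the package's own problem sizes.

The MCC summary takes clade posteriors from the post-burn-in sample, picks
the sampled topology maximising the product of its clade posteriors, and
sets each node height to the *common-ancestor height* — the mean MRCA
height of the clade's taxon set over all post-burn-in trees — with 95%
HPDs; rare parent/child height inversions produced by CA averaging are
flattened by an epsilon push.  ESS is the autocorrelation-based estimate
(arviz); a constant series reports ESS 1 with a warning.

## Sampler validation

Two experiments in the test suite justify trusting the chain:

* **Prior recovery** — with the likelihood off, the sampled root height is
  uniform on its bounds (KS test on a strided subsample, since raw MCMC
  draws are autocorrelated).
* **Simulation-based coverage** — 20 replicates at 12 taxa × 300
  characters, with the true tree drawn from the inference prior itself (a
  short prior-only chain), scalar truths drawn from their priors, data
  simulated by the exact forward version of the likelihood (stationary
  root, observable-conditioned), and chains initialised at the truth; the
  95% HPDs for root age, α and s must cover the truth in ≥ 90% of
  replicates.  Initialising at the truth is the standard shortcut for a
  scaled-down coverage experiment: it removes burn-in transients without
  touching the stationary distribution being tested.

## Phylogeography

The per-branch displacement density on the central angle,
f(θ|v) ∝ exp(−θ²/(2v)) with the spherical area weight sinθ and v = t/τ, is
a documented approximation to the exact spherical heat kernel, normalised
numerically (cached quadrature) and isolated in one function so the exact
series density could be swapped in.  τ has a lognormal prior centred on the
initial guess (log-sd 2 by default; degenerate identical-tip scenarios
need a wider prior, e.g. 4, to let τ escape upward — a config choice, as
the likelihood then grows without bound).  Location proposals are
tangent-plane Gaussian steps whose size adapts to √(mean branch
duration/τ), which keeps acceptance reasonable across the whole τ range;
heights, when enabled, slide inside uniform windows given by the dating
round's 95% HPDs intersected with local tree constraints (the two-round
design: topology fixed by clades with posterior support ≥ 0.70).

80% HPD regions are convex hulls of the densest 80% of posterior samples
around the spherical mean — adequate for unimodal clouds, an
over-approximation for crescent-shaped ones.

## Radiocarbon calibration

Probability-method calibration on a 1-year grid spanning the curve, with
the curve error added in quadrature; 95.4% HPD unions; endpoints rounded
*outward* to 10 years (inferred convention of archaeological range
reporting).  No reservoir, outlier or sequence modelling.  The identity
curve μ(θ) = θ with negligible error gives the analytic ±2σ check
(2430 ± 20 → cal BP 2470–2390).  A real southern-hemisphere curve is not
shipped (it is a sizable external data product); any IntCal-format CSV can
be passed to `analysis/06_radiocarbon.py --curve`.

## Synthetic data: what it emulates, and what it does not

The generator produces: birth–death trees conditioned on the taxon count
(forward simulation, pruned and rescaled to the root age), lognormal branch
rates, concept-structured cognate characters evolving by the covarion jump
process (Gillespie per branch) with fresh-set innovation along branches,
one optional horizontal transfer per character (recipient subtree re-evolved
from the donor's state at a uniform event time — the minimal mechanistic
choice), per-language coverage masks, and isolate replacement roots where a
language lost every inherited set (a documented language always has *some*
word).  Geography is a forward spherical random walk using the same kernel
as the inference (rejection sampling with a Rayleigh envelope).

Defaults are the study conditions: 40 doculects, 415 concepts, coverage
49–99%, root age 3300 BP, and τ = 25 000 (root-to-tip dispersal ≈ 20°, a
continental footprint).  The lexical turnover defaults (clock mean 1×10⁻⁴
changes/character/year, relative loss 0.7, innovation 0.35 per lineage per
expected change) were calibrated once so the generated family's cognacy
diversity sits at the documented ≈ 15% level for a family of this size and
age; they imply roughly 10% basic-vocabulary replacement per millennium.

What passing tests show — and what they do not: the recovery and coverage
experiments demonstrate internal consistency (the inference recovers what
the forward model generated) at small problem sizes.  They do not show that
real lexical data satisfy the covarion model, that borrowing in real
families is a single uniform-time copy event, or that documentation gaps
are independent Bernoulli masks.  Topology recovery is asserted only under
*high-signal* settings (trees rejection-filtered to internal edges ≥ 8% of
the root age, 200 concepts, mild rate variation): with short internal
edges the data genuinely do not determine the topology and no sampler
could recover it.

The borrowing experiments compare *paired* datasets — the transfer events
are applied to a clone of the same simulated characters — because the
directional effect of borrowing on TIGER (down) and δ (up) is small
relative to between-run simulation noise.  The experiment uses full
coverage and a higher lexical turnover than the package defaults
(clock 6×10⁻⁴, innovation 1.0): TIGER measures agreement between concepts'
multistate partitions, so the effect is only visible when concepts carry
informative multi-member classes; near-uniform cognacy leaves it nothing
to measure.

## Known limitations

* The birth–death density ignores tip-age corrections for serial samples.
* The spherical kernel is the Gaussian-on-angle approximation, not the
  exact heat kernel (isolated behind `angle_log_density`).
* The MCC search considers sampled topologies only (as summary tools do).
* The NNLS split-weight fit is exact for circular-decomposable metrics but
  the agglomerative ordering is a heuristic for general data.
* Likelihood computations are single-threaded and recomputed in full per
  proposal; fine at desk scale, not tuned for 10⁷-iteration runs.
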