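# lexiclade

Lexical phylogenetics for cognate-coded wordlists: from a comparative
word table to (i) reticulation diagnostics, (ii) a Bayesian dated language
phylogeny under a binary covarion model, and (iii) a continuous
phylogeographic reconstruction on the sphere, with the radiocarbon
calibration arithmetic needed to compare linguistic dates with
archaeological chronologies.

The package is organised as an analysis project: every computation lives in
the library under `src/lexiclade/`, and the numbered scripts under
`analysis/` run the study pipeline end to end on a synthetic comparative
dataset whose statistical structure mirrors a continental-scale language
family (40 doculects, 415 concepts, per-language concept coverage between
49% and 99%, covarion-style rate heterogeneity, relaxed-clock branch rates,
optional horizontal transfer).

## The models

**Characters.** Each cognate set — a group of words descending from one
ancestral root, scoped to a single concept ("root-meaning" coding) — is a
binary presence/absence character.  Cells are *present*, *absent* (the
language attests the concept with other roots) or *missing* (the concept is
undocumented for that language).

**Reticulation diagnostics.**  With pairwise distances d = 1 − (shared
cognacy), every 4-subset of taxa yields the three pairing sums
m₁ ≥ m₂ ≥ m₃; the δ-score (m₁−m₂)/(m₁−m₃) and the Q-residual (m₁−m₂)² on
mean-1-rescaled distances are zero exactly when the quartet is additive.
A from-scratch NeighborNet (agglomerative circular ordering + nonnegative
least-squares split weights) displays the conflicting signal; TIGER rates
score each concept's agreement with the taxon partitions induced by all
other concepts.  Cognacy diversity is D = (C−M)/(W−M) for C cognate sets,
M concepts, W coded words.

**Dating.**  Characters evolve by a 4-state binary covarion chain — a
symmetric presence/absence process that switches between a fast and a slow
regime (ratio α, switch rate s) — rescaled to one expected visible change
per unit branch length, with ascertainment correction for never-observable
all-absent patterns.  The tree prior is a birth–death process conditioned
on the root age, the root gets a uniform prior on user-set bounds, branch
rates are i.i.d. lognormal (UCLN relaxed clock), and monophyly constraints
are honoured by the samplers.  The posterior is summarised as a maximum
clade credibility tree with common-ancestor heights and 95% HPDs.

**Phylogeography.**  Given the dated tree and tip coordinates, internal
locations follow an isotropic spherical diffusion whose per-branch step has
density ∝ exp(−θ²/2v)·sinθ with v = t/τ; the posterior of node locations
and the precision τ is sampled by MH, and 80% HPD regions are exported as
GeoJSON.

**Radiocarbon.**  Conventional ¹⁴C ages are calibrated against an
IntCal-format curve by the probability method, reported as 2σ (95.4%) HPD
calendar ranges rounded outward to 10 years.

## Worked example

```sh
python analysis/01_simulate_dataset.py --seed 1
python analysis/02_cognacy_stats.py
python analysis/03_reticulation_network.py
python analysis/04_dated_phylogeny.py --seed 1
python analysis/05_phylogeography.py --seed 1
python analysis/06_radiocarbon.py
```

prints, stage by stage (seed 1):

```
simulated 40 doculects x 415 concepts (12707 coded words, 1009 cognate sets)
coverage range 0.47-0.98; wrote results/data

cognacy diversity: 15.0%
TIGER mean 0.94 (±0.04) over 415 concepts

δ-score 0.3124, Q-residual 0.014330 over 91390 quartets
125 weighted splits; wrote results/network

study 'full': 44 concepts, 253 characters
root height 2274 BP (95% HPD 1502-4020)

root location posterior mean: (-31.15, -86.51)
diffusion precision τ median: 19217

2430±20 14C BP  ->  cal BP 2470-2390   (synthetic identity curve)
2010±75 14C BP  ->  cal BP 2160-1860   (synthetic identity curve)
```

The diversity of 15% says the simulated family is lexically homogeneous
(fully shared vocabulary would give 0%, every word an isolate 100%); the
δ-score of 0.31 indicates a substantial non-tree-like component, as
expected with borrowing switched on.  The dated run recovers a root inside
the prior window with an honest, wide HPD (the truth, 3300 BP, lies
within it).  The phylogeographic round, which inherits whatever topology
and dating error the short desk-scale chain leaves behind, here places the
root about 30° from the simulated homeland at (−10, −55) — the
pipeline-level recovery experiments in the test suite quantify this
honestly (the 80% HPD region contains the true root in most seeded
replicates when the topology is well supported).  The last stage
reproduces the analytic ±2σ ranges on the identity curve; point `--curve`
at a southern-hemisphere calibration CSV to calibrate against a real
curve.

A `lexiclade` console command exposes the same stages
(`encode`, `stats`, `network`, `infer`, `geo`, `c14`, `simulate`) for use
on your own wordlists.

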