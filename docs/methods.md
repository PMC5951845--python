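# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the design decisions behind `nestevo`, in the
spirit of a statistical-methods appendix.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The Mk model and its likelihood

Each nest character is modelled as a k-state continuous-time Markov
chain on a rooted tree with branch lengths (structure and site: k = 7;
attachment: k = 4).  The default equal-rates (ER) parameterisation has a
single rate *q* (expected transitions per unit branch length) and the
closed-form transition probabilities

    P_same(t) = 1/k + (k−1)/k · e^(−k q t),
    P_diff(t) = 1/k − 1/k · e^(−k q t).

The all-rates-different (ARD) variant exponentiates the generator via
eigendecomposition, with a dense `expm` fallback when the eigenvector
matrix is ill-conditioned (condition number > 1e8); tiny negative
entries from round-off are clipped at zero.

Likelihoods are computed by Felsenstein pruning over a flat postorder
encoding of the tree, compiled with numba.  Per-node partial-likelihood
vectors are rescaled by their maximum, with log-scalers accumulated, so
243-tip × 7-state likelihoods stay in range.  Tip data are *sets* of
states: a polymorphic family contributes an indicator vector with 1 on
every observed state (the likelihood sums over them), a missing family
an all-ones vector.  The root is closed with a uniform prior over the k
states; with that prior the ER chain is time-reversible, so the
likelihood is invariant to root placement (property-tested).  Pruning is
verified against exhaustive enumeration over internal-node assignments
on random trees of up to six tips, to 1e-10.

## Bayesian sampling over a tree set

Rates carry independent exponential priors with mean 0.1 (in units of
transitions per unit branch length — weakly informative for
time-calibrated trees whose height is a few units).  Sampling is
Metropolis–Hastings on log-rates with symmetric uniform (sliding-window)
proposals; the log-transform Jacobian is included so the target remains
the posterior of *q*.  One randomly chosen rate is updated per
iteration.

Rather than repeating the analysis on every tree of the set, the tree
index is a sampled parameter: each iteration proposes replacing the
current tree with one drawn uniformly from the set and accepts by the
likelihood ratio.  The posterior therefore integrates over topological
and branch-length uncertainty in a single run.

The proposal window is adapted every 100 iterations during burn-in
toward a 20–40% acceptance band and is frozen at the end of burn-in, so
detailed balance holds for every retained sample; ending outside the
band raises a warning, not an error.  Desk-scale defaults (50k
iterations, 10k burn-in, thinning 20, 3 chains) keep a run in seconds;
the published-scale profile (20M/2M/10k for ancestral states, 200M/20M
for the interdependence tests) is available via
`MCMCConfig.published_profile` and the pipeline's `profile="published"`.

Convergence is gated programmatically instead of by eyeballing trace
plots: classic split-chain R-hat (threshold 1.05) plus Geyer
initial-positive-sequence effective sample size (threshold 500).  The
ESS estimator enforces monotone non-increasing autocorrelation pair
sums and is cross-checked in the tests against arviz and against the
closed-form AR(1) value.

**Prior recovery as a correctness oracle.**  With every tip missing the
likelihood is identically 1, so the sampler must reproduce the
exponential(0.1) prior; the acceptance suite checks the posterior mean
against 0.1 within three Monte-Carlo standard errors.

## Ancestral states

For every retained posterior sample (rates + tree index), marginal state
probabilities are computed at each node by the standard up–down pass.
Monitored clades are identified by their tip sets (by default the clades
of the majority-rule consensus); on each sampled tree the clade's value
is read at the MRCA of its tip set, and samples whose tree does not
contain the clade as a monophyletic group are excluded from that clade's
average.  The reported `support` is the fraction of samples containing
the clade.  An explicitly requested clade present in no sampled tree is
an error rather than a silent NaN.

## Consensus tree with least-squares branch lengths

The majority-rule consensus keeps exactly the clades occurring in
strictly more than half of the trees (clade = rooted tip set, counted
directly rather than as unrooted bipartitions).  Branch lengths are fit
by unweighted least squares of the edge–path incidence matrix against
the mean patristic distance matrix of the set, constrained non-negative
(plain `lstsq` when the unconstrained solution is already non-negative,
bounded least squares otherwise).  On a set of identical trees this
reproduces the original branch lengths to 1e-8 because the distances
are exactly additive.

## Interdependence between characters

The Discrete framework compares an *independent* model — each binary
trait has its own gain and loss rate (4 free rates; nothing in the
analysis constrains them equal) — with a *dependent* model in which each
trait's gain/loss rates take different values depending on the other
trait's current state (8 free rates).  Both are Markov chains on the
joint states {00, 01, 10, 11} with simultaneous double transitions fixed
at rate 0.  With context-free rates the joint likelihood factorises into
the two single-trait likelihoods; the tests verify this equivalence
against the Mk machinery to 1e-8.

Multi-state characters are collapsed to binary ones by the three named
presets (scrape × ground, cup × non-tree vegetation, cup-or-dome ×
non-basal).  A family carrying states of both categories is coded as the
later-derived category; missing families stay missing, and a tip missing
one trait is treated as compatible with both joint states of that
component.

Model comparison uses BF = 2·ΔlnML with the harmonic-mean estimator,
computed stably in log space.  The harmonic mean is kept as the primary
estimator for fidelity to common practice despite its known high
variance; two mitigations are built in: (1) the per-chain estimates of
the three replicate chains are averaged, and (2) a power-posterior
stepping-stone estimator (betas at Beta(0.3, 1) quantiles) is available
for robustness checks.  Conclusions are read from the BF > 5 threshold,
not from the absolute lnML values.

Directionality is summarized from the dependent-model posterior as
ordering probabilities, e.g. P[q(B gain | A derived) > q(B gain | A
ancestral)], mirroring the question of which character's change enables
the other's.

## Phylogenetic signal

Trait dissimilarity between two families is Bray–Curtis on their state
sets, 1 − 2|A∩B|/(|A|+|B|), which on single-state families reduces to
the 0/1 mismatch metric; families missing the character are dropped from
both matrices beforehand.  Phylogenetic distance is patristic distance
on the consensus tree (an option averages patristic matrices over the
tree set instead).  The Mantel statistic is the Pearson correlation of
the strictly-upper-triangle entries.

*Conventional* null: joint row/column permutation of the trait matrix
(family-label shuffling), the standard Mantel permutation scheme.
*Evolutionary-model* null: the character is re-simulated on the tree
under the fitted neutral ER model — posterior-mean rate and MAP root
state, as point estimates — and each replicate yields one null
correlation.  Simulated null tips are single states (the neutral
simulator produces no polymorphism); empirical polymorphism enters only
through the empirical Bray–Curtis matrix.  Zero-variance simulated
matrices (monomorphic replicates) are dropped with a warning and
reported in the result.

p-values are two-sided by doubling the smaller add-one-corrected tail,
because conserved characters deviate positively and anti-conserved ones
negatively from the nulls.  At saturating rates the EM null and the
permutation null coincide in distribution (tested by Kolmogorov–
Smirnov), as simulated tips become label-exchangeable.  Both tests are
calibrated: under their own nulls the empirical type-I error at α = 0.05
is nominal within three binomial standard errors (200 datasets × 199
replicates).  Default replicates are 9,999 per test; the desk profile
uses 199.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs:

- **Trees**: Yule (pure-birth) trees, default 242 tips and birth rate 1
  per unit time, root split at time 0 and a final exponential extension,
  so the expected height is Σ_{m=2..n} 1/m (checked by Monte Carlo).
  Tree-set uncertainty is emulated by random rooted NNI moves (default
  2 per tree) plus multiplicative log-normal branch-length noise with
  mean 1 and CV 0.1 — a controllable, seedable stand-in for a
  pseudo-posterior tree sample; ultrametricity is deliberately *not*
  restored after jitter, since no downstream method relies on it.
- **Traits**: recursive simulation from the model's transition matrices
  from a chosen root state.  Polymorphism and missingness are injected
  post hoc per tip (defaults: 15% second-state probability, 3% missing),
  because no generative model of within-family polymorphism is implied
  by the analysis; the polymorphism is therefore *neutral* with respect
  to the tree.
- **Correlated binary pairs**: a 4-state joint chain built from 8
  contingent rates.  Two named reference conditions are exported:
  `STRONG_DEPENDENCE_RATES` (B gains its derived state only while A is
  derived: contingent gain 1.0 vs 0, A toggling at 0.3, losses 0.1) and
  `CONTEXT_FREE_RATES` (same magnitudes, no contingency).  Strong
  dependence at the 200-tip scale yields BF > 5 in the large majority of
  replicates, with the residual failures being data-limited (the
  maximum-likelihood gap itself is small when the tree realises few
  informative contrasts), not estimator noise.
- **Demo family table**: the demo matrix mirrors the published
  descriptive profile of nest attachment — 80% of families exclusively
  basal, 90% basal inclusive — by filling category quotas in the rank
  order given by a low-rate Markov simulation on the tree, so marginal
  frequencies are matched exactly (up to rounding) while phylogenetic
  clustering of the non-basal families is preserved.  Six families are
  flagged missing (brood parasite / mound builder / no data), and the
  clade closest to 55% of tips is flagged as the passerines so
  subset analyses have a monophyletic target.

What passing tests on these data do *not* show: real nest characters
are not Mk-distributed (rates vary across lineages and states),
polymorphism is phylogenetically structured in reality, and BirdTree
pseudo-posteriors differ from NNI-jittered tree sets.  The tests
establish correctness and calibration of the machinery, not biological
conclusions.

## Degenerate inputs and numerical edge cases

- Zero-variance trace → ESS and R-hat raise rather than return NaN.
- A binary trait with a single observed state triggers a degenerate-
  trait warning (contingent rates unidentifiable) but the fit proceeds.
- Empty state sets are rejected by Bray–Curtis (missing families must be
  dropped upstream); a monomorphic empirical character makes the Mantel
  statistic undefined and raises.
- `t = 0` branches yield exact identity transition matrices; likelihood
  0 returns −inf rather than a numerical error.
- Character CSV I/O validates the state vocabulary, the
  missing-reason/empty-states invariant and family uniqueness at parse
  time.

## Reported problem sizes

Acceptance-level checks run at the scale the analyses target: 200–242-tip
trees for parameter recovery, model selection and conserved-trait
detection; 50-tip trees × 200 datasets for Mantel calibration; sampler
runs of 6k–60k iterations with the acceptance band and thinning as
above.  These sizes are the package's desk-scale study conditions; the
`published` profile reproduces the published run lengths when compute
allows.
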