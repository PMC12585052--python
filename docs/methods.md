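# Methods

## The model

`bbmrange` reconstructs ancestral geographic ranges on a fossil-calibrated
ultrametric phylogeny (a chronogram, branch lengths in Myr, ages measured
backward from the present) and converts the reconstruction into per-lineage
rates of geographic transition and in-situ lineage origination.

Presence or absence of a lineage in each of up to ten single-letter areas is
treated as an independent binary character evolving under a two-state F81
process.  With stationary presence frequency π₁ (π₀ = 1 − π₁), the
instantaneous rates are gain = βπ₁ and loss = βπ₀ with
β = 1 / (2π₀π₁), which normalizes the process to one expected change per Myr
per unit rate multiplier at stationarity.  The finite-time transition
probabilities are

    P_ij(t) = π_j + (δ_ij − π_j) · exp(−β r t)

Among-area rate heterogeneity ("+G") is a discrete-gamma mixture: a mean-1
gamma with shape α is cut into k equal-probability categories (k = 4 by
default, the dominant convention), each category's multiplier being the mean
of its quantile slice, so multipliers are strictly increasing with mean
exactly 1.  Each area belongs to an unknown category; the likelihood
averages categories with equal weight per area.

Character likelihoods use Felsenstein pruning with the stationary
distribution (π₀, π₁) as root prior.  Marginal presence posteriors at every
node come from a standard outside–inside (up–down) pass, mixing the gamma
categories by their per-area data likelihoods.  The pruning engine is
level-batched: nodes are grouped into topological levels and each level is
processed as one vectorized numpy operation over (areas × categories × 2)
arrays; the F81 structure collapses the 2×2 matrix–vector product to
`m_i = e·L_i + (1 − e)·(π·L)`, so a full-tree likelihood at 100–200 tips,
10 areas and 4 categories costs ~1–2 ms.

## MCMC

The sampler is Metropolis–Hastings over (π₁, α) with the product of
per-area pruning likelihoods as the data term.  Priors are weakly
informative: π₁ ~ Uniform(0, 1), α ~ Exponential(mean 1).  Proposals
alternate a reflected sliding window for π₁ (half-width 0.1, reflected at 0
and 1) and a multiplier move for α (log-scale window 0.7, Hastings ratio
α′/α).  Chains start from dispersed points (π₁ uniform on (0.05, 0.95), α
log-uniform on (0.25, 4)) and run independently; samples after burn-in are
pooled.  The default run configuration — ten chains of 100,000 generations,
20,000 burn-in, sampling every 100, ancestral ranges capped at three areas —
yields 8,000 pooled samples.

One master seed spawns per-chain substreams (`numpy.random.SeedSequence`),
so identical (seed, inputs) give bit-identical output.

Per-node presence posteriors are Rao-Blackwellized: the analytic marginal
posterior is computed at every retained sample and averaged (memoized on the
parameter pair, since rejected moves repeat values).  Per-area posteriors
p_a at a node are composed into a range posterior assuming independence:

    weight(S) = Π_{a∈S} p_a · Π_{a∉S} (1 − p_a)

over non-empty S with |S| ≤ max_areas, renormalized; if every allowed weight
underflows to zero, the posterior collapses to the single best area.  The
MAP range is the argmax, with ties broken deterministically by smaller
cardinality, then lexicographically in alphabet order.  The reference
implementation of this style of analysis (RASP's Bayesian Binary method)
does not document whether it composes marginals multiplicatively or samples
joint ranges; the composition above is this package's definition and is
exactly testable.

## Events and rates

Given one range per node, a **transition** is any branch whose parent and
child ranges differ as sets (including pure expansions, {D} → {D,E}); an
**origination** is any internal-node split, flagged in-situ when the node
and both daughters share one range.  Multi-area ranges act as single
composite states.  Counting is per branch: at most one transition per
branch, because only branch endpoints are observable in a reconstruction.

Transitions are dated at the branch midpoint by default (unbiased under a
uniform prior on the change time); `transition_dating="child"` dates them at
the younger node instead.  The midpoint convention errs by up to half the
branch length, which matters when rate episodes are narrower than typical
branches (see the burst-detection note below).

Sliding-window rates use contiguous windows of width 0.1 Myr (100,000
years) stepping from an old edge t_max toward t_min, half-open on the young
side.  The value of a window is

    events in window / lineages at the window's old edge / width

i.e. events per lineage ("per branch") per Myr, with the lineage count
taken at the window's old edge under the half-open crossing convention
(a branch is counted where parent age > t ≥ child age).  Windows with zero
lineages and zero events keep value 0; a zero-lineage window that contains
events (possible only at the root age, e.g. the root's origination) is
dropped with a logged warning.  By construction
Σ value·width·lineages = total events in the retained windows, an exact
conservation law asserted in the test suite.

Period averages are the arithmetic mean of window values whose old edges
fall inside the period (half-open, old side included); a pooled alternative
(total events / total lineage-time) is available via `pooled=True`.

Plotted series replace windows with symmetric triangular cones of base
width 0.2 Myr (twice the window), one per event, each integrating to
1/(lineages at the event time), so the curve's integral equals the summed
per-lineage event weight.

Lineage-through-time curves are right-continuous step functions on node
ages, starting at 2 just younger than the (clade) root and ending at the
clade's tip count, with optional truncation at a young cutoff.

## Synthetic data

The generator provides ground truth at two levels.

**Trees** come from a constant- or epoch-rate birth–death process.
Tip-count conditioning runs the process from the crown until the birth that
would exceed the target; that birth's time becomes the present, which makes
the pure-birth crown age E[T] = Σ_{j=2..n} 1/(jλ) exactly.  Crown-age
conditioning runs for a fixed span, requires both crown lineages to
survive, and prunes extinct subtrees.  Epoch-varying speciation rates (a
`birth_epochs` table, simulated exactly by thinning) are only available
under crown-age conditioning, since epoch boundaries are ages and the
present must be known in advance.

**Ranges** evolve by exact Gillespie simulation along branches: area a is
gained at rate gain · (epoch dispersal multiplier) while |S| < max_areas
and lost at rate loss unless it is the last area — empty ranges are
impossible by construction rather than by rejection, which keeps
exposure-time accounting simple.  Every gain/loss event's exact time is
recorded, so dating conventions can be tested against truth.

**Calibration data** for the MCMC are simulated directly under the
inference model: each area draws a gamma category uniformly and evolves as
an independent binary chain with rates βπ₁r / βπ₀r from a Bernoulli(π₁)
root.  These matrices may contain all-absent tips; the matrix-level entry
point `run_bbm_mcmc_matrix` accepts them so calibration is unbiased, while
the public coding-based API enforces non-empty observed ranges.

### The two-burst profile

`two_burst_profile()` emulates the study conditions this package targets: a
10.5-Myr crown, ten areas, ~190 extant tips (crown-age conditioning with an
acceptance band of [n/2, 2n]), tip ranges of 1–3 areas, and two epochs —
6.6–5.8 and 4.7–3.1 mya — in which speciation is elevated six-fold and
per-area dispersal twenty-fold over a baseline gain of 0.01 and loss of
0.4 per Myr.  The multipliers mirror the order-of-magnitude contrast
between burst and lull per-lineage rates reported for continental
radiations with episodic dispersal (~1.8 vs ~0.1 transitions per lineage
per Myr); the joint elevation matters, because in such systems lineage
generation and dispersal spike together.

A constant-rate tree with dispersal-only bursts is *not* a detectable
emulation at this scale: with ~2-Myr branches early in the tree,
midpoint-dated endpoint differences smear a 0.8-Myr episode by up to half a
branch length, and the observable burst/flank contrast saturates near 1.5
regardless of how strong the dispersal multiplier is.  With joint bursts,
splits closely follow dispersal, and the child-node dating convention
places transitions in their episodes; burst-epoch window means then exceed
the flanking lull (5.8–4.7) and post-burst (3.1–2.0) means by a factor of
~3–14.  Burst analyses in this package therefore use child dating; the
pipeline default elsewhere remains the midpoint.

## What the simulations do and do not show

The generator reproduces the features the statistics depend on — tree
scale, range sizes, episodic rates, exact event times — but not features of
real data such as phylogenetic and dating uncertainty, area delimitation
error, range-coding thresholds (the 10%-of-range presence rule applied
upstream), extinct-range history (only extant tips are emitted), or
state-dependent diversification.  Passing tests demonstrate internal
correctness and recoverability under the model's own assumptions, not
robustness to violations of them.

## Numerical choices and degenerate inputs

- Ultrametricity tolerance: max |tip age| ≤ 1e-6 × root age; tip ages are
  then snapped to exactly 0 so boundary conventions are exact.
- Polytomies are rejected, not resolved: event counting assumes one new
  lineage per split.
- Partial likelihoods are rescaled per node by their maximum (log scale
  accumulated), so 200-tip × 10-area runs stay in range.
- Window boundaries share exact floating-point values
  (t_max − i·width), so an event on a boundary is counted exactly once.
- Degenerate codings (all tips identical, or fewer than two observed
  areas) are rejected — there is no signal to reconstruct.
- Missing or ambiguous tip states are unsupported; every tip must be coded.

## Problem sizes in the test and acceptance runs

Oracle-equivalence tests enumerate all internal-state combinations on trees
of ≤ 6 tips (hundreds of random cases).  MCMC calibration uses 100-tip
trees with reduced chains (2 chains of a few thousand generations, a
scaled-down analogue of the 10 × 100,000 default) across 20 seeded
replicates; burst detection uses 50 replicates of the two-burst profile;
the acceptance script runs one full pipeline replicate at the profile's
scale.  These sizes are the package's own choices for routine verification;
all constants are ordinary function arguments, so larger runs are a
one-line change.
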