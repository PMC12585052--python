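# bbmrange

Bayesian binary ancestral range reconstruction and sliding-window
biogeographic rate estimation on time-calibrated phylogenies.

`bbmrange` is aimed at historical biogeographers who have (1) an
ultrametric chronogram (newick or NEXUS, branch lengths in Myr) and (2) a
table coding each species into one or more of up to ten single-letter
geographic areas, and who want to ask *where* ancestral lineages lived and
*when* between-region transitions and in-situ lineage originations were
concentrated — the kind of question raised by continental radiations with
episodic waves of dispersal and diversification.

## The model in brief

Presence in each area is an independent binary character under a two-state
F81 process with stationary presence frequency π₁ and normalizer
β = 1/(2π₀π₁), giving transition probabilities
P_ij(t) = π_j + (δ_ij − π_j)·e^(−βrt), with discrete-gamma (+G, shape α,
k = 4 categories, mean 1) rate variation across areas.  A
Metropolis–Hastings sampler (by default ten chains of 100,000 generations,
20,000 burn-in, sampling every 100 — 8,000 pooled samples) integrates over
(π₁, α); per-node presence posteriors are Rao-Blackwellized over the
samples and composed, under independence, into posteriors over ranges of at
most `max_areas` (default 3) areas.  Each node's MAP range then yields:

- **transition events** — branches whose endpoint ranges differ — and
- **origination events** — splits, in-situ when parent and daughters agree —

which are binned into contiguous 0.1-Myr windows and normalized as
*events per lineage per Myr* (lineages counted at each window's old edge),
plus triangular-cone plotted series (0.2-Myr base), period averages and
lineage-through-time curves.  A birth–death + Gillespie range-evolution
simulator with exact event times provides ground truth for every statistic.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from bbmrange import *

# ground-truth world: 40 extant species in 10 areas, with an 8-fold
# dispersal burst between 3.5 and 2.5 mya
cfg = SimConfig(birth=0.6, death=0.05, n_tips=40, seed=11, gain=0.05, loss=0.4,
                epochs=((3.5, 2.5, 8.0),))
chron = simulate_bd_tree(cfg)
coding, truth = simulate_range_evolution(chron, cfg)
print(f"simulated {chron.n_tips} tips, crown age {chron.root_age:.2f} Myr")

bbm_cfg = BBMConfig(generations=2000, burnin=500, samplefreq=10, chains=2,
                    max_areas=3, seed=1)
result = run_bbm_mcmc(chron, coding, bbm_cfg, cfg.alphabet)
print(f"pooled {len(result.samples)} samples; "
      f"pi1 = {result.samples.pi1.mean():.3f} +/- {result.samples.pi1.std():.3f}, "
      f"alpha = {result.samples.alpha.mean():.2f} +/- {result.samples.alpha.std():.2f}")

maps = result.map_ranges()
internal = [v for v in range(chron.n_nodes) if not chron.is_tip(v)]
acc = np.mean([maps[v] == truth.node_ranges[v] for v in internal])
print(f"MAP ranges match the simulated truth at {100*acc:.0f}% of internal nodes")

events = extract_events(chron, maps, transition_dating="child")
series = sliding_window_rates(events, chron, "transition", width=0.1,
                              t_max=0.99 * chron.root_age)
print(f"{int(series.counts.sum())} transitions in the analysis span; "
      f"mean rate in 3.5-2.5 mya: {period_mean_rate(series, 3.5, 2.5):.2f} "
      f"vs 2.5-1.5 mya: {period_mean_rate(series, 2.5, 1.5):.2f} per lineage per Myr")
```

prints

```
simulated 40 tips, crown age 4.50 Myr
pooled 300 samples; pi1 = 0.276 +/- 0.073, alpha = 0.23 +/- 0.12
MAP ranges match the simulated truth at 67% of internal nodes
15 transitions in the analysis span; mean rate in 3.5-2.5 mya: 0.39 vs 2.5-1.5 mya: 0.00 per lineage per Myr
```

π₁ ≈ 0.28 reflects that most species occupy few of the ten areas; the MAP
reconstruction recovers two-thirds of ancestral ranges in this short demo
run despite the deliberately strong dispersal burst; and the windowed
transition rate localizes that burst: ~0.39 transitions per lineage per Myr
inside 3.5–2.5 mya versus none in the Myr after it.

## Command line

The same pipeline is scriptable from the shell; all randomness flows
through one seed, and every table carries the config hash in its header:

```sh
bbmrange simulate    --out fixture --seed 3 --tips 190   # tree + codings + truth
bbmrange reconstruct --config run.yaml                   # MCMC -> posteriors + annotated tree
bbmrange rates       --annotated-tree out/annotated.nwk --config run.yaml
bbmrange ltt         --tree fixture/tree.nwk --out out
```

`run.yaml` names the tree, codings, output directory, the MCMC block
(generations, burnin, samplefreq, chains, max_areas, seed) and the rate
block (window/cone widths, analysis span, named periods, clades).

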