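# Methods

`scratchabc` estimates two macroscopic parameters of collective cell
spreading — the cell diffusivity *D* (μm² h⁻¹) and the per-capita
proliferation rate *λ* (h⁻¹) — from a handful of snapshots of a scratch
(wound-healing) assay, without ever evaluating a likelihood.  This note
records the model, the numerical choices, and what the package's own tests
do and do not establish.

## The forward model

The cell population is represented as an exclusion process on an *X* × *Y*
square lattice with spacing Δ equal to one cell diameter (default 25 μm);
each site holds at most one agent.  During a timestep of duration τ
(default 1/24 h):

1. **Motility sweep** — *N(t)* agents are selected uniformly with
   replacement; each selected agent moves with probability *P*ₘ to one of
   its four nearest-neighbour sites chosen uniformly.  A move whose target
   is occupied or outside the domain is aborted (volume exclusion;
   zero-flux boundaries realized as aborted events, the standard
   convention for exclusion processes).
2. **Proliferation sweep** — a further *N(t)* selections with replacement
   from the pool frozen at sweep start; each selected agent places a
   daughter on a uniformly chosen neighbour with probability *P*ₚ, aborted
   on occupied or off-domain targets.  Daughters born mid-sweep are not
   selectable until the next timestep; freezing the pool fixes the number
   of attempts at *N(t)* and makes the sweep order-insensitive in
   expectation.

There is no death mechanism, so *N* is non-decreasing.  Agents start
uniformly at random (without overlap) in the band *y* ≤ *Y₀*, mimicking the
cell-bearing side of a freshly scratched monolayer; the x axis runs
parallel to the scratch.

The per-step probabilities are interchangeable with the continuum rates
through the standard lattice-to-continuum relations

D = *P*ₘ Δ²/(4τ)  λ = *P*ₚ/τ,

which at the package defaults give the reference pairs
(*P*ₘ, *P*ₚ) = (0.25, 2×10⁻³) ⇔ (D, λ) = (937.5 μm² h⁻¹, 4.8×10⁻² h⁻¹)
and (0.36, 1.04×10⁻³) ⇔ (1350 μm² h⁻¹, 2.5×10⁻² h⁻¹).

**RNG.** The simulation kernel uses an inline xorshift64\* stream, seeded
from the configuration seed through a splitmix64 finalizer; one stream per
realization, consumed in a documented order (selection index, event
Bernoulli, then direction only when the event fires).  This keeps a full
10⁴-proposal inference chain within minutes on one core while remaining
bit-reproducible.  A completely full lattice is advanced without drawing
random numbers: no motility or proliferation event can succeed there, so
the skip is exact.

## Summary statistics

Snapshots are reduced before comparison:

- **c(i)** — the number of unordered pairs of occupied sites in the same
  column separated by *i* rows, *i* = 1 … *Y*−1.  Only the direction
  perpendicular to the scratch is counted: that is where the spreading
  front carries signal.
- **ĉ(i) = X (Y−i) · N(N−1) / (XY (XY−1))** — the expected counts under
  uniform random placement of *N* agents without overlap: the number of
  same-column site pairs at separation *i* times the probability that both
  sites of a pair are occupied.  This normalization is pinned by two
  oracles in the test suite: a ≥10⁵-replicate Monte-Carlo placement mean,
  and the identity q ≡ 1 on a fully occupied lattice.
- **q(i) = c(i)/ĉ(i)** — the pair correlation function; q > 1 means pairs
  at that separation are over-represented relative to spatial randomness
  (freshly divided cells push q(1) up; motility relaxes it back toward 1).

Distances between observed and simulated summaries are per-time-point
values averaged over the observation times (default 4, 8, 12 h — three
snapshots, the package's deliberate subsampling of a continuously imaged
assay):

- d[q] = mean over *i* of |q_obs − q_sim|;
- d[c] = mean over *i* of |c_obs − c_sim|, divided by max(1, mean_i c_obs)
  so that the statistic is scale-free;
- d[N] = |N_obs − N_sim| / N_obs;
- d[K] = (d[q] + d[N]) / 2 — the combined statistic.

All normalizations use the observed side, so distances are deliberately
asymmetric in their arguments.  The mean-absolute-difference forms were
chosen so that d[q] and d[N] are both dimensionless and O(1) for plausible
mismatches — a plain average of the two (the statistic K) is only
meaningful if its parts share a scale.

Centroid tables (μm) are discretized by assigning each point to the
nearest site centre ((x−½)Δ, (y−½)Δ).  Exclusion is enforced
deterministically: points are processed in input order and a displaced
point goes to the vacant site nearest its own continuous position (ties to
smaller x, then smaller y).  Collisions are rare when Δ is at most one
cell diameter.

## ABC-MCMC

The posterior over θ = (*P*ₘ, *P*ₚ) under a uniform prior on [0,1]² is
approximated by accepting θ whenever one fresh simulator realization at θ
lies within a tolerance ε of the observed summaries.  A Metropolis random
walk with component-wise uniform increments on [−Γₘ, Γₘ] × [−Γₚ, Γₚ]
(defaults Γ = (10⁻¹, 10⁻³)) keeps proposals in the region that already
matched; out-of-box proposals are rejected outright (prior ratio zero).
Uniform increments are the minimal symmetric reading of a "step width" and
keep the sampler valid.  One realization per proposal — the same
single-realization protocol that generates the synthetic observations.  No
burn-in is discarded by default (configurable); all M states, repeats
included, constitute the sample.

The starting point comes from plain rejection sampling against the prior.
When a good region is already known (tolerance descent, production chain
after tuning), the search is warm-started by drawing candidate starts from
the proposal kernel around the supplied state; the start must still pass
the distance test, so the warm start changes only the cost, not the
admissible set.

**Choosing ε.** The tolerance is the method's main tuning knob.  The
package sets it in two stages:

1. a prior-predictive pilot (default 100 draws) fixes the overall scale as
   a low quantile (default 2%) of the distance distribution;
2. a descent schedule (default factors 1, ½, …, 1/32 of that scale) runs a
   short pilot chain (600 proposals) at each candidate and accepts the
   largest ε whose coarse-grid (20 × 20) posterior is within total
   variation 0.05 of the next-smaller candidate's.  Pilot chains share one
   seed (common random numbers), so two thresholds that accept identical
   proposal sets compare as exactly equal.  Candidates below the
   attainable distance floor (no start found, or acceptance below 1%) are
   infeasible; if no stable pair exists the smallest feasible candidate is
   used and the diagnostics carry a warning flag.  In practice, short
   pilot chains are too autocorrelated for the TV criterion to settle, so
   the procedure usually lands on the smallest feasible threshold — the
   conservative end of "the posterior stopped changing".  The acceptance
   rate of every run is logged, as the practical tuning proxy.

**Posterior summaries.**  The chain is binned on an equally spaced grid
over the unit box (default 100 × 10⁴ cells for *P*ₘ × *P*ₚ); marginals are
row/column sums.  Point estimates are the marginal mean and the modal cell
(ties toward the smaller value); the credible interval grows symmetrically
about the mode one cell per side, clipped at the box edge, until it holds
the target mass (default 90%).  The Kullback–Leibler divergence from the
uniform prior, D_KL(f‖π) = Σ f log(f/π) in natural log with 0·log 0 = 0,
measures the information gained by the data and is used to compare
summary statistics.  Reduced-length desk chains are discretized on coarser
grids (20 × 200 for ranking) because a sparse 10⁶-cell histogram of a
10⁴-state chain inflates D_KL; the default grid is kept for full-scale
runs.

**Ranking statistics.**  `rank_statistics` runs the full pipeline (pilot,
schedule, chain) for each statistic on R independently generated
observations at the same true θ, averages the posterior histograms per
statistic, and reports D_KL of each average.  Each statistic descends to
its own attainable tolerance — the same stability criterion applied
uniformly — so the comparison measures how much information each summary
can extract, not how a shared arbitrary threshold happens to treat it.

## Synthetic observations and the experiment-shaped fixture

The generator produces a single stochastic realization at known θ,
summarized at 4, 8, 12 h, on the reference geometry: a 900 × 675 μm field
(X = 36, Y = 27 at Δ = 25 μm), initial band Y₀ = 10, with N(0) = 100 for
the synthetic-recovery protocol and N(0) = 102 with θ drawn near
(*P*ₘ, *P*ₚ) = (0.36, 1.04×10⁻³) — the rates a 3T3-fibroblast scratch
assay typically yields — for the experiment-shaped stand-in.  Every
fixture is regenerable bit for bit from its (θ, config, seed) manifest.

What the generator does *not* emulate: segmentation error in locating
cell centroids, cell-size heterogeneity (one lattice site is one average
cell diameter), cell–cell adhesion, directed motility cues, and any
3-D structure.  Passing the recovery tests therefore shows that the
inference machinery is self-consistent at realistic data sizes — it does
not validate the exclusion process as a model of any particular cell line,
and parameter estimates from real coordinate tables inherit all the usual
caveats of the lattice idealization.

## Problem sizes and numerical tolerances

Desk-scale defaults used by the heavy tests: chains of M = 10⁴ proposals
(tuning pilots of 600), 3 replicates for the ranking comparison, recovery
mode estimates on a 10 × 2000 grid.  The grid is asymmetric on purpose: a
10⁴-proposal chain resolves the broad *P*ₘ plateau only to about 0.1, so
*P*ₘ cells are 0.1 wide (a finer argmax just reports chain noise), while
the sharply peaked *P*ₚ marginal supports 5×10⁻⁴-wide cells, fine enough
to place its mode within a factor-four band around 2×10⁻³.  Monte-Carlo
oracles use ≥10⁴–10⁵ replicates with 3–4 standard-error bands; the
mean-field growth oracle carries an extra 1% allowance for parent–daughter
crowding, which it ignores by construction.  Conversions, pair counting,
KL closed forms and interval routines are deterministic and tested
exactly (to floating-point round-off).

## Known limitations

- The supplementary material that fixed the original experiment's exact
  distance definitions and ε values is not available; the forms above are
  declared choices, so absolute ε values and absolute D_KL values are not
  comparable across implementations — only within-package comparisons
  (orderings, stability) are meaningful.
- Mode-based summaries of short chains on fine grids are noisy; use the
  coarser grids for M ≪ 10⁶.
- The sampler is a single chain; no cross-chain convergence diagnostics
  beyond the logged acceptance rate are provided.
- ABC posteriors are conditional on the chosen summary statistic; K is the
  package default because it ranks highest in information gain, not
  because it is sufficient.
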