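# scratchabc

Likelihood-free estimation of **cell diffusivity** *D* (μm² h⁻¹) and
**proliferation rate** *λ* (h⁻¹) from a few snapshots of a scratch
(wound-healing) assay.

A scratch assay scrapes a gap into a confluent cell monolayer and images
the repopulating front.  `scratchabc` interprets such snapshots with a
lattice exclusion process: agents on an *X* × *Y* square lattice (spacing
Δ = one cell diameter) move to a random nearest-neighbour site with
probability *P*ₘ per timestep τ and place a daughter there with
probability *P*ₚ, with events aborted when the target site is occupied or
outside the domain.  The per-step probabilities are interchangeable with
the continuum rates:

    D = Pm · Δ² / (4τ)        λ = Pp / τ

The likelihood of a snapshot sequence under this model is intractable, so
the posterior over (*P*ₘ, *P*ₚ) is sampled by **ABC-MCMC**: a random-walk
proposal is accepted when one fresh simulation at the proposed parameters
reproduces the observed summary statistics to within a tolerance ε.
Snapshots are summarized by column-wise pair counts *c(i)*, the pair
correlation function *q(i) = c(i)/ĉ(i)* (normalized against uniform random
placement), the cell count *N*, or the combined statistic
*K = (d[q] + d[N])/2* — the package default, because it carries both the
spatial structure and the population growth.  Posterior quality across
statistics is compared by the Kullback–Leibler divergence from the uniform
prior.  See `docs/methods.md` for the full model and numerical choices.

Intended users: quantitative cell biologists and modellers who have
centroid tables (or can simulate them) and want parameter estimates *with
credible intervals* instead of point fits.

## Worked example

Generate a synthetic observation at known parameters
(*P*ₘ, *P*ₚ) = (0.25, 2×10⁻³) — i.e. (D, λ) = (937.5 μm² h⁻¹,
4.8×10⁻² h⁻¹) — on the reference geometry (36 × 27 sites, initial band
Y₀ = 10, N(0) = 100, snapshots at 4, 8, 12 h), then fit it:

```python
from scratchabc import (
    make_synthetic_observation, paper_style_sim_config, ScratchAssayABC,
)

fix = make_synthetic_observation((0.25, 2e-3), paper_style_sim_config(N0=100), seed=7)
print("N per time:", fix.summaries.N.tolist())

model = ScratchAssayABC(fix.summaries, fix.sim_config, statistic="K", M=10_000)
res = model.fit(seed=1)        # tunes epsilon, runs the chain (~1 min)
print(res.summary())
```

Output (verbatim):

```
N per time: [116, 134, 152]
ABC-MCMC posterior for the lattice exclusion process
============================================================
statistic: K    epsilon: 0.128981
chain length M: 10000    acceptance rate: 0.506
proposal half-widths Gamma: (0.1, 0.001)
lattice: 36 x 27 (delta = 25.0 um, tau = 0.0416667 h)
observation times (h): [4.0, 8.0, 12.0]
------------------------------------------------------------
                   mean    mode   ci_lo   ci_hi
Pm             0.202204   0.145   0.005   0.355
Pp           0.00219583 0.00205 0.00105 0.00305
D_um2_per_h     758.265  543.75   18.75 1331.25
lambda_per_h  0.0526999  0.0492  0.0252  0.0732
------------------------------------------------------------
credible level: 90% (interval symmetric about the mode)
```

Reading it: the cell count grew 116 → 152 over 8 h, and the posterior
pins the proliferation probability tightly — *P*ₚ mean 2.2×10⁻³ against a
true 2×10⁻³, a 90% interval of (1.05–3.05)×10⁻³.  The motility
probability is only weakly identified by three snapshots and a
10⁴-proposal chain: its posterior is a broad plateau whose mean (0.20)
sits below the true 0.25 — the known small-sample bias of comparing noisy
pair-correlation summaries — but the true value lies well inside the 90%
interval.  The last two rows restate both parameters in physical units
via the conversion above.

From the shell, the same analysis is:

```sh
scratchabc fixtures make-synthetic --pm 0.25 --pp 0.002 --seed 7 --out fix/
scratchabc infer --summaries fix/ --seed 1 --m 10000 --out results/
```

Other entry points: `scratchabc simulate` (raw realizations),
`scratchabc summarize` (centroid CSV → pair statistics),
`scratchabc epsilon-tune` (tolerance diagnostics), `scratchabc rank`
(compare summary statistics by information gain), `scratchabc pipeline`
(YAML-driven end-to-end run).

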