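# dilusim

A simulator for microbial communities competing for nutrients under a
serial-dilution protocol, built to study how two kinds of metabolic
flexibility — regulatory enzyme switching within a lifetime, and
strategy-randomizing mutation across generations — reshape community
diversity.

## Who this is for

Theoretical ecologists and systems biologists working with
consumer-resource models of batch-culture ("passaging") experiments, where
nutrients arrive as a bolus, are consumed to exhaustion, and a fixed
inoculum is carried into the next batch.

## The model

Each batch starts with total nutrient c₀ split over p nutrients and total
biomass ρ₀ split over m species. Species σ carries a strategy vector α⃗_σ of
maximum uptake rates constrained to a common enzyme budget E = Σᵢ α_σ,ᵢ = 1,
and grows by Monod uptake j_σ,ᵢ = cᵢ/(K + cᵢ) · α_σ,ᵢ:

    dcᵢ/dt = − Σ_σ ρ_σ j_σ,ᵢ,        dρ_σ/dt = ρ_σ Σᵢ j_σ,ᵢ.

When the nutrients are exhausted, the end-of-batch composition is rescaled
to ρ₀ and the cycle repeats. A serial steady state is a whole batch
timecourse that maps the inoculum onto itself. In the small-bolus
(chemostat-like) limit, any number of species coexist as long as the convex
hull of their strategies contains the supply composition.

On top of this deterministic core the package provides:

* **An adapter species** (`dilusim.adapter`): senses the relative nutrient
  difference Δ = |c₁−c₂|/max(c₁,c₂) and, when Δ exceeds its tolerance Δc,
  redirects enzyme production to the more abundant nutrient, with enzyme
  dynamics dα_i/dt = (P_i − α_i) Σ j that conserve the budget. Includes the
  invasion protocol (steady community, replace a biomass fraction with an
  adapter, classify TAKEOVER / LOCKED_COEXISTENCE / UNRESOLVED).
* **Stochastic mutation-selection dynamics** (`dilusim.stochastic`): an
  exact Gillespie birth process on discrete cells in which each division
  consumes one nutrient unit and, with probability ν, produces a daughter
  with a strategy drawn uniformly from a grid of evenly spaced strategies;
  batches are linked by exact-ρ₀ multinomial bottlenecks.
* **A drift-diffusion solver** (`dilusim.fokker_planck`): the density
  P(x₁, ρ) of the two-type relative abundance evolves in the
  total-population coordinate with diffusion D = (1−ν)x₁(1−x₁)/(ρ+1)²
  (demographic noise) and drift V = ν(1−2x₁)/(ρ+1) (mutational pull toward
  x₁ = 0.5), solved by a conservative finite-volume scheme, with a built-in
  cross-check against the microscopic two-label birth process.
* **Diversity statistics** (`dilusim.metrics`): Shannon diversity
  S = −Σ P_σ ln P_σ, effective species number mₑ = e^S, rank-abundance
  curves, and extant-strategy counts.

## Worked example

```python
import numpy as np
import dilusim as ds

community = ds.CommunityState.from_strategies(
    ds.equally_spaced_community(21), np.full(21, 1 / 21)
)
config = ds.BatchConfig(c0=1.0, nutrient_fractions=[0.7, 0.3], rho0=1.0, K=1.0)
table, steady = ds.run_serial(community, config, max_batches=100, ss_tol=1e-4)
print(steady)                      # 37
print(round(table.iloc[-1, -1], 4))  # 0.133
print(round(ds.effective_species(table.iloc[-1].to_numpy()), 2))  # 15.97
```

A 21-species community with equally spaced strategies under a 70/30 supply
settles into its serial steady state (successive inoculum fractions within
L1 < 1e-4) at batch 37; the nutrient-1 specialist ends up the most abundant
(13.3% of the inoculum), and the community retains an effective species
number of ≈16.

The same machinery drives the drift-diffusion solver from the shell:

```sh
$ dilusim --out-dir out fokker-planck --nu 0.5 --rho-start 10 --rho-end 10000
final variance: 3.88228e-05 (rho=10000)
```

Starting from a narrow density at x₁ = 0.5 with variance 4.0e-4, demographic
noise first spreads the distribution (variance peaks at 5.6e-3 near ρ ≈ 20)
before mutation re-concentrates it fourteen-fold below its starting width —
the "rich-get-poorer" effect in miniature.

Other subcommands: `simulate` (deterministic serial runs from a YAML/JSON
config), `invade` (adapter invasions), `mutate` (stochastic
mutation-selection runs), `metrics` (diversity summary of a fractions CSV).

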