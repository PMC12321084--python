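# Methods

This note records the model assumptions, the numerical choices behind each
solver, the design decisions taken where the problem was genuinely open, and
what the test conditions do and do not demonstrate.

## Serial-dilution batch dynamics

Within a batch, m species grow on p nutrients by Monod uptake
j_σ,ᵢ = cᵢ/(K + cᵢ)·α_σ,ᵢ with a single shared half-saturation K, unit
biomass yield, and a common enzyme budget E = Σᵢ α_σ,ᵢ = 1. The within-batch
equations conserve Σᵢcᵢ + Σ_σρ_σ exactly, so end-of-batch biomass equals
ρ₀ + (c₀ − residual).

**Depletion.** "Nutrients exhausted" cannot mean cᵢ = 0 for Monod kinetics
(concentrations decay exponentially but never vanish), so a batch ends when
Σᵢcᵢ < `depletion_tol`·c₀, with `depletion_tol = 1e-6` by default. The
residual is discarded at dilution. This tolerance caps the per-batch mass
defect at 1e-6·c₀.

**Integrator.** LSODA via `scipy.integrate.solve_ivp` with rtol 1e-8 and
atol 1e-10, with the depletion condition as a terminal event. The tight
tolerances matter because invasion experiments integrate thousands of
batches and per-batch error compounds into the emergent takeover timescale.
The adaptive integrator is validated against a fixed-step forward-Euler
oracle (dt = 1e-4, same termination rule) to 1e-3 relative on end
abundances.

**Steady state.** A serial steady state is detected when the L1 distance
between successive start-of-batch fraction vectors drops below `ss_tol`
(default 1e-8). Relaxation is geometric (about ×0.82 per batch for the
21-species reference community), so the reported batch count depends on the
tolerance: the reference community is visually settled (L1 ≈ 2e-2) near
batch 10 and reaches L1 < 1e-4 at batch 37.

**No extinction cutoff.** Deterministic abundances may decay exponentially
without being zeroed; the slow decline of the residents is exactly what sets
the adapter's emergent timescale. An optional cutoff is deliberately absent
from the default pipeline.

**Convex hull.** Containment of the supply point in the strategy hull is
tested on budget-normalized strategies with a closed-hull boundary tolerance
of 1e-9; p = 2 reduces to an interval test, general p uses a feasibility LP.

## The adapter

The adapter's enzyme levels obey dα_i/dt = (P_i − α_i)·Σᵢ' j_i', with P the
one-hot production indicator: each unit of newly grown biomass carries newly
produced enzyme, all of the currently selected type, while growth dilutes
the existing pool. Σα therefore relaxes to the common budget E = 1 and stays
there — the adapter's advantage over fixed strategies is one of timing, not
of budget. The sensing rule switches P to the more abundant nutrient
whenever Δ = |c₁−c₂|/max(c₁,c₂) strictly exceeds Δc.

**Switching numerics.** P is piecewise constant, so the batch is integrated
segment by segment with terminal events. While producing enzyme i the event
function is c_other·(1−Δc) − c_i (rising crossing), which is algebraically
equivalent to "Δ > Δc and the other nutrient is more abundant"; this form
resolves the strict inequality exactly at the crossing and cannot re-fire
immediately after the switch. The rule is also applied once at every batch
start, since the fresh bolus can exceed the threshold outright. A safety cap
of 1000 switches per batch guards against chattering at Δc ≈ 0.

**Uninitialized production.** Before the adapter has ever sensed a
supra-threshold difference, production is constitutive — proportional to the
current enzyme levels — so dα/dt = 0 and the adapter is exactly equivalent
to a fixed-strategy species. (The alternative, producing nothing, would let
the enzyme pool decay by dilution and make a never-triggered adapter die
out, which contradicts the requirement that an adapter with an unreachable
threshold behave as a plain resident.) Carried enzyme levels and production
state persist across batch boundaries.

**Invasion protocol.** Residents (21 equally spaced strategies by default)
are run to steady state, then an `invasion_fraction` (default 0.35) of the
inoculum biomass is replaced by an adapter with α = (0.5, 0.5). Outcomes:
TAKEOVER when the adapter's inoculum fraction reaches `takeover_threshold`
(0.5); LOCKED_COEXISTENCE when `lock_window` (50) consecutive batches show
zero production switches and steady fractions; UNRESOLVED otherwise. Because
the invasion starts at 0.35, the 0.5 crossing happens early (batch ≈ 128 in
the reference run); the emergent transition is better characterized by the
dominance batch (fraction ≥ 0.95, batch ≈ 700), which is insensitive to the
dominance cut anywhere in 0.9–0.99.

**Sequential consumption.** An adapter monoculture at saturating bolus
consumes the nutrients largely in sequence, but not perfectly so: with a
2% sensing threshold the production switch fires as soon as the abundant
nutrient undershoots the other by 2%, after which the leftover of nutrient 1
is co-consumed with nutrient 2. At c₀/K = 100 with a 70/30 split, about 72%
of nutrient 1 is consumed before 10% of nutrient 2, and ~28% of nutrient 2
has been consumed by the time nutrient 1 reaches 90% — a soft, not strict,
diauxie. This is a structural property of the switch-on-relative-difference
rule (independent of ρ₀ and of the initial enzyme state), confirmed against
an independent fixed-step integration.

## Stochastic mutation-selection engine

Cells and nutrients are discrete, in cell-mass units; one birth consumes
exactly one unit of one nutrient. The reaction scheme is a birth-only
chemical master equation: species σ is chosen with probability ∝
ρ_σ·Σᵢj_σ,ᵢ (Monod factors evaluated at the current integer nutrient
counts), the consumed nutrient with probability j_σ,ᵢ/Σᵢj_σ,ᵢ, and with
probability ν the daughter's strategy is drawn uniformly from the
201-strategy grid (σ → σ + σ′), independent of the parent. This is the
minimal scheme consistent with the stated growth and mutation rates, the
unit yield of the deterministic equations, and mutants entering as single
cells. Waiting times are exponential at the total rate; the direct
(exact) method is implemented in a numba kernel with per-event rate
refresh. Batches end when both nutrient counts reach zero, giving the exact
identity end cells = ρ₀ + c₀ cells; if the total uptake rate hits zero with
nutrient remaining (e.g., only specialists of the exhausted nutrient
survive), the batch stalls, the leftover is discarded, and an error carrying
the partial population is raised.

Inocula are exact-ρ₀ multinomial samples of the end-of-batch composition.
The default founding inoculum is monomorphic on the central (generalist)
grid strategy; under mutation-selection balance the founder is forgotten
after burn-in. Runs are bit-for-bit reproducible from (config, seed): batch
seeds and the sampling stream derive from one `SeedSequence`.

Reference parameters follow the cell-unit pairing ρ₀ = 1000 cells,
K = 1000, ν = 0.01.

## Drift-diffusion description of neutral growth

For two neutrally growing types with label-randomizing mutation, the
relative-abundance density is evolved in the total-population coordinate ρ
using the drift and diffusion coefficients quoted above, taken as given.
Discretization: cell-centered finite volume on [0, 1] (401 cells by
default), central diffusive fluxes, upwinded drift fluxes, zero-flux
boundaries (probability conserved to machine precision; the x(1−x)
prefactors make the boundary treatment mild). Explicit stepping with the
step bounded by 0.4× the diffusive and advective stability limits; the
whole ρ: 10 → 10⁴ sweep takes ~10⁴ steps. The "narrow initial distribution"
is a discretized Gaussian of sd 0.02 at x₁ = 0.5.

**A known quantitative discrepancy.** The microscopic per-birth variance of
x₁ is x₁(1−x₁)/(ρ+1)², which equals the stated D at ν = 0 — but the stated
operator form ∂_ρP = ∂ₓ(D∂ₓP) − ∂ₓ(PV) grows variance at rate
2⟨D⟩ + 2⟨xD′⟩, i.e., twice the microscopic rate near x₁ = 0.5 (the
Kramers–Moyal form would place D inside a second derivative with a factor
1/2). Consequently the cross-validation against the exact two-label birth
process (a Pólya urn at ν = 0, simulated synchronously across replicates
since event order alone fixes the composition) shows a total-variation
distance that saturates near 0.14 regardless of the starting population:
the empirical variance matches the exact urn formula to <1%, while the
solved density is √2 wider. The solver intentionally implements the
equation as stated rather than the variance-matched form; the qualitative
behavior — variance rising then falling, terminal concentration at
x₁ = 0.5 — is unaffected. `fp_vs_gillespie` bins both distributions on 20
uniform bins (empirical sampling noise in the TV estimate at 10⁴ replicates
is ≈0.03 with this binning).

## Diversity statistics

Shannon diversity is computed in nats on start-of-batch fractions, with
zero-abundance entries contributing zero, and mₑ = e^S. For stochastic runs
the reported statistics are medians over post-burn-in batches, with burn-in
defaulting to the first half of the run. Rank-abundance flatness is scored
by the Gini coefficient (0 = perfectly even); flatter curves have smaller
Gini.

## Problem sizes in the bundled checks

The automated checks run the reference 21-species community (steady state
and a 1500-batch invasion), 10 deterministic and 5 stochastic
mass-balance batches, a 500-batch chemostat-limit run at c₀/K = 1e-3,
200 stochastic replicates of the ν = 0 consistency batch at
ρ₀ = c₀ = 10⁴ cells (the supply is 70/30 — a balanced supply would make all
five end fractions identical and the check vacuous), 10⁴ replicates of the
neutral two-label process, and 20 replicates × 120 batches of the
mutation-selection engine at c₀/K ∈ {0.1, 10}. The full-scale diversity
curves at larger boluses scale the same code up; the bundled comparison is
the scaled-down version of the trend.

## What the synthetic conditions do not show

All inputs are generated by the simulator itself; there is no measurement
noise, no immigration, no death or maintenance cost, nutrient yields are
unity and equal, half-saturations are equal across nutrients, and sensing is
free for the adapter. Passing checks therefore demonstrate internal
consistency of the implemented dynamics — mass balance, stochastic↔mean-field
agreement, documented timescales — not agreement with any particular
experimental system.

## Known limitations

* Two nutrients only for the adapter and the stochastic engine; the
  deterministic core and the hull predicate accept general p.
* One adapter per community; adapters do not mutate or speciate.
* The drift-diffusion solver covers two types only and implements the
  stated coefficient forms with their factor-2 variance discrepancy (above).
* Tau-leaping is not implemented; very large boluses (≫10⁴ cells per batch)
  are slow in the exact engine.
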