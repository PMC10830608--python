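# Methods

## Model overview

`matewave` simulates a stage-structured, two-sex metapopulation spreading
through a corridor-shaped gridded landscape. One model year (one generation
for all rate reporting, since breeding is annual) runs three phases:

1. **Mating and reproduction.** Within each patch, adult females breed
   subject to the harmonic-mean mating function with harem size `h`;
   realized breeders are Bernoulli draws at `Pr = c/f`, litters are Poisson.
   In the female-only baseline every female breeds (mate finding is assumed
   perfect); in two-sex mode fecundity is doubled and offspring sex is
   Bernoulli(½), so expected daughters per mother are identical across the
   two variants and their comparison isolates mate limitation.
2. **Dispersal.** Only age-0 juveniles can emigrate (fixed probability
   0.5). Movement is a stochastic stepwise walk on the cost raster;
   settlement rules decide where the walk ends. There is no step cap:
   dispersal distance distributions are emergent outcomes of landscape
   configuration, settlement behaviour and per-step mortality.
3. **Survival and aging.** Everyone — residents and this year's settlers —
   survives with `σ = σ₀,stage · exp(−b·N_f)`, where `N_f` counts all
   females (juvenile and adult) present in the patch when survival is
   applied. Survivors age one year; age never exceeds 3.

Extinction (no patch left holding a potential breeding population — for
two-sex runs at least one individual of each sex) is absorbing, because
only newborns disperse.

### Key assumptions

- Patches are single 1-ha cells of identical quality within a run; the
  matrix is uninhabitable but traversable.
- Males are demographically free: they contribute fertilization only and do
  not enter the density term of survival, which makes female-only and
  two-sex runs directly comparable.
- The harmonic-mean mating function allows `c > m` under monogamy when the
  sexes are balanced (at `f = m`, `c = f`); "monogamy" therefore limits
  matings through the harem-size parameter of the encounter function rather
  than by strict pairing. Its consequences (mating failure driven by local
  sex-ratio imbalance) are the object of study, not an implementation
  accident.
- Generations overlap (max age 3, juveniles mature at 1).

## Parameters

| Parameter | Symbol | Default | Units / notes |
|---|---|---|---|
| Grid | — | 20 × 1000 | cells of 100 m; hard borders |
| Habitat fraction | — | 0.07 | exact count, `round(frac · n_cells)` |
| Founder rate | λ | 2.0 | zero-truncated Poisson, per sex per patch |
| Fecundity | φ | 2–4 | mean offspring/female (female-only scale) |
| Adult max survival | σ₀,adult | 0.3 | at zero density |
| Juvenile max survival | σ₀,juv | 1.0 | see below |
| Density dependence | 1/b | 2–14 | "habitat quality", females/patch |
| Emigration probability | — | 0.5 | juveniles only |
| Perceptual range | PR | 5 | cells |
| Directional persistence | DP | 3.0 | 90° turn 9× less likely than straight |
| Step mortality | — | 0.005 | per step; mean ≈ 200 steps if never settling |
| Movement costs | — | 1 / 10 | habitat / matrix |
| Settlement inflection | β_s | 0.75 | on the b·N scale |
| Settlement slope | α_s | −10 | negative ⇒ avoid crowded patches |
| Horizon | — | 50 years | 5 replicates per scenario |

σ₀ for juveniles is not a published constant; the package defaults to 1.0,
which places the single-patch quasi-equilibrium near `(1/b)·ln(0.3 + φ)`
females — of order the habitat quality 1/b itself, consistent with reading
1/b (females/patch) as patch quality. It is configurable
(`DemographyParams.sigma0_juvenile`) for sensitivity analysis, as is the
density definition used by survival.

## Movement and settlement details

**Step choice.** From its current cell a disperser evaluates the eight
neighbours; off-grid neighbours are removed (hard borders, no reflection).
The probability of stepping to neighbour `i` in direction `d` is
proportional to `DP^(−turn) / effective_cost(i, d)`, where `turn` is the
heading change in 45° units relative to the previous step (first steps have
no heading, so on homogeneous ground they are uniform). Per-step mortality
is resolved before the move; the order is irrelevant to the geometric
survival law.

**Effective cost.** The cost a disperser perceives for a candidate cell is
the arithmetic mean of per-cell costs over the cells within the perceptual
range in that direction. Two aggregations are provided: the default
`"sector"` averages every cell within Chebyshev distance PR−1 of the
candidate whose bearing falls in the 45° wedge of the direction (the
perceptual-cone semantics of stochastic movement simulators), and `"line"`
averages only the straight ray of PR cells. Both are precomputed per
landscape as a `(rows, cols, 8)` array shared by the compiled kernel and the
pure-Python reference `step`, which exists so tests can cross-check the
kernel distributionally. The choice barely moves emergent kernels here
(mean settled displacement 4.7 vs 4.4 rows for sector vs line at the
standard parameters); sector is kept as the more faithful semantics.

**Scheduling and simultaneous arrival.** All of a year's emigrants advance
one step per global tick in a freshly shuffled random order, and settlement
is evaluated the moment an individual steps onto non-natal habitat, against
up-to-the-moment occupancy (previous-year residents, natal stayers and
already-settled immigrants). At the end of each tick, any patch holding
unsettled dispersers of both sexes settles them together — this gives the
mate-search rule's "both arrive at an empty patch simultaneously" a
well-defined, order-artifact-free meaning. Emigrants may re-enter and pass
through their natal patch but can never settle in it.

**Settlement density.** The logistic settlement probability uses the
patch's current occupant count `N` on the `b·N` scale. By default `N`
counts occupants of both sexes (`density_measure="all"`), matching
settlement assessed against total patch population; a females-only variant
mirrors the survival equation's weighting. The two coincide exactly in
female-only runs. The default was fixed by behaviour-level validation
against the reference platform's published outputs: with total counts the
density-dependent kernel is 2.2× the habitat-only kernel and
density-dependent settlement lifts polygynous spread to (or above) the
female-only baseline at habitat quality ≥ 8; with females only
(occupied-patch densities sitting right at the inflection b·N ≈ 0.75) both
signatures are far too weak (ratio 1.6, spread well below baseline).

## Statistical layer

Factorial responses are analysed with OLS on categorical factors (habitat
quality, fecundity, mating system) plus all two-way interactions.
Relative importance uses the LMG measure — the R² increment of a term
averaged over entry orderings — computed by exact subset/permutation
enumeration with each factor's dummy block (or an interaction's product
block) entering as one group. Orderings are restricted to respect
marginality (an interaction never enters before its main effects), the
standard convention for models with interactions; without the restriction,
treatment-coded interaction blocks absorb main-effect variance and the
decomposition is not interpretable term-by-term. Shares are non-negative
and sum to the full-model R² (property-tested against an independent
ordering-enumeration oracle).

The occupancy model takes one year-50 core-occupancy value per run
(extinct runs contribute 0). The spread model takes the per-5-year-window
rates as its unit of analysis, so window-to-window variability lands in the
residual rather than inflating the mating-system share; overall spread
rates reported elsewhere remain per-run means of window rates. Spread
analyses include only parameter combinations where spread occurred for all
mating systems (habitat quality > 6, fecundity > 2) and runs that maintain
quasi-equilibrium occupancy.

Mating failure is modelled with a binomial GLM (logit link) on patch-level
unmated proportions — successes = unmated females, trials = females, so
patches are weighted by female count — with a mating-system ×
patch-population-size interaction and fecundity as a categorical control.
Patch population size enters untransformed as the adult count of both
sexes. Complete separation is detected (fitted probabilities at the
boundary) and flagged rather than hidden.

## Randomness and reproducibility

Every stochastic stream derives from `(master_seed, scenario_id hash,
replicate, stream name)` through numpy `SeedSequence`, so any scenario ×
replicate cell can be recomputed in isolation, bit-identically, on any
platform. Landscape generation is seeded by `(master_seed, replicate)`
only: scenarios within a replicate share one landscape realization, making
scenario contrasts paired and reducing between-scenario noise (fully
independent landscapes are available by varying the master seed). The
movement kernel runs its own compiled RNG stream seeded per cohort from
the replicate's movement stream.

## Synthetic data

The landscape generator is the model's only input source: a random corridor
with an exact habitat-cell count (so replicates differ in configuration,
never amount, of habitat) and zero-truncated-Poisson founder counts
(exactly half the core patches populated, a deterministic count). λ is
interpreted as the Poisson rate before truncation (realized mean
λ/(1−e^(−λ)) ≈ 2.31 at λ = 2); a flag switches to the
target-realized-mean interpretation. The generator emulates fragmentation
(uniform random single-cell patches in a hostile matrix) but not features
of real landscapes such as spatial aggregation of habitat, patch-size
variation, quality gradients or temporal change — so passing tests
demonstrate internal consistency of the mechanisms under the stated
conditions, not predictions for any empirical system.

## Numerical choices and problem sizes

- Exact inverse-CDF sampling for the zero-truncated Poisson (via the
  Poisson quantile function), valid at any rate.
- The tick-loop has a safety valve (10⁶ ticks) whose triggering raises a
  distinct error; mortality guarantees it is unreachable in practice.
- Per-year conservation is asserted in the engine: every emigrant is
  accounted settled or dead-in-transit, and end-of-year counts equal
  start + births − transit deaths − survival losses.
- The test-suite runs the factorials at reduced size (500-row corridor,
  40 years, 3 replicates, 30-year spread horizon — the shorter horizon
  because fast-spreading runs reach the half-length corridor's far border
  after about 35 years). Kernel measurements use the full 1000-row
  corridor, since emergent dispersal distances are the quantity of
  interest there. `scripts/acceptance.py` runs the full factorial
  (315 runs of 50 years) and full-size kernel scenarios.

## Known limitations

- **Movement is single-step correlated.** Directional persistence acts on
  the previous step's heading only. Against the reference platform's
  published emergent kernels, both the habitat-only and density-dependent
  settled-distance means come out shorter by a common factor of roughly
  0.6 (4.7 vs 8.0 rows and 10.4 vs 17.6 rows at habitat quality 10,
  fecundity 3), while every relative signature — the density-dependent to
  habitat-only ratio (2.2), the ~3% mate-search effect, spread-rate
  orderings, lag magnitudes, extinction fractions and variance shares —
  matches. A multi-step direction memory (not part of this package's
  movement contract) would straighten paths and scale both kernels
  together; the discrepancy is documented rather than compensated.
- Demography operates on patch × sex × age counts (individuals within a
  class are exchangeable), which is distributionally exact for this model
  but means individual identities exist only during dispersal.
- One landscape per replicate is shared across scenarios by design;
  scenario contrasts are paired, so between-scenario differences should be
  interpreted conditional on the shared landscapes.
- No evolution, no heterogeneous patches, no periodic boundaries, no
  sex-biased emigration, no checkpoint/restart mid-run.
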