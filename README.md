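# matewave

Two-sex individual-based metapopulation model of range expansion through
fragmented landscapes.

Many species expand their ranges more slowly than environmental change makes
new habitat available, and mate finding is one underappreciated brake: at
the sparsely occupied range edge, encounters between the sexes become rare,
females go unmated, and the expansion wave is pushed from behind rather than
pulled by edge growth (a mate-finding Allee effect). `matewave` simulates
this process for a short-lived, stage-structured species spreading through a
corridor of single-cell habitat patches, and provides the statistical layer
used to analyse factorial simulation experiments: how mating system
(female-only baseline, polygyny, obligate monogamy), habitat quality,
fecundity and dispersal-settlement behaviour jointly set metapopulation
size, spread rate and mating success from the range core to its edge.

It is aimed at spatial population ecologists who want a fast, scriptable,
fully reproducible reimplementation of this class of model — every run is
deterministic given a master seed — rather than a GUI platform.

## Model core

* **Landscape** — a 20 × 1000 grid of 1-ha cells with hard borders; 7% of
  cells are habitat, each its own patch; the rest is hostile matrix.
  Founders occupy half the patches in the first 500 rows ("core"), with
  zero-truncated-Poisson(λ = 2) counts per sex.
* **Mating** — in a patch with `f` reproductive females, `m` males and harem
  size `h` (1 = monogamy, 100 = polygyny), the expected number of matings is
  the harmonic-mean mating function

  `c = min(1, 2hm / (f + hm)) · f`,

  and each female breeds with probability `Pr = c/f` (Bernoulli), with a
  Poisson(φ) litter (φ doubled and sex ratio ½ in two-sex mode, so the
  female-only and two-sex models are directly comparable).
* **Dispersal** — juveniles emigrate with probability 0.5 and move cell to
  cell under a stochastic movement simulator: step probabilities combine
  directional persistence (DP = 3; a 90° turn is 9× less likely than going
  straight, a reversal 81×) with the inverse of the effective cost of each
  neighbouring cell (habitat cost 1, matrix 10, averaged over a perceptual
  range of 5 cells), with 0.005 per-step mortality and no step cap, so
  dispersal kernels are emergent.
* **Settlement** — four rules: settle on any non-natal habitat; only where
  an opposite-sex conspecific is present (mate search, with simultaneous
  same-tick arrivals founding pairs); with logistic probability
  `P_s = 1 / (1 + exp(−(bN − β_s)·α_s))` declining in patch density
  (negative density-dependent settlement, β_s = 0.75, α_s = −10); or both.
* **Survival** — after settlement, everyone survives with
  `σ = σ₀·exp(−b·N_f)` where `N_f` is the patch's female count and `1/b`
  (females/patch) is read as habitat quality; survivors age, and nobody
  lives past 3 years.
* **Analysis** — range edge (furthest breeding patch), spread rate (extra
  rows per 5-year window / 5), quasi-equilibrium occupancy
  (mean Δp + SE > 0 over years 20–50), 10-row neighbourhood occupancy and
  mating-failure profiles behind the edge, LMG relative-importance
  decomposition of the factorial responses, and a binomial GLM of unmated
  proportions.

## Worked example

Compare a mate-unlimited (female-only) population with a polygynous two-sex
population at habitat quality 1/b = 10 and fecundity 3 on a half-length
corridor:

```python
from matewave import SimConfig, run_simulation
from matewave.demography import DemographyParams, FEMALE_ONLY, POLYGYNOUS
from matewave.landscape import InitSpec
from matewave.metrics import spread_rate

for mating, name in ((FEMALE_ONLY, "female-only"), (POLYGYNOUS, "polygynous")):
    cfg = SimConfig(
        n_rows=500, init=InitSpec(core_rows=250),
        mating=mating,
        demography=DemographyParams(fecundity=3.0, b=0.1),  # 1/b = 10
        years=40, master_seed=1, scenario_id=f"demo_{name}",
    )
    res = run_simulation(cfg, replicate=0)
    edges = res.range_series.set_index("year").edge_row
    print(f"{name:12s} edge {edges.iloc[0]:3d} -> {edges.iloc[-1]:3d} rows, "
          f"occupancy {res.range_series.core_occupancy.iloc[-1]:.2f}, "
          f"spread {spread_rate(edges, horizon_years=30):.2f} rows/generation")
```

prints

```
female-only  edge 248 -> 499 rows, occupancy 0.94, spread 6.77 rows/generation
polygynous   edge 249 -> 367 rows, occupancy 0.88, spread 2.93 rows/generation
```

Both populations fill the core (occupancy 0.94 vs 0.88), but explicit mate
finding cuts the spread rate by more than half (2.93 vs 6.77 rows per
generation): mating failure at the sparse range edge, not demography in the
core, is what slows the advance.

The same machinery is scriptable from a shell:

```bash
matewave landscape --ncols 20 --nrows 1000 --habitat-fraction 0.07 --seed 1 --out land/
matewave run --config my_scenario.ini --replicate 0 --out out/
matewave experiment --design exp1 --out exp1/ --seed 1 --reps 5 --years 50
matewave analyze --experiment exp1 --in exp1/ --out report/
```

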