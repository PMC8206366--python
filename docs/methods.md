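# Methods

## Model

The simulator couples `N` local Lotka-Volterra competition communities through
dispersal on a random spatial network:

```
dB_ix/dt = B_ix (R_ix − Σ_j A_ij B_jx) − e B_ix + Σ_{y∈N(x)} (e/k_y) exp(−d_xy/ℓ) B_iy
```

with `k_y = Σ_{z∈N(y)} exp(−d_yz/ℓ)`. All species share the dispersal
parameters (`e`, `ℓ`); interactions are purely competitive (a single guild);
the growth-rate matrix `R` is frozen at initialisation, so any temporal
turnover in a simulation is autonomous. There is no demographic stochasticity
and no environmental forcing, by design: these are the processes the null
model deliberately excludes.

### Parameters and defaults

| parameter | meaning | default | units |
|---|---|---|---|
| `N` | number of patches | 8 (scalable) | — |
| `e` | emigration fraction | 0.01 | per unit time |
| `ℓ` | dispersal length | 0.5 | arena length |
| `φ` | environment autocorrelation length | 10 | arena length |
| `σ²` | growth-rate variance | 0.01 | (per unit time)² |
| `μ` | growth-rate mean | 1.0 | per unit time |
| connectance | P(off-diagonal interaction ≠ 0) | 0.5 | — |
| strength | value of non-zero `A_ij` | 0.5 | — |
| `ε` | propagule pressure (isolated model) | 10⁻¹⁰ | biomass per unit time |
| extinction threshold | regional removal cut-off | 10⁻⁴ | biomass |
| detection threshold | presence cut-off for richness stats | 10⁻⁴ | biomass |

The arena side is `√N`, so patch density is one per unit area for every `N`
and the dispersal scale `ℓ` retains the same meaning as the landscape grows.
Since `μ = 1`, one unit time is roughly the time an uncontested population
needs to approach carrying capacity; transitions between community states
occur on scales of tens of unit times.

### Geometry choices

The Gabriel graph uses the *closed*-disk exclusion rule: a third point lying
exactly on the circle with the candidate edge as diameter blocks the edge.
On points in general position the rule is immaterial (a measure-zero event);
in degenerate symmetric configurations (e.g. the four corners of a square) it
drops the crossing diagonals and preserves planarity. Distances are plain
Euclidean; there is no periodic boundary, and no special treatment of patches
near the arena edge. Edge candidates are restricted to the Delaunay
triangulation (the Gabriel graph is a subgraph) and the disk test uses a
k-d tree, so construction scales to thousands of patches; `D` is stored
sparse so the dynamics' matrix products scale with the number of edges, not
`N²`.

The growth-rate field is sampled through the eigendecomposition of
`Σ_xy = exp(−d_xy/φ)`. Eigenvalues in `(−10⁻¹⁰, 0)` are treated as rounding
noise and clipped to zero; anything more negative raises, since it indicates
an invalid distance matrix rather than conditioning.

## Numerical integration

The stiff BDF scheme (`scipy.integrate.solve_ivp`) integrates the flattened
system with an analytic sparse Jacobian (per-patch competition blocks plus
the constant `I_S ⊗ Dᵀ` dispersal part), `rtol = 10⁻⁸`, `atol = 10⁻¹⁰`.
Integration proceeds in 500-unit chunks; sampled values in `(−atol, 0)` are
clamped to zero and anything below −10⁻⁶ aborts the run. The vector field is
evaluated on the non-negative part of the state: a biomass that undershoots
zero by solver error feels no dynamics, which prevents a positive growth rate
from amplifying the unphysical excursion. With `ε > 0` no species ever
reaches zero; its floor abundance is `ε/|invasion deficit|`.

Equilibrium solves (`isolated_equilibrium`, `source_diversity`) integrate the
single-patch system until `max |dB/dt| < 10⁻¹⁰` *and* no excluded species
(biomass < 10⁻⁴) has a positive invasion growth rate, or a 10⁴-unit horizon
expires. The uninvadability condition matters: a trajectory lingering near an
unstable node of a heteroclinic network also has a vanishing derivative, and
the derivative criterion alone would mistake that pause for convergence.
Non-convergence is reported as a flag, not an error — it is the expected
outcome beyond the multiple-attractor transition.

## Assembly protocol

Each invasion event generates `5 × (⌊0.05·S⌋+1)` candidates (growth-rate rows
from the field law, interaction rows/columns from the Bernoulli law),
introduces them all at 10⁻⁶ biomass into every patch of a *copy* of the
resident state, simulates 10 unit times, and passes candidates whose final
biomass exceeds the initial one somewhere; the best patch is the one with the
greatest proportional growth (ties: lowest patch index). Candidate-candidate
interactions are neglected during the test (at 10⁻⁶ abundance their mutual
effects are of order 10⁻⁷ and cannot affect the pass decision); the mutual
interactions of the batch actually introduced are sampled from the standard
law so the assembled matrix keeps the one-shot statistics. If fewer
candidates pass than the batch rule requires, one regeneration round is
attempted and any remaining shortfall accepted. Residents are restored
exactly after screening. The loop stops at `max_invasions` or when the
regional-richness trend over the trailing 500 invasions flattens below 10⁻³
species per invasion. All sampling flows from one master seed through
per-stage substreams, so runs are reproducible bit-for-bit given solver
determinism.

Between invasions the dynamics run for exactly 500 unit times. Long turnover
assays (2×10⁴ unit times, second half analysed) are run on state copies at
configurable checkpoints rather than every invasion, for cost; source
diversity, which needs a per-patch equilibrium relaxation, is likewise
measured at a configurable cadence.

## Turnover statistics

Bray-Curtis matrices are computed on **raw biomasses**: the index is
abundance-based, and the 10⁻⁴ detection threshold applies only to
presence-derived statistics (richness, occupancy, STAR). Temporal matrices
subsample every 10th sample by default (a 10⁴-sample series yields a 10³×10³
matrix); a full-resolution mode exists. Cluster counts cut the
complete-linkage dendrogram at 0.25. Turnover is flagged when the mean
off-diagonal temporal Bray-Curtis exceeds 10⁻². STAR windows grow around
each focal patch by nearest-neighbour distance (ties: patch index), slide
over every admissible start time, and the exponents `z`, `w` are the maximum
successive slopes of the mean-richness curves on log₁₀-log₁₀ axes — in a
closed system both curves must saturate, so the maximum slope, not a global
fit, characterises the power-law regime.

## The isolated-community turnover threshold

The sweep (`isolated_sweep` recipe, `scripts/acceptance.py`) integrates pools
of `S ∈ {20, …, 50}` species (growth Normal(1, 0.01), Bernoulli interactions,
`ε = 10⁻¹⁰`) from independent Uniform(0, 1) initial biomasses, discards a
**200-unit burn-in**, then analyses a 10⁴-sample window. The burn-in is a few
times the single-population saturation time: it removes the relaxation from
the arbitrary initial condition, which otherwise contributes 2-3 spurious
clusters in every run regardless of `S`, while leaving genuine
attractor-level wandering observable. The reported threshold is the smallest
`S` whose three-replicate mean cluster count exceeds one.

Caveat: near the onset, finite pools still harbour occasional feasible,
uninvadable, linearly stable sub-communities, and trajectories that find one
stop turning over. We verified directly that such settled states at
`S = 35–50` are genuine (all excluded species have negative invasion rates;
the community Jacobian's spectrum is strictly stable; settling times are
unchanged under rtol 10⁻¹⁰/atol 10⁻¹⁴). Wandering for the full window is
therefore a stochastic event whose probability increases with `S`, and the
three-replicate threshold estimator is noisy: across master seeds it
typically lands between 30 and 40 species, occasionally higher. Increasing
replication tightens it, at proportional cost.

## What the synthetic conditions do and do not show

All inputs are generated internally; there is no empirical data path. The
generator reproduces the study conditions: uniform patch scatter, Gabriel
connectivity, exponential dispersal and environmental kernels, discrete
interaction distribution. It does **not** emulate trophic structure,
species-specific dispersal, temporally varying environments, demographic
noise, or speciation — so passing tests demonstrate internal consistency of
the competitive-metacommunity mechanism, not that real turnover data arise
from it. Desk-scale problem sizes are used throughout the test suite
(landscapes up to `N = 32` assembled for ~100–200 invasions, pools up to
`S = 60`, windows of 10³–10⁴ samples); the qualitative regimes (fixed points
for small `N`, oscillatory and continuous turnover as `N` or neighbourhood
richness grows) are already expressed at these sizes, while headline-scale
landscapes (`N = 256`, ~3000 species, 10⁴ invasions) require
cluster-computing budgets and are out of scope here.

## Known limitations

- The propagule-pressure term is an additive constant `ε` per species per
  unit time, the simplest form consistent with a weak biomass influx;
  floor-style alternatives give indistinguishable statistics in our checks.
- `atol = 10⁻¹⁰` equals the default `ε`, so floor abundances are resolved
  only to order unity; cluster counts are insensitive to this, but precise
  escape times from near-extinction are not meaningful at default tolerances.
- Complete-linkage cluster counts include every sampled snapshot; a single
  transition snapshot can add a cluster. Counts should be read as "states
  visited", not as a partition of time.
- The saturation stopping rule (slope of a 500-invasion trailing window) is
  heuristic; short runs should simply set `max_invasions`.
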