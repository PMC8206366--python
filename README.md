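# lvmcm

A spatially explicit **Lotka-Volterra metacommunity** simulator for studying
*autonomous compositional turnover*: change in local species composition driven
purely by ecological interactions and dispersal, with a fixed environment and
no external forcing.

The package is aimed at theoretical ecologists and macroecologists who want a
controlled null model of community time series — how much turnover should we
expect from intrinsic dynamics alone before invoking environmental change?

## Model

Local population biomasses `B_ix` (species `i`, patch `x`) follow the coupled
Lotka-Volterra competition system

```
dB/dt = B ∘ (R − A B) + B D
```

- **Landscape** — `N` patches scattered uniformly on a `√N × √N` arena (unit
  patch density for every `N`), linked by a **Gabriel graph** (mean degree ≈ 4,
  planar, contains the Euclidean MST). The dispersal operator `D` has diagonal
  `−e` (emigration fraction `e = 0.01` per unit time) and off-diagonal entries
  `e·exp(−d_xy/ℓ)/k_y` toward Gabriel neighbours, normalised so every row sums
  to zero — dispersal conserves biomass. Default dispersal length `ℓ = 0.5`.
- **Environment** — intrinsic growth rates `R_ix` are independent species-wise
  draws from a Gaussian random field with mean 1, variance `σ² = 0.01` and
  exponential spatial correlation `Σ_xy = exp(−d_xy/φ)`, `φ = 10`, sampled via
  spectral decomposition. The environment never changes during a simulation.
- **Interactions** — competition coefficients `A_ij` (i≠j) equal 0.5 with
  probability 0.5 and 0 otherwise (independent directed effects); `A_ii = 1`.
- **Assembly** — metacommunities are built by iterated regional invasion:
  `⌊0.05·S⌋+1` randomly generated species are screened for positive invasion
  growth, introduced at 10⁻⁶ biomass into their best patch, the dynamics run
  for 500 unit times, and species below 10⁻⁴ biomass everywhere are removed.
  Local richness saturates at the onset of ecological structural instability;
  regional richness saturates later through spatial differentiation.
- **Turnover statistics** — Bray-Curtis dissimilarity matrices in time and
  space, compositional cluster counts (complete-linkage, 25 % cut), temporal
  occupancy, source diversity `α_src`, neighbourhood richness, and the
  species-time-area relation (STAR) with exponents `z` and `w`.

The isolated analogue — a single Lotka-Volterra community of pool size `S`
under weak additive propagule pressure `ε` (default 10⁻¹⁰ biomass per species
per unit time) — reveals the mechanism: beyond a threshold pool size the
system has no stable saturated state and wanders along a heteroclinic network
of unstable equilibria, visiting one community composition after another.

## Worked example

Count compositional clusters for one isolated community below and one above
the turnover threshold:

```python
import numpy as np
from lvmcm import IsolatedConfig, simulate_isolated_with_pressure
from lvmcm.turnover import temporal_dissimilarity, count_clusters

for S in (20, 60):
    cfg = IsolatedConfig(S=S, epsilon=1e-10, seed=7)
    ts = simulate_isolated_with_pressure(cfg, duration=5200.0)
    keep = ts.times > 200.0  # discard the initial-condition relaxation
    D = temporal_dissimilarity(
        type(ts)(ts.tensor[:, :, keep], ts.times[keep], ts.species_ids), 0
    )
    print(S, count_clusters(D))
```

prints

```
20 1
60 4
```

the 20-species pool settles into a single community state (one cluster), while
the 60-species pool keeps turning over, visiting four distinct compositional
clusters in 5 000 unit times.

The same from the shell:

```bash
lvmcm generate --n 64 --seed 1 --out landscape/     # patches, edges, dispersal CSVs
lvmcm assemble --set N=8 --set max_invasions=200 --out run8/
lvmcm recipe isolated_sweep --set seed=1 --out sweep/
```

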