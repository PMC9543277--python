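# paranet

Tools for mapping the global complexity of brood parasite–host interaction
networks, and for asking what predicts it.

Obligate avian brood parasites (cuckoos, cowbirds, honeyguides, viduid
finches, one duck) lay their eggs in the nests of other species. The
documented parasite→host relationships form a global bipartite network, but
what a bird community actually experiences is local: within any one region,
only the interactions between co-occurring species can play out. `paranet`
discretises the world into equal-area hexagonal cells, intersects species
breeding ranges with the grid, assembles each cell's **potential network**
(the documented interactions between species co-present in that cell), and
measures its complexity, then models the geography of that complexity with
spatially explicit regressions.

## The statistics at the core

**Linkage density.** For a cell's potential network with *I* interactions
among *S* species (species incident to at least one interaction, counted
once), complexity is

    LD = I / S

A lone parasite–host pair scores the minimum, 1/2 = 0.5; two parasites and
two hosts with all four interactions score 4/4 = 1.0. Networks are also
classified as one-to-one, one-to-many, many-to-one or many-to-many by their
parasite and host node counts.

**Spatial-error SAR.** Per-cell complexity is spatially autocorrelated
(neighbouring cells share species), so alongside OLS the package implements
the maximum-likelihood simultaneous autoregressive model with the
autoregressive process in the error term:

    y = Xβ + u,   u = λWu + ε,   ε ~ N(0, σ²I)

where *W* is a row-standardised spatial weights matrix (binary neighbours
within a 200 km centroid distance band — six neighbours per interior cell on
a ~23,323 km² hexagon grid). λ is profiled out via the concentrated
log-likelihood with log|I − λW| computed from the eigenvalues of *W*; model
comparison uses the likelihood-ratio statistic against OLS (df = 1) and
Nagelkerke's pseudo-R² against an intercept-only null.

Everything is exercisable end to end on synthetic worlds: the generator
produces spatially clustered elliptical ranges with a configurable richness
gradient, long-tailed host repertoires (negative binomial, calibrated to the
documented median of 11 hosts per parasite), shared hosts across parasites,
and regression responses drawn from the error-SAR process itself.

## A worked example

```python
import numpy as np
import paranet as pn

grid = pn.build_planar_hex_grid((0, 0, 3300, 2850), 23323.0)
W = pn.distance_band_weights(grid.centroids(), 200.0)
rng = np.random.default_rng(5)
X = np.column_stack([np.ones(W.n), rng.normal(size=W.n)])
y = pn.simulate_sar_response(X, W, beta=(1.0, 2.0), lam=0.7, sigma=1.0, seed=99)

ols = pn.ols_fit(y, X)
sar = pn.sar_error_fit(y, X, W)
```

prints (see `examples/04_sar_regression.py`):

```
441 cells; interior cells have 6 neighbours within 200 km
OLS:  beta = [0.973 1.905], R2 = 0.640, F[1, 439] = 780.1
SAR:  beta = [0.987 1.959], lambda = 0.754 (true 0.7), Nagelkerke R2 = 0.779
LR vs OLS = 198.0 on df = 1
```

The SAR recovers the spatial parameter it was simulated with (λ̂ = 0.754
against a true 0.7) and improves on OLS by a likelihood ratio of 198 on one
degree of freedom — the spatial error term absorbs structure OLS would
misattribute to the covariate.

The other scripts in `examples/` walk through each capability: grid
construction and DGGS cell-size arithmetic (`01`), interaction-list
summaries — median hosts per parasite, multi-partner fractions (`02`),
per-cell potential networks and the complexity table (`03`), and the full
file-driven pipeline with its per-covariate model reports (`05`). The same
pipeline is scriptable from the shell:

```
paranet simulate --seed 7 --out-dir world/
paranet run --config run.yaml
```

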