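# Methods

## Potential networks and linkage density

The unit of analysis is a grid cell's *potential network*: the bipartite
graph whose edges are the globally documented parasite→host interactions
between species both present in the cell. "Potential" is a real caveat —
co-occurrence plus a documented interaction elsewhere does not guarantee
local parasitism — but it is the only construction available when
interaction records cannot be georeferenced to cells.

Complexity is linkage density, LD = interactions / species. Two conventions
matter and are fixed here:

- **The denominator counts only species incident to at least one edge in
  the cell.** A host that co-occurs with no documented parasite of its own
  contributes nothing. This is what makes the worked anchors come out
  right: 1/2 = 0.5, 4/4 = 1.0, 241/86 ≈ 2.8. Note that the
  bipartite-network literature also uses "linkage density" for a
  *weighted* quantity (marginal-weighted mean links per species); with
  binary potential networks the two agree only in special cases, and this
  package implements the binary ratio.
- **LD ≥ 0.5 for every non-empty network**, since each species incident to
  an edge forces S ≤ 2I. Equality holds exactly when every species has one
  partner — i.e. on perfect matchings, of which the single parasite–host
  pair is the connected case. (It is *not* true that only single-edge
  networks attain 0.5: two disjoint pairs give 2/4.)

Empty networks have no linkage density; they are reported as missing, never
as zero, and are excluded from regressions. Topology classes
(one-to-one … many-to-many) are assigned at whole-network level from the
parasite/host node counts; a per-connected-component breakdown is available
as a diagnostic (`component_topologies`) since e.g. two disjoint pairs
classify as many-to-many at network level.

Reported linkage densities are rounded to one decimal place
(`linkage_density_1dp`), and summary percentages to whole numbers; raw
values are always carried alongside.

## Grids

The load-bearing property of the grid is equal cell area, so that per-cell
richness and network size are comparable. Two tessellations are provided:

- **Planar** (km coordinates): exact regular pointy-top hexagons of side
  s = √(2A/(3√3)), in offset rows; every cell has exactly the target area
  and all six neighbours sit at centroid distance s√3 (≈164 km for
  A = 23,323 km²). Cells are kept only if they share positive area with the
  requested extent. Point-in-cell assignment uses nearest centroid, which
  for a hexagonal lattice is exact (the hexagon is the Voronoi region of
  its centroid) and resolves boundary ties deterministically.
- **Spherical** (lon/lat): the latitude band is mapped through the Lambert
  cylindrical equal-area projection (x = Rλ, y = R sin φ), tiled with
  regular hexagons there, and mapped back with densified edges. Because the
  projection preserves area, every cell encloses the target area on the
  sphere (verified against a spherical-excess oracle to ~1e-5 relative);
  cell *shape* distorts toward high latitude, which is accepted and is why
  the band is capped at ±85°. The number of hexagon rows is chosen as
  round(band height / row spacing) so the tiled area matches the band area
  to within half a row (<1%); the row selection may therefore be asymmetric
  about the equator by one row. Cells whose planar image would cross the
  antimeridian keep a continuous longitude ring (values may slightly exceed
  the principal range), mirroring how planar boundary cells may extend past
  the extent.

A true icosahedral (Snyder-projection, aperture-3) grid is deliberately not
implemented: its equal-area property is what the analysis uses, and that is
delivered exactly by the tessellations above, while externally produced
hexagon files can be loaded from GeoJSON (areas are recomputed from
geometry, not trusted). The aperture arithmetic is provided for cell-size
bookkeeping: an aperture-a system at resolution r has 10·a^r + 2 cells
(including the 12 pentagons), so aperture 3 at resolution 7 has 21,872
cells of 4πR²/21,872 ≈ 23,321 km² on the authalic sphere (R = 6371.007 km),
the familiar "~23,323 km²" global hexagon size.

## Presence–absence

A species is present in a cell if its (merged, optionally
native-breeding-filtered) range shares **any positive area** with the cell;
tangential contact counts as absent to avoid floating-point-dependent
presences. Any-overlap is the inclusive reading appropriate for potential
networks; a fractional-overlap predicate (intersection ≥ f × cell area) is
exposed for sensitivity analyses. Range attribute filtering follows the
range-map convention presence=extant, origin=native,
seasonal∈{resident, breeding} when those fields exist, and keeps everything
(with a logged warning) when they do not. Species names are normalised
(lowercase, collapsed whitespace) with an optional user synonym table; the
package supplies the mechanism, not a taxonomy.

## Spatial regression

Weights: binary neighbours within a 200 km **centroid** distance band
(great-circle on lon/lat grids, Euclidean on planar ones), row-standardised.
On the ~23,323 km² hexagon grid the centroid spacing is ≈164 km, so interior
cells have exactly six neighbours; 200 km is the conventional threshold that
produces this topology. Cells with no neighbour ("islands") keep zero rows —
their errors are left untransformed — and are reported, not dropped.

The error-SAR y = Xβ + u, u = λWu + ε is fitted by maximum likelihood using
the profile log-likelihood in λ:

    ℓ(λ) = −(n/2)[log(2πσ²(λ)) + 1] + Σᵢ log(1 − λωᵢ)

with β(λ), σ²(λ) from least squares on the filtered data (I − λW)y,
(I − λW)X, and ωᵢ the eigenvalues of W. For W = D⁻¹B with symmetric binary
B the spectrum is real and equals that of D^(−1/2)BD^(−1/2), which is what
is diagonalised (dense symmetric eigendecomposition; islands contribute
ω = 0). λ is searched inside (1/ω_min, 1/ω_max) — the upper bound is 1 for
row-standardised weights — by bounded Brent minimisation to 1e-8; an
optimum within 1e-6 of a bound raises a convergence warning. Fixing λ = 0
reproduces OLS exactly (same β, same log-likelihood), which is tested to
1e-10 and is the basis of the LR comparison: LR = 2(ℓ_SAR − ℓ_OLS), df = 1.
This dense-eigenvalue path is intended for n up to a few thousand cells;
sparse log-determinant approximations are out of scope.

Nagelkerke's pseudo-R² is computed against an intercept-only non-spatial
Gaussian null:
R² = [1 − exp((2/n)(ℓ₀ − ℓ))] / [1 − exp((2/n)ℓ₀)].
**Caveat:** for continuous responses the Gaussian log-likelihood can be
positive (whenever the null residual sd < (2πe)^(−1/2) ≈ 0.242), making the
normaliser non-positive and the statistic undefined. The standalone
function raises in that case; `sar_error_fit` degrades to NaN with a
warning and still reports the LR, which is invariant to rescaling y. The
small synthetic worlds used in the tests sit in this corner (linkage
density sd ≈ 0.1); realistic continental-scale tables do not.

Each richness covariate (parasite, host, and optionally total bird
richness) is fitted in its own univariate model with intercept, not jointly
— three separate model pairs, matching how such results are conventionally
reported — and regressions use only cells with a defined linkage density.

## The synthetic world

The generator exists so the whole pipeline is testable without proprietary
range maps. What it emulates, and its defaults:

| parameter | default | rationale |
|---|---|---|
| extent | 3300 × 2850 km | ≈ a 20 × 20 grid of 23,323 km² hexagons |
| n_parasites / n_hosts / n_other_birds | 10 / 60 / 40 | small-world test scale |
| range areas | log-normal, median 2×10⁵ km², σ_log = 0.8 | a species spans a handful of cells |
| centroid density | linear gradient along x, strength 0.5 | produces a richness gradient |
| hosts per parasite | max(1, NegBin(r = 0.7, μ = 20)) | closed-form median 11, IQR 25, long tail — the documented global repertoire distribution |
| host sharing | 0.35 | roughly a third of hosts acquire >1 parasite |
| SAR response | β = (1, 2), λ = 0.7, σ = 1 | clearly autocorrelated but well inside the stationarity bounds |

Ranges are single convex ellipses (64 vertices) clipped to the domain; real
ranges are fragmented and concave. Host choice has no phylogenetic or
geographic signal: a parasite's hosts are drawn without reference to range
overlap, so small worlds produce many cells where a parasite co-occurs with
none of its hosts (empty networks) and the richness–complexity coupling is
weak. Passing tests therefore demonstrate pipeline correctness and
estimator calibration, not biological realism of effect sizes. Everything
is deterministic given the config seed (distinct derived seeds for ranges
and interactions, so changing one block does not reshuffle the other).

## Numerical choices and degenerate inputs

- Areas and distances in km²/km on the authalic sphere R = 6371.007 km.
- Quartiles (hence IQR = Q3 − Q1) use linear interpolation between order
  statistics; pinned by a fixture test.
- Duplicate interaction rows are collapsed with a logged count; a
  parasite-equals-host row is an error naming the row.
- Empty inputs: empty land set → empty grid with a warning; empty
  interaction table → pipeline aborts at the interactions stage with a
  machine-readable error code; empty networks → missing metrics.
- Degree draws are truncated at the host-pool size; a configured mean
  degree exceeding the pool is rejected outright.
- Pipeline reruns on identical inputs are byte-identical (CSV, GeoJSON and
  GAL outputs carry no timestamps or float jitter).

## Problem sizes

Tests and the acceptance script run on a 441-cell planar grid (the 20 × 20
world above): SAR fits there take milliseconds each since the weights
spectrum is computed once and cached, and the full suite completes in
about a minute. The same code paths handle thousands of cells; only the
dense eigendecomposition (O(n³), n = cells with defined response) caps
practical size at a few thousand cells.

## Known limitations

- Interaction lists are binary: host-use frequency, local host preference
  and gens/subspecies structure are not represented.
- The potential-network construction overstates local interaction richness
  wherever a documented pair co-occurs but does not locally interact.
- No true ISEA3H indexing; loaded third-party grids are trusted for
  topology but re-measured for area.
- The spherical tessellation's cell shapes (not areas) distort with
  latitude; polar caps beyond ±85° are unsupported.
- p-values beyond the F and LR statistics are out of scope.
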