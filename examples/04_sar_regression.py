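"""Spatial-error SAR versus OLS on spatially autocorrelated data.

Simulates a response with genuine error autocorrelation (lambda = 0.7) on
a hexagon grid, then fits OLS (which ignores the spatial structure) and
the maximum-likelihood error-SAR (which models it).  The SAR recovers the
autocorrelation parameter and wins the likelihood-ratio comparison.
"""

import numpy as np

import paranet as pn

grid = pn.build_planar_hex_grid((0, 0, 3300, 2850), 23323.0)
W = pn.distance_band_weights(grid.centroids(), 200.0)
print(f"{W.n} cells; interior cells have "
      f"{int(np.asarray(W.binary.sum(axis=1)).max())} neighbours within 200 km")

rng = np.random.default_rng(5)
X = np.column_stack([np.ones(W.n), rng.normal(size=W.n)])
y = pn.simulate_sar_response(X, W, beta=(1.0, 2.0), lam=0.7, sigma=1.0, seed=99)

ols = pn.ols_fit(y, X)
sar = pn.sar_error_fit(y, X, W)
print(f"OLS:  beta = {np.round(ols.beta, 3)}, R2 = {ols.r2:.3f}, "
      f"F[{ols.df[0]}, {ols.df[1]}] = {ols.F:.1f}")
print(f"SAR:  beta = {np.round(sar.beta, 3)}, lambda = {sar.lam:.3f} "
      f"(true 0.7), Nagelkerke R2 = {sar.nagelkerke:.3f}")
print(f"LR vs OLS = {sar.lr_vs_ols:.1f} on df = {sar.lr_df}: the spatial "
      f"error term captures most of the structure OLS misattributes.")
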