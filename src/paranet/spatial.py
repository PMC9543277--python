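"""Spatial regression: distance-band weights, OLS, and the ML error-SAR.

Per-cell network complexity is spatially autocorrelated (neighbouring
hexagons share species), so ordinary least squares understates uncertainty
and its fit statistics conflate spatial structure with the covariate of
interest.  The standard remedy in macroecology is the simultaneous
autoregressive model with the autoregressive process in the error term
(error-SAR):

    y = X beta + u,    u = lambda W u + eps,    eps ~ N(0, sigma^2 I)

where W is a row-standardised spatial weights matrix — here binary
neighbours within a fixed centroid-distance band (200 km by convention for
~23,000 km2 hexagon grids, whose centroid spacing is ~164 km, giving six
neighbours per interior cell), with each row divided by its sum.

Estimation is by maximum likelihood with the profile (concentrated)
log-likelihood in lambda:

    ell(lambda) = -(n/2) [log(2 pi sigma^2(lambda)) + 1] + log|I - lambda W|

where beta(lambda) and sigma^2(lambda) come from least squares on the
spatially filtered data y* = (I - lambda W) y, X* = (I - lambda W) X, and
log|I - lambda W| = sum_i log(1 - lambda w_i) over the eigenvalues w_i of
W.  For W = D^-1 B with symmetric binary B, the eigenvalues are real and
equal to those of the symmetric D^-1/2 B D^-1/2, which is what is
diagonalised (rows with no neighbours — "islands" — contribute zero
eigenvalues and keep untransformed errors).  lambda is searched within
(1/w_min, 1/w_max) by bounded scalar minimisation.

Model comparison uses the likelihood-ratio statistic against OLS (the
lambda = 0 restriction, df = 1) and Nagelkerke's pseudo-R2 against an
intercept-only non-spatial null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .grid import EARTH_RADIUS_KM


class SpatialStatsError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class SpatialWeights:
    """Row-standardised distance-band weights.

    ``matrix`` is the row-standardised sparse W; ``binary`` the symmetric
    0/1 neighbour matrix it came from.  Island observations (no neighbour
    within the threshold) have all-zero rows and are listed in ``islands``.
    """

    matrix: sparse.csr_matrix
    binary: sparse.csr_matrix
    threshold_km: float
    islands: list[int]
    row_standardised: bool = True
    _eigvals: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.matrix.getrow(i).indices

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W via the symmetric similarity transform.

        W = D^-1 B is similar to S = D^-1/2 B D^-1/2 on the non-island
        block; islands contribute zeros.  Cached after first computation.
        """
        if self._eigvals is None:
            d = np.asarray(self.binary.sum(axis=1)).ravel()
            live = d > 0
            if not live.any():
                self._eigvals = np.zeros(self.n)
            else:
                b = self.binary.toarray()[np.ix_(live, live)]
                dinv_sqrt = 1.0 / np.sqrt(d[live])
                s = b * dinv_sqrt[:, None] * dinv_sqrt[None, :]
                ev = np.linalg.eigvalsh((s + s.T) / 2.0)
                self._eigvals = np.concatenate([ev, np.zeros(self.n - live.sum())])
        return self._eigvals

    def lambda_bounds(self) -> tuple[float, float]:
        ev = self.eigenvalues()
        wmin, wmax = ev.min(), ev.max()
        if wmin >= 0 or wmax <= 0:
            raise SpatialStatsError("degenerate weights: cannot bound lambda")
        return 1.0 / wmin, 1.0 / wmax

    def sparse_identity_minus(self, lam: float) -> sparse.csr_matrix:
        return (sparse.identity(self.n, format="csr") - lam * self.matrix).tocsr()

    def to_gal(self, path, ids: list[str] | None = None) -> None:
        """Write the binary neighbour structure in GAL text format."""
        ids = ids or [str(i) for i in range(self.n)]
        lines = [str(self.n)]
        coo = self.binary.tocoo()
        nbrs: dict[int, list[int]] = {i: [] for i in range(self.n)}
        for i, j in zip(coo.row, coo.col):
            nbrs[i].append(j)
        for i in range(self.n):
            lines.append(f"{ids[i]} {len(nbrs[i])}")
            lines.append(" ".join(ids[j] for j in sorted(nbrs[i])))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def great_circle_km(
    a: np.ndarray, b: np.ndarray, radius: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Haversine distance between lon/lat arrays (degrees), in km."""
    lon1, lat1 = np.radians(np.asarray(a, float)).T
    lon2, lat2 = np.radians(np.asarray(b, float)).T
    h = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * radius * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def distance_band_weights(
    centroids: np.ndarray,
    threshold_km: float,
    metric: str = "euclidean_km",
    radius: float = EARTH_RADIUS_KM,
) -> SpatialWeights:
    """Binary neighbours within ``threshold_km`` of each centroid, row-standardised.

    ``metric="euclidean_km"`` treats centroids as planar km coordinates;
    ``metric="great_circle"`` treats them as lon/lat degrees and uses
    great-circle distance on the authalic sphere (implemented by querying
    the equivalent chord length on the unit sphere).  Self-neighbourhood is
    excluded.  Islands keep all-zero rows and are reported, not dropped.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise SpatialStatsError("need at least two 2-d centroids")
    if threshold_km <= 0:
        raise SpatialStatsError("threshold_km must be positive")
    if metric == "euclidean_km":
        query_pts, query_r = pts, threshold_km
    elif metric == "great_circle":
        lon, lat = np.radians(pts[:, 0]), np.radians(pts[:, 1])
        query_pts = np.column_stack(
            [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
        ) * radius
        query_r = 2 * radius * math.sin(min(threshold_km / (2 * radius), math.pi / 2))
    else:
        raise SpatialStatsError(f"unknown metric {metric!r}")
    if len(np.unique(pts, axis=0)) < len(pts):
        warnings.warn("duplicate centroids: coincident cells become mutual neighbors",
                      stacklevel=2)
    tree = cKDTree(query_pts)
    pairs = tree.query_pairs(query_r, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        binary = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
    else:
        binary = sparse.csr_matrix((n, n))
    rowsum = np.asarray(binary.sum(axis=1)).ravel()
    islands = np.flatnonzero(rowsum == 0).tolist()
    if len(islands) == n:
        raise SpatialStatsError(
            f"no centroid pair is within {threshold_km} km; all rows empty"
        )
    inv = np.where(rowsum > 0, 1.0 / np.maximum(rowsum, 1), 0.0)
    w = sparse.diags(inv) @ binary
    return SpatialWeights(w.tocsr(), binary.tocsr(), threshold_km, islands)


@dataclass(frozen=True)
class OlsFit:
    beta: np.ndarray
    r2: float
    F: float
    df: tuple[int, int]
    sigma2: float
    logLik: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)


def _gaussian_loglik(rss: float, n: int) -> float:
    sigma2 = rss / n
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def ols_fit(y: np.ndarray, X: np.ndarray) -> OlsFit:
    """Ordinary least squares with an already-included intercept column.

    Reports R2 about the mean, the overall F statistic with (k-1, n-k)
    degrees of freedom, and the Gaussian log-likelihood at the ML variance
    RSS/n (so it is directly comparable to the SAR log-likelihood).
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n, k = X.shape
    if n <= k:
        raise SpatialStatsError(f"need n > k (n={n}, k={k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, r = np.linalg.qr(X)
        bad = [j for j in range(k) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-10]
        raise SpatialStatsError(f"X is rank-deficient; suspect columns {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if k > 1 and rss > 0:
        F = ((tss - rss) / (k - 1)) / (rss / (n - k))
    else:
        F = math.inf if rss == 0 else 0.0
    return OlsFit(
        beta=beta,
        r2=r2,
        F=float(F),
        df=(k - 1, n - k),
        sigma2=rss / n,
        logLik=_gaussian_loglik(rss, n) if rss > 0 else math.inf,
        n=n,
        residuals=resid,
    )


def nagelkerke_r2(logLik_model: float, logLik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R2, normalised so a saturated model scores 1."""
    if logLik_model < logLik_null - 1e-9:
        raise SpatialStatsError("model log-likelihood below the null's")
    denom = 1.0 - math.exp(2.0 / n * logLik_null)
    if denom <= 0:
        raise SpatialStatsError("degenerate null model (denominator <= 0)")
    return (1.0 - math.exp(2.0 / n * (logLik_null - logLik_model))) / denom


@dataclass(frozen=True)
class SarFit:
    """Maximum-likelihood error-SAR fit."""

    lam: float
    beta: np.ndarray
    sigma2: float
    logLik: float
    logLik_null: float
    logLik_ols: float
    nagelkerke: float
    lr_vs_ols: float
    lr_df: int
    lambda_bounds: tuple[float, float]
    n: int
    converged: bool

    def report(self) -> dict:
        return {
            "lambda": self.lam,
            "beta": list(map(float, self.beta)),
            "sigma2": self.sigma2,
            "logLik": self.logLik,
            "nagelkerke_r2": None if math.isnan(self.nagelkerke) else self.nagelkerke,
            "LR": self.lr_vs_ols,
            "df": self.lr_df,
            "n": self.n,
        }


def _profile_pieces(y, X, W: SpatialWeights, lam: float):
    a = W.sparse_identity_minus(lam)
    ys = a @ y
    xs = a @ X
    beta, _, _, _ = np.linalg.lstsq(xs, ys, rcond=None)
    resid = ys - xs @ beta
    rss = float(resid @ resid)
    return beta, rss


def _concentrated_loglik(y, X, W: SpatialWeights, lam: float, eigvals: np.ndarray) -> float:
    _, rss = _profile_pieces(y, X, W, lam)
    n = len(y)
    sigma2 = rss / n
    logdet = float(np.log1p(-lam * eigvals).sum())
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) + logdet


def sar_error_fit(
    y: np.ndarray,
    X: np.ndarray,
    W: SpatialWeights,
    fix_lambda: float | None = None,
    xtol: float = 1e-8,
) -> SarFit:
    """Fit the error-SAR y = X beta + u, u = lambda W u + eps, by ML.

    The profile log-likelihood in lambda is maximised by bounded scalar
    search inside (1/w_min, 1/w_max); at the optimum, beta and sigma2 are
    the GLS values from the spatially filtered regression.  ``fix_lambda``
    evaluates the profile at a fixed lambda instead (lambda = 0 reproduces
    OLS exactly).  The Nagelkerke pseudo-R2 is computed against an
    intercept-only non-spatial Gaussian null, and the LR statistic against
    the OLS fit on the same (y, X) with df = 1.
    """
    if not W.row_standardised:
        raise SpatialStatsError("weights must be row-standardised")
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    n = len(y)
    if X.shape[0] != n or W.n != n:
        raise SpatialStatsError("y, X and W dimensions disagree")
    eigvals = W.eigenvalues()
    lo, hi = W.lambda_bounds()
    converged = True
    if fix_lambda is not None:
        if not (lo < fix_lambda < hi):
            raise SpatialStatsError(f"fix_lambda outside ({lo:.4f}, {hi:.4f})")
        lam = float(fix_lambda)
    else:
        eps = 1e-9 * (hi - lo)
        res = minimize_scalar(
            lambda l: -_concentrated_loglik(y, X, W, l, eigvals),
            bounds=(lo + eps, hi - eps),
            method="bounded",
            options={"xatol": xtol},
        )
        lam = float(res.x)
        if min(lam - lo, hi - lam) < 1e-6 * (hi - lo):
            converged = False
            warnings.warn(
                f"lambda optimum {lam:.6f} at the boundary of ({lo:.4f}, {hi:.4f})",
                ConvergenceWarning,
                stacklevel=2,
            )
    beta, rss = _profile_pieces(y, X, W, lam)
    sigma2 = rss / n
    loglik = _concentrated_loglik(y, X, W, lam, eigvals)
    ols = ols_fit(y, X)
    null = ols_fit(y, np.ones((n, 1)))
    try:
        nk = nagelkerke_r2(loglik, null.logLik, n)
    except SpatialStatsError:
        # Nagelkerke's normaliser 1 - exp(2*logLik_null/n) is non-positive
        # whenever the null's residual sd falls below (2*pi*e)^-1/2 ~ 0.242
        # (a continuous-response corner where the Gaussian density exceeds 1);
        # the statistic is undefined there.  The LR, which is invariant to
        # rescaling y, is unaffected.
        warnings.warn(
            "Nagelkerke R2 undefined: null log-likelihood is positive "
            "(response dispersion too small); reporting NaN",
            stacklevel=2,
        )
        nk = math.nan
    return SarFit(
        lam=lam,
        beta=beta,
        sigma2=sigma2,
        logLik=loglik,
        logLik_null=null.logLik,
        logLik_ols=ols.logLik,
        nagelkerke=nk,
        lr_vs_ols=max(0.0, 2.0 * (loglik - ols.logLik)),
        lr_df=1,
        lambda_bounds=(lo, hi),
        n=n,
        converged=converged,
    )


def simulate_sar_response(
    X: np.ndarray,
    W: SpatialWeights,
    beta: np.ndarray,
    lam: float,
    sigma: float,
    seed: int,
) -> np.ndarray:
    """Draw y = X beta + (I - lambda W)^-1 eps with eps ~ N(0, sigma^2 I).

    Deterministic given ``seed``.  The induced error field is exactly the
    error-SAR data-generating process, so fitted models should recover
    (beta, lambda, sigma) up to sampling noise.
    """
    X = np.atleast_2d(np.asarray(X, float))
    beta = np.asarray(beta, float).ravel()
    lo, hi = W.lambda_bounds()
    if not (lo < lam < hi):
        raise SpatialStatsError(f"lambda {lam} outside invertibility bounds ({lo:.4f}, {hi:.4f})")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=W.n)
    u = sparse.linalg.spsolve(W.sparse_identity_minus(lam).tocsc(), eps)
    return X @ beta + u
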