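"""Geostatistics for log-transformed indoor radon.

Estimation of the spatial structure of log-radon (empirical semivariogram and
weighted-least-squares variogram fitting), ordinary kriging on a regular grid,
the bias-corrected lognormal back-transform, and aggregation of the kriged
surface to administrative-region means.

All coordinates are planar projected kilometres; great-circle geometry is out
of scope. Radon concentrations are Bq/m^3 and strictly positive, so kriging
operates on natural logs throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, spatial, stats

logger = logging.getLogger(__name__)

VALID_FAMILIES = ("spherical", "exponential", "gaussian")


class VariogramFitError(RuntimeError):
    """Variogram fitting failed to converge.

    Carries the best iterate found so far in ``best_model`` plus a diagnostic
    message, so callers can inspect or override.
    """

    def __init__(self, message: str, best_model: "VariogramModel | None" = None):
        super().__init__(message)
        self.best_model = best_model


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram model on the log scale.

    gamma(0) = 0 by definition; the nugget appears as the limit for h -> 0+.
    ``sill = nugget + psill`` and the covariance implied for field simulation
    and kriging is C(h) = sill - gamma(h).

    For the exponential and gaussian families ``range`` is the practical
    range: gamma reaches ~95% of the sill at h = range (i.e. the exponential
    uses exp(-3h/a) and the gaussian exp(-3(h/a)^2)).
    """

    family: str
    nugget: float
    psill: float
    range: float

    def __post_init__(self):
        if self.family not in VALID_FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0:
            raise ValueError(
                f"nugget and partial sill must be >= 0 "
                f"(got nugget={self.nugget}, psill={self.psill})"
            )
        if self.range <= 0:
            raise ValueError(f"range must be > 0 (got {self.range})")

    @property
    def sill(self) -> float:
        return self.nugget + self.psill

    def __call__(self, h):
        """Semivariance gamma(h); h may be a scalar or array, in km."""
        h = np.asarray(h, dtype=float)
        hr = h / self.range
        if self.family == "spherical":
            struct = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
        elif self.family == "exponential":
            struct = 1.0 - np.exp(-3.0 * hr)
        else:  # gaussian
            struct = 1.0 - np.exp(-3.0 * hr**2)
        gamma = self.nugget + self.psill * struct
        # gamma(0) = 0 exactly; the nugget is the h -> 0+ limit
        return np.where(h > 0, gamma, 0.0)

    def covariance(self, h):
        """C(h) = sill - gamma(h); C(0) = sill (nugget variance included)."""
        return self.sill - self(h)


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned method-of-moments semivariogram estimate.

    ``gamma`` is NaN for empty bins (flagged, never interpolated).
    ``gamma_zero``/``n_zero_pairs`` collect exactly-coincident pairs, which
    estimate the nugget and never enter a positive-lag bin.
    """

    bin_centers: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    gamma_zero: float = float("nan")
    n_zero_pairs: int = 0

    def __post_init__(self):
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("lag bin centers must be strictly increasing")
        if np.any(self.gamma[np.isfinite(self.gamma)] < 0):
            raise ValueError("semivariance must be nonnegative")

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


def skewness(values) -> float:
    """Adjusted Fisher-Pearson sample skewness G1 = g1 * sqrt(n(n-1))/(n-2).

    The bias-corrected coefficient used to diagnose the heavy right tail of
    indoor-radon surveys. Requires n >= 3 and nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size < 3:
        raise ValueError(f"skewness requires at least 3 values (got {v.size})")
    if np.ptp(v) == 0 or np.var(v) == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(stats.skew(v, bias=False))


def empirical_semivariogram(
    x, y, values, n_lags: int = 15, max_lag: float | None = None
) -> EmpiricalVariogram:
    """Method-of-moments semivariogram of point data (log scale expected).

    gamma_hat(h_k) = 1/(2 N_k) * sum over pairs in bin k of (y_i - y_j)^2,
    with equal-width bins (0, max_lag] and right-inclusive edges. Default
    max_lag is half the diagonal of the bounding box. Coincident pairs
    (h = 0 exactly) are accumulated separately as a nugget estimate.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    v = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xy = np.column_stack([x, y])
    if max_lag is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        max_lag = float(np.hypot(*span)) / 2.0
    if max_lag <= 0:
        raise ValueError(f"max_lag must be > 0 (got {max_lag})")

    d = spatial.distance.pdist(xy)
    sq = spatial.distance.pdist(v[:, None], metric="sqeuclidean")

    zero = d == 0
    n_zero = int(zero.sum())
    gamma_zero = float(sq[zero].sum() / (2 * n_zero)) if n_zero else float("nan")

    in_range = (d > 0) & (d <= max_lag)
    if not in_range.any() and n_zero == 0:
        raise ValueError(f"all point pairs lie beyond max_lag={max_lag}")
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    # right-inclusive bins (0, e1], (e1, e2], ...
    idx = np.searchsorted(edges, d[in_range], side="left") - 1
    idx = np.clip(idx, 0, n_lags - 1)
    counts = np.bincount(idx, minlength=n_lags)
    sums = np.bincount(idx, weights=sq[in_range], minlength=n_lags)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(centers, gamma, counts, gamma_zero, n_zero)


def fit_variogram(
    emp: EmpiricalVariogram, family: str = "spherical"
) -> VariogramModel:
    """Fit a variogram model by Cressie-style weighted least squares.

    Minimises sum_k N_k * (gamma_hat_k - gamma_model_k)^2 / gamma_model_k^2
    over nonempty bins, with bounds nugget >= 0, psill >= 0, range > 0.
    Raises :class:`VariogramFitError` (carrying the best iterate) on
    non-convergence.
    """
    ok = emp.nonempty & np.isfinite(emp.gamma)
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 nonempty lag bins to fit a variogram (got {int(ok.sum())})"
        )
    h = emp.bin_centers[ok]
    g = emp.gamma[ok]
    n = emp.counts[ok].astype(float)
    eps = 1e-12

    def residuals(theta):
        c0, c, a = theta
        gm = VariogramModel(family, max(c0, 0.0), max(c, 0.0), max(a, eps))(h)
        gm = np.maximum(gm, eps)
        return np.sqrt(n) * (g - gm) / gm

    g_max = float(g.max())
    c0_init = float(max(min(g[0], g_max), eps))
    starts = [
        (0.5 * c0_init, max(g_max - 0.5 * c0_init, eps), h.max() / 2),
        (eps, g_max, h.max() / 3),
        (0.5 * g_max, 0.5 * g_max, h.max()),
    ]
    best = None
    best_cost = np.inf
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                theta0,
                bounds=([0.0, 0.0, eps], [np.inf, np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:  # singular jacobian etc.; try next start
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        raise VariogramFitError(
            f"variogram WLS failed for family {family!r} from all starts"
        )
    c0, c, a = best.x
    model = VariogramModel(family, float(max(c0, 0.0)), float(max(c, 0.0)), float(max(a, eps)))
    if not best.success:
        raise VariogramFitError(
            f"variogram WLS did not converge (status {best.status}: {best.message})",
            best_model=model,
        )
    return model


def _dedupe_points(xy: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average log-values at exactly coincident locations.

    Duplicate survey locations would make the kriging system singular; on the
    log scale, averaging matches the annual-average semantics of the data.
    """
    uniq, inv = np.unique(xy, axis=0, return_inverse=True)
    if uniq.shape[0] == xy.shape[0]:
        return xy, y
    sums = np.bincount(inv, weights=y, minlength=uniq.shape[0])
    cnts = np.bincount(inv, minlength=uniq.shape[0])
    return uniq, sums / cnts


def ordinary_kriging(
    points_xy, log_values, model: VariogramModel, target
) -> tuple[float, float, float]:
    """Solve the ordinary-kriging system at one target location.

    Solves [Gamma, 1; 1^T, 0] [w; mu] = [gamma_0; 1] built from the
    semivariogram and returns (yhat, sigma2_ok, mu_lagrange) with
    yhat = sum w_i y_i and sigma2_ok = sum w_i gamma(h_i0) + mu.
    Coincident data points are deduplicated by log-scale averaging first.
    """
    xy = np.atleast_2d(np.asarray(points_xy, float))
    yv = np.asarray(log_values, float)
    if xy.shape[0] < 1:
        raise ValueError("ordinary kriging requires at least one neighbour")
    xy, yv = _dedupe_points(xy, yv)
    k = xy.shape[0]
    t = np.asarray(target, float)

    d = spatial.distance.cdist(xy, xy)
    a = np.zeros((k + 1, k + 1))
    a[:k, :k] = model(d)
    a[:k, k] = 1.0
    a[k, :k] = 1.0
    b = np.empty(k + 1)
    g0 = model(np.hypot(*(xy - t).T))
    b[:k] = g0
    b[k] = 1.0
    try:
        sol = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular ordinary-kriging system with {k} deduplicated points"
        ) from exc
    w = sol[:k]
    mu = float(sol[k])
    yhat = float(w @ yv)
    sigma2 = float(w @ g0 + mu)
    if sigma2 < -1e-9:
        raise FloatingPointError(f"kriging variance {sigma2} < -1e-9")
    return yhat, max(sigma2, 0.0), mu


def lognormal_backtransform(yhat, sigma2_ok, mu_lagrange):
    """Bias-corrected back-transform of an OK log-scale estimate to Bq/m^3.

    zhat = exp(yhat + sigma2_ok/2 - mu_lagrange), the standard unbiased
    back-transform for ordinary lognormal kriging. Overflow is guarded by
    clipping the exponent at 700.
    """
    yhat = np.asarray(yhat, float)
    s2 = np.asarray(sigma2_ok, float)
    mu = np.asarray(mu_lagrange, float)
    if not (np.all(np.isfinite(yhat)) and np.all(np.isfinite(s2)) and np.all(np.isfinite(mu))):
        raise ValueError("non-finite input to lognormal back-transform")
    if np.any(s2 < -1e-9):
        raise ValueError("kriging variance must be >= 0")
    expo = yhat + np.maximum(s2, 0.0) / 2.0 - mu
    return np.exp(np.clip(expo, -700.0, 700.0))


@dataclass
class KrigedGrid:
    """Per-cell ordinary lognormal kriging results on a regular grid.

    Arrays are (ny, nx), row 0 = southernmost row (grid row-major order).
    ``fallback`` flags cells with no neighbour in the search radius, filled
    with the global log-mean.
    """

    yhat: np.ndarray
    ok_variance: np.ndarray
    lagrange: np.ndarray
    zhat: np.ndarray
    fallback: np.ndarray = field(default=None)  # type: ignore[assignment]


def krige_grid(
    points_xy,
    log_values,
    model: VariogramModel,
    grid,
    n_neighbors: int = 16,
    max_radius: float | None = None,
) -> KrigedGrid:
    """Ordinary lognormal kriging of every cell centre of ``grid``.

    Search neighbourhood: nearest ``n_neighbors`` points within ``max_radius``
    (default 3x the variogram range). Cells with no neighbour in radius fall
    back to the global log-mean with sigma2 = sill and are flagged.
    """
    xy = np.atleast_2d(np.asarray(points_xy, float))
    yv = np.asarray(log_values, float)
    xy, yv = _dedupe_points(xy, yv)
    if max_radius is None:
        max_radius = 3.0 * model.range
    tree = spatial.cKDTree(xy)
    centers = grid.cell_centers()  # (N, 2) row-major
    k = min(n_neighbors, xy.shape[0])
    dist, idx = tree.query(centers, k=k)
    dist = np.asarray(dist).reshape(len(centers), k)
    idx = np.asarray(idx).reshape(len(centers), k)

    n_cells = len(centers)
    yhat = np.empty(n_cells)
    s2 = np.empty(n_cells)
    mu = np.empty(n_cells)
    fb = np.zeros(n_cells, dtype=bool)
    global_mean = float(yv.mean())
    for i in range(n_cells):
        use = idx[i][dist[i] <= max_radius]
        if use.size == 0:
            yhat[i], s2[i], mu[i] = global_mean, model.sill, 0.0
            fb[i] = True
            continue
        yhat[i], s2[i], mu[i] = ordinary_kriging(xy[use], yv[use], model, centers[i])
    if fb.any():
        logger.warning(
            "%d of %d grid cells had no neighbour within radius %.1f km; "
            "filled with the global log-mean",
            int(fb.sum()), n_cells, max_radius,
        )
    zhat = lognormal_backtransform(yhat, s2, mu)
    shape = (grid.ny, grid.nx)
    return KrigedGrid(
        yhat.reshape(shape),
        s2.reshape(shape),
        mu.reshape(shape),
        zhat.reshape(shape),
        fb.reshape(shape),
    )


def aggregate_to_regions(zhat: np.ndarray, regions) -> pd.DataFrame:
    """Aggregate a kriged concentration surface to region means.

    Unweighted arithmetic mean of cell estimates within each region (cells are
    equal-area, so this is the area-weighted mean). Returns a DataFrame with
    columns region_id, radon_bqm3, n_cells.
    """
    z = np.asarray(zhat, float).ravel()
    member = np.asarray(regions.membership).ravel()
    if z.shape != member.shape:
        raise ValueError("field and region membership shapes differ")
    rows = []
    for rid in regions.region_ids:
        mask = member == rid
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"region {rid} has no grid cells")
        rows.append({"region_id": rid, "radon_bqm3": float(z[mask].mean()), "n_cells": n})
    return pd.DataFrame(rows)
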