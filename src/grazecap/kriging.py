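"""Ordinary kriging onto the county grid.

Empirical semivariogram (Matheron estimator), weighted least-squares model
fitting (spherical / exponential / gaussian), moving-neighbourhood ordinary
kriging in covariance form with the unbiasedness constraint, and
leave-one-out cross-validation.

Conventions: gamma(0) = 0; for h > 0 the model is
gamma(h) = nugget + (sill - nugget) * g(h / range), so `sill` is the total
sill. The kriging system uses C(h) = sill - gamma(h) with C(0) = sill;
covariance and variogram forms give identical weights (asserted in tests).
Negative predictions are clamped to zero with the count recorded —
densities cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .grid import GridSpec, Raster

__all__ = [
    "Semivariogram",
    "KrigingResult",
    "empirical_semivariogram",
    "fit_semivariogram",
    "krige",
    "cross_validate",
]

_MODELS = ("spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class Semivariogram:
    model: str = "spherical"
    nugget: float = 0.0
    sill: float = 1.0
    range_km: float = 10.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_km <= 0:
            raise ValueError("require 0 <= nugget <= sill and range > 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        """gamma(h); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        r = self.range_km
        if self.model == "spherical":
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        elif self.model == "exponential":
            g = 1.0 - np.exp(-3.0 * h / r)
        else:  # gaussian
            g = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        out = self.nugget + psill * g
        return np.where(h > 0, out, 0.0)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = sill - gamma(h); C(0) = sill."""
        return self.sill - self(h)


@dataclass
class KrigingResult:
    prediction: Raster
    variance: Raster
    variogram: Semivariogram
    n_clamped: int = 0
    cross_validation: dict[str, float] = field(default_factory=dict)


# ------------------------------------------------------- empirical variogram


def empirical_semivariogram(
    points: np.ndarray,
    values: np.ndarray,
    lag_width: float,
    max_lag: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matheron estimator binned by pair distance.

    Returns (lag centres, semivariances, pair counts); empty bins omitted.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    if lag_width <= 0 or max_lag <= 0:
        raise ValueError("lag_width and max_lag must be positive")
    d = pdist(points)
    if np.all(d < 1e-12):
        raise ValueError("all points coincident; semivariogram undefined")
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    keep = d <= max_lag
    d, sq = d[keep], sq[keep]
    edges = np.arange(0.0, max_lag + lag_width, lag_width)
    idx = np.digitize(d, edges) - 1
    centers, gammas, counts = [], [], []
    for b in range(len(edges) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        gammas.append(float(sq[m].mean()))
        counts.append(n)
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_semivariogram(
    lags: np.ndarray,
    gammas: np.ndarray,
    counts: np.ndarray,
    model: str = "spherical",
) -> tuple[Semivariogram, dict]:
    """Weighted least-squares variogram fit (weights = pair count / lag^2).

    Returns the fitted model and a diagnostics dict with the weighted RMSE
    and a ``pure_nugget`` flag raised when the spatial structure is
    unidentifiable (partial sill negligible or range at its bound).
    """
    lags = np.asarray(lags, float)
    gammas = np.asarray(gammas, float)
    counts = np.asarray(counts, float)
    if len(lags) < 3:
        raise ValueError("need at least 3 non-empty lag bins to fit")
    w = np.sqrt(counts / np.maximum(lags, 1e-9) ** 2)

    gmax = max(gammas.max(), 1e-12)
    lmax = lags.max()

    def resid(theta: np.ndarray) -> np.ndarray:
        nugget, psill, rng = theta
        sv = Semivariogram(model=model, nugget=nugget, sill=nugget + psill, range_km=rng)
        return w * (sv(lags) - gammas)

    best = None
    for r0 in (lmax / 3.0, lmax / 10.0, lmax):
        try:
            sol = least_squares(
                resid,
                x0=[0.0, gmax, r0],
                bounds=([0.0, 0.0, 1e-6], [gmax * 2.0, gmax * 3.0, lmax * 3.0]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        resids = None if best is None else best.fun.tolist()
        raise RuntimeError(f"variogram fit failed; residuals={resids}")

    nugget, psill, rng = best.x
    sv = Semivariogram(model=model, nugget=float(nugget), sill=float(nugget + psill), range_km=float(rng))
    wrmse = float(np.sqrt(np.mean(best.fun**2)))
    pure_nugget = psill < 1e-3 * (nugget + psill + 1e-12) or rng >= lmax * 2.999
    return sv, {"weighted_rmse": wrmse, "pure_nugget": bool(pure_nugget), "n_bins": len(lags)}


# ---------------------------------------------------------------- kriging


def _ok_weights(
    pts: np.ndarray, vals: np.ndarray, target: np.ndarray, variogram: Semivariogram
) -> tuple[np.ndarray, float, float]:
    """Solve the ordinary-kriging system for one target location.

    Returns (weights, prediction, variance). Covariance form with a
    Lagrange multiplier enforcing sum(weights) = 1.
    """
    n = len(pts)
    dmat = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    C = variogram.covariance(dmat)
    d0 = np.hypot(*(pts - target).T)
    c0 = variogram.covariance(d0)

    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.append(c0, 1.0)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        A[:n, :n] += np.eye(n) * max(variogram.sill, 1.0) * 1e-10
        sol = np.linalg.solve(A, b)  # second failure propagates
    lam, mu = sol[:n], sol[n]
    pred = float(lam @ vals)
    var = float(variogram.sill - lam @ c0 - mu)
    return lam, pred, var


def krige(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Semivariogram,
    grid: GridSpec,
    neighborhood_size: int = 16,
    clamp_negative: bool = True,
) -> KrigingResult:
    """Ordinary kriging of point data onto every grid cell centre.

    Uses the ``neighborhood_size`` nearest points per cell (all points if
    fewer). Weights sum to 1 at every cell; the kriging variance is
    non-negative up to round-off.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 1:
        raise ValueError("need at least one data point")
    X, Y = grid.center_mesh()
    targets = np.column_stack([X.ravel(), Y.ravel()])

    if len(points) == 1:
        pred = np.full(grid.shape, values[0])
        var = variogram.covariance(np.hypot(X - points[0, 0], Y - points[0, 1]))
        var = np.maximum(variogram.sill * 2.0 - 2.0 * var, 0.0)  # 2*gamma(h) for n=1
        return KrigingResult(Raster(grid, pred), Raster(grid, var), variogram)

    k = min(neighborhood_size, len(points))
    tree = cKDTree(points)
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr)

    preds = np.empty(len(targets))
    variances = np.empty(len(targets))
    for i, t in enumerate(targets):
        idx = nbr[i]
        lam, p, v = _ok_weights(points[idx], values[idx], t, variogram)
        if abs(lam.sum() - 1.0) > 1e-9:
            raise RuntimeError(f"kriging weights sum to {lam.sum()}, not 1")
        preds[i] = p
        variances[i] = v
    if variances.min() < -1e-9 * max(variogram.sill, 1.0):
        raise RuntimeError(f"negative kriging variance {variances.min()}")
    variances = np.maximum(variances, 0.0)

    n_clamped = 0
    if clamp_negative:
        neg = preds < 0
        n_clamped = int(neg.sum())
        preds = np.maximum(preds, 0.0)
    return KrigingResult(
        prediction=Raster(grid, preds.reshape(grid.shape)),
        variance=Raster(grid, variances.reshape(grid.shape)),
        variogram=variogram,
        n_clamped=n_clamped,
    )


def krige_points(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Semivariogram,
    targets: np.ndarray,
    neighborhood_size: int = 16,
) -> tuple[np.ndarray, np.ndarray]:
    """Kriging predictions and variances at arbitrary target locations (no clamp)."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    targets = np.atleast_2d(np.asarray(targets, float))
    k = min(neighborhood_size, len(points))
    tree = cKDTree(points)
    _, nbr = tree.query(targets, k=k)
    nbr = np.atleast_2d(nbr)
    preds = np.empty(len(targets))
    variances = np.empty(len(targets))
    for i, t in enumerate(targets):
        idx = np.atleast_1d(nbr[i])
        _, preds[i], variances[i] = _ok_weights(points[idx], values[idx], t, variogram)
    return preds, variances


def cross_validate(
    points: np.ndarray,
    values: np.ndarray,
    variogram: Semivariogram,
    neighborhood_size: int = 16,
) -> dict[str, float]:
    """Leave-one-out cross-validation of the kriging predictor."""
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    n = len(points)
    if n < 3:
        raise ValueError("need at least 3 points for cross-validation")
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        pred, _ = krige_points(points[keep], values[keep], variogram, points[i], neighborhood_size)
        errs[i] = pred[0] - values[i]
    return {
        "rmse": float(np.sqrt(np.mean(errs**2))),
        "mean_error": float(errs.mean()),
        "n": n,
    }
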