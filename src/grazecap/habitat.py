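"""Presence-only maximum-entropy habitat model and range masking.

A deliberately small MaxEnt: linear + quadratic features of the covariates
(aspect encoded as sin/cos), standardised over the background (all county
cells); the fitted model is the Gibbs distribution p(cell) ∝ exp(w·f)
maximising the L1-penalised presence log-likelihood. The problem is convex
and is solved by a monotone ascent (the objective trace never decreases);
the Gibbs normalisation holds at every iterate. At beta = 0 the fitted
feature expectations match the presence sample means (the maximum-entropy
moment conditions).

The continuous suitability score is a logistic transform of the centred
linear predictor — monotone in w·f, in (0, 1) — and is binarised into a
range mask, by default at the 10th percentile of suitability over the
presence cells. The mask clips the kriged density surface; no
renormalisation is applied, so population totals are computed after
masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logsumexp

from .grid import GridSpec, Raster

__all__ = [
    "FeatureSpace",
    "MaxentModel",
    "RangeMask",
    "build_features",
    "fit_maxent",
    "threshold_range",
    "mask_density",
]


@dataclass
class FeatureSpace:
    """Standardised per-cell features over the background (all county cells)."""

    grid: GridSpec
    matrix: np.ndarray  # (n_cells, n_features), standardized
    names: list[str]
    means: np.ndarray
    stds: np.ndarray

    def row_of_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return rows * self.grid.ncols + cols


@dataclass
class MaxentModel:
    features: FeatureSpace
    coef: np.ndarray
    beta: float
    objective_trace: list[float]
    converged: bool
    max_normalization_error: float

    @property
    def linear_predictor(self) -> np.ndarray:
        return self.features.matrix @ self.coef

    def raw_probabilities(self) -> np.ndarray:
        """Gibbs probabilities over background cells (sum to 1)."""
        eta = self.linear_predictor
        return np.exp(eta - logsumexp(eta))

    def suitability(self) -> Raster:
        """Logistic suitability score in (0,1), monotone in the linear predictor."""
        eta = self.linear_predictor
        score = expit(eta - eta.mean())
        return Raster(self.features.grid, score.reshape(self.features.grid.shape))


@dataclass
class RangeMask:
    mask: Raster  # binary {0,1}
    rule: str
    threshold: float

    @property
    def suitable_area_km2(self) -> float:
        return float(self.mask.values.sum() * self.mask.spec.cell_area)


# ----------------------------------------------------------------- features


def build_features(covariates: dict[str, Raster], circular: tuple[str, ...] = ("aspect",)) -> FeatureSpace:
    """Linear + quadratic standardised features; circular covariates become (sin, cos).

    Constant covariates carry no information and are dropped with a warning.
    """
    import warnings

    grids = {r.spec for r in covariates.values()}
    if len(grids) != 1:
        raise ValueError("covariates must share one grid")
    grid = next(iter(grids))

    cols, names = [], []
    for name, r in covariates.items():
        v = r.values.ravel().astype(float)
        if name in circular:
            rad = np.radians(v)
            cols += [np.sin(rad), np.cos(rad)]
            names += [f"{name}_sin", f"{name}_cos"]
        else:
            if v.std() < 1e-12:
                warnings.warn(f"covariate {name!r} is constant; dropped from feature space")
                continue
            cols += [v, v**2]
            names += [name, f"{name}^2"]
    if not cols:
        raise ValueError("no usable covariates")
    M = np.column_stack(cols)
    means = M.mean(axis=0)
    stds = M.std(axis=0)
    stds[stds < 1e-12] = 1.0
    return FeatureSpace(grid=grid, matrix=(M - means) / stds, names=names, means=means, stds=stds)


# -------------------------------------------------------------------- fit


def fit_maxent(
    presence_rows: np.ndarray,
    features: FeatureSpace | np.ndarray,
    beta: float = 0.5,
    max_iter: int = 2000,
    tol: float = 1e-10,
    grid: GridSpec | None = None,
) -> MaxentModel:
    """Fit the maximum-entropy Gibbs model by monotone iterative ascent.

    ``presence_rows`` are background row indices of the presence cells
    (repeats allowed). ``features`` may be a FeatureSpace or a plain
    (n_cells, n_features) matrix (then ``grid`` must be given). The
    penalised objective J(w) = w·f̄ − log Z(w) − λ·||w||_1 is concave; the
    line-searched ascent never lets J decrease across iterations (the trace
    is returned on the model). Following the usual MaxEnt convention the
    effective penalty is λ = beta / sqrt(n_presences) — the L1 weight
    tracks the standard error of the presence feature means, so one beta
    works across sample sizes.
    """
    if isinstance(features, np.ndarray):
        if grid is None:
            raise ValueError("grid required when passing a raw feature matrix")
        features = FeatureSpace(
            grid=grid,
            matrix=np.asarray(features, float),
            names=[f"f{i}" for i in range(features.shape[1])],
            means=np.zeros(features.shape[1]),
            stds=np.ones(features.shape[1]),
        )
    F = features.matrix
    presence_rows = np.asarray(presence_rows, int)
    if presence_rows.size < 1:
        raise ValueError("need at least one presence cell")
    if presence_rows.min() < 0 or presence_rows.max() >= F.shape[0]:
        raise ValueError("presence rows outside the background")
    fbar = F[presence_rows].mean(axis=0)
    lam = beta / np.sqrt(presence_rows.size)
    d = F.shape[1]

    nerr_box = [0.0]

    def smooth(w: np.ndarray) -> tuple[float, np.ndarray]:
        eta = F @ w
        lz = logsumexp(eta)
        p = np.exp(eta - lz)
        nerr_box[0] = max(nerr_box[0], abs(p.sum() - 1.0))
        return float(w @ fbar - lz), fbar - F.T @ p

    # classic L1 splitting w = u - v, u,v >= 0: the penalty lam*sum(u+v)
    # is smooth on the box, so a bound-constrained quasi-Newton solver
    # applies; its line search makes the objective trace monotone.
    def negobj(x: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = x[:d], x[d:]
        g, grad = smooth(u - v)
        f = -(g - lam * (u.sum() + v.sum()))
        return f, np.concatenate([-(grad - lam), grad + lam])

    trace: list[float] = [-negobj(np.zeros(2 * d))[0]]

    def track(x: np.ndarray) -> None:
        trace.append(-negobj(x)[0])

    from scipy.optimize import minimize

    sol = minimize(
        negobj,
        np.zeros(2 * d),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * d),
        callback=track,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10, "maxfun": 10 * max_iter},
    )
    if not sol.success and "ITERATIONS REACHED LIMIT" in str(sol.message).upper():
        raise RuntimeError(
            f"maxent did not converge in {max_iter} iterations; objective tail={trace[-5:]}"
        )
    w = sol.x[:d] - sol.x[d:]
    converged = bool(sol.success)
    max_nerr = nerr_box[0]
    return MaxentModel(
        features=features,
        coef=w,
        beta=beta,
        objective_trace=trace,
        converged=converged,
        max_normalization_error=float(max_nerr),
    )


# ------------------------------------------------------------------ mask


def threshold_range(
    model: MaxentModel,
    presence_rows: np.ndarray,
    rule: str = "presence_percentile",
    percentile: float = 10.0,
    threshold: float | None = None,
) -> RangeMask:
    """Binarise suitability into a range mask.

    Default rule keeps every cell at least as suitable as the 10th
    percentile of the presence cells (ties inclusive), so >= 90% of the
    presences fall inside the mask by construction.
    """
    import warnings

    suit = model.suitability()
    flat = suit.values.ravel()
    if rule == "presence_percentile":
        thr = float(np.percentile(flat[np.asarray(presence_rows, int)], percentile))
    elif rule == "fixed":
        if threshold is None:
            raise ValueError("rule='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    mask = (flat >= thr).astype(float).reshape(suit.spec.shape)
    if mask.sum() == 0:
        warnings.warn("range mask is empty at this threshold")
    return RangeMask(mask=Raster(suit.spec, mask), rule=rule, threshold=thr)


def mask_density(density: Raster, mask: RangeMask) -> tuple[Raster, float]:
    """Clip a density surface to the range mask.

    Cells outside the mask are set to 0; inside values are unchanged (no
    renormalisation). Returns the clipped surface and the total number of
    animals removed (density x cell area outside the mask).
    """
    if density.spec != mask.mask.spec:
        raise ValueError("density and mask are on different grids")
    m = mask.mask.values
    clipped = density.values * m
    removed = float(np.sum(density.values * (1.0 - m)) * density.spec.cell_area)
    return density.with_values(clipped), removed
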