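"""Trend surface models: spatial polynomial summaries of a connectopy.

A trend surface model (TSM) of order ``p`` predicts a voxel's gradient value
from pure powers of its three spatial coordinates: x, y, z, x², y², z², ...
up to power ``p`` — no cross terms, so a third-order model has exactly
3 axes × 3 powers = 9 spatial regressors plus a nuisance intercept.

The fit is Bayesian linear regression: an isotropic Gaussian prior on the
coefficients whose precision is chosen by evidence (type-II maximum
likelihood) with the classic MacKay fixed-point updates.  As the evidence
drives the prior precision toward zero the estimate converges to ordinary
least squares, which the noiseless-recovery contract exploits.

Coordinates are normalized per axis (centered at the ROI centroid, scaled to
unit population sd) before powers are taken; raw mm values cubed are badly
conditioned.  Normalization parameters are stored in the fit so coefficients
are comparable across subjects sharing a common-space ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from gradpain.errors import DataError, NumericalError

log = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-12
_BETA_CEIL = 1e12


@dataclass
class TSMFit:
    """Result of a trend-surface fit.

    ``coefficients`` holds the 3·order spatial coefficients in basis column
    order (x, y, z, x², y², z², x³, y³, z³ for order 3); the intercept is
    nuisance and not part of the feature vector.
    """

    coefficients: np.ndarray
    intercept: float
    residual_variance: float
    prior_precision: float
    r2_spatial: float
    order: int
    center: np.ndarray
    scale: np.ndarray
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (3 * self.order,):
            raise DataError(f"expected {3 * self.order} coefficients for order {self.order}")
        if not np.all(np.isfinite(self.coefficients)):
            raise DataError("non-finite TSM coefficients")

    def predict(self, coords: np.ndarray) -> np.ndarray:
        Phi = tsm_basis(coords, order=self.order, center=self.center, scale=self.scale)
        return self.intercept + Phi @ self.coefficients


def normalize_coordinates(
    coords: np.ndarray,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each axis at the centroid and scale to unit population sd.

    Degenerate axes (all voxels coplanar) keep scale 1 with a warning.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if coords.shape[1] != 3:
        raise DataError(f"coordinates must be N x 3, got {coords.shape}")
    if center is None:
        center = coords.mean(axis=0)
    if scale is None:
        scale = coords.std(axis=0)
        flat = scale <= 0
        if flat.any():
            log.warning("normalize_coordinates: degenerate (coplanar) axis/axes %s", np.where(flat)[0])
            scale = np.where(flat, 1.0, scale)
    return (coords - center) / scale, np.asarray(center, float), np.asarray(scale, float)


def tsm_basis(
    coords: np.ndarray,
    order: int = 3,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """Design matrix of pure coordinate powers.

    Columns, in fixed order, are x, y, z, x², y², z², ..., up to ``order``;
    no intercept and no cross terms.  If ``center``/``scale`` are omitted the
    coordinates are normalized internally.
    """
    if order < 1:
        raise DataError("order must be >= 1")
    if center is None or scale is None:
        Xn, center, scale = normalize_coordinates(coords)
    else:
        Xn, _, _ = normalize_coordinates(coords, center, scale)
    return np.hstack([Xn**p for p in range(1, order + 1)])


def fit_tsm(
    values: np.ndarray,
    coords: np.ndarray,
    order: int = 3,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> TSMFit:
    """Fit a trend surface to per-voxel values by evidence-calibrated ridge.

    The hyperparameters (prior precision α, noise precision β) follow the
    MacKay fixed point: α = γ/‖w‖², β = (N−γ)/RSS with γ the effective number
    of parameters.  β is capped so that a perfect (noiseless polynomial) fit
    converges to the OLS solution instead of diverging.
    """
    y = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite connectopy values in TSM fit")
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    N = y.shape[0]
    if coords.shape[0] != N:
        raise DataError("values and coordinates are not aligned")
    p = 3 * order
    if N < p + 2:
        raise DataError(f"need more than {p + 1} voxels for an order-{order} fit, got {N}")
    Xn, center, scale = normalize_coordinates(coords)
    Phi = np.hstack([Xn**q for q in range(1, order + 1)])
    ybar = y.mean()
    yc = y - ybar
    Phibar = Phi.mean(axis=0)
    Phic = Phi - Phibar

    # eigendecomposition of the Gram matrix makes each update closed form
    evals, evecs = np.linalg.eigh(Phic.T @ Phic)
    evals = np.maximum(evals, 0.0)
    b = evecs.T @ (Phic.T @ yc)
    tss = float(yc @ yc)
    if tss <= 0:  # constant input: all spatial coefficients vanish
        return TSMFit(np.zeros(p), float(ybar), 0.0, _ALPHA_FLOOR, 0.0, order, center, scale)

    alpha, beta = 1.0, N / tss
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w_rot = beta * b / (alpha + beta * evals)
        w = evecs @ w_rot
        rss = float(np.sum((yc - Phic @ w) ** 2))
        gamma = float(np.sum(beta * evals / (alpha + beta * evals)))
        alpha_new = max(gamma / max(float(w @ w), 1e-300), _ALPHA_FLOOR)
        beta_new = min(max(N - gamma, 1e-12) / max(rss, (N - gamma) / _BETA_CEIL), _BETA_CEIL)
        if abs(np.log(alpha_new / alpha)) < tol and abs(np.log(beta_new / beta)) < tol:
            alpha, beta = alpha_new, beta_new
            break
        alpha, beta = alpha_new, beta_new
    w_rot = beta * b / (alpha + beta * evals)
    w = evecs @ w_rot
    rss = float(np.sum((yc - Phic @ w) ** 2))
    if not np.all(np.isfinite(w)):
        raise NumericalError("TSM evidence optimization produced non-finite coefficients")
    r2 = float(np.clip(1.0 - rss / tss, 0.0, 1.0))
    intercept = float(ybar - Phibar @ w)
    log.debug("fit_tsm: %d evidence iterations, alpha=%.3e beta=%.3e R2=%.4f", n_iter, alpha, beta, r2)
    return TSMFit(w, intercept, rss / N, alpha, r2, order, center, scale, n_iter=n_iter)
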